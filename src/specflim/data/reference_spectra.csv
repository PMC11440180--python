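wavelength_nm,free_nadh,bound_nadh
380.000000,0.000000,0.005856
382.000000,0.000000,0.009276
384.000000,0.000001,0.014136
386.000000,0.000003,0.020799
388.000000,0.000010,0.029648
390.000000,0.000030,0.041059
392.000000,0.000078,0.055388
394.000000,0.000184,0.072942
396.000000,0.000399,0.093967
398.000000,0.000804,0.118627
400.000000,0.001518,0.146992
402.000000,0.002704,0.179035
404.000000,0.004579,0.214622
406.000000,0.007408,0.253520
408.000000,0.011504,0.295400
410.000000,0.017218,0.339849
412.000000,0.024926,0.386386
414.000000,0.035010,0.434473
416.000000,0.047838,0.483533
418.000000,0.063745,0.532970
420.000000,0.083008,0.582182
422.000000,0.105836,0.630578
424.000000,0.132346,0.677595
426.000000,0.162560,0.722702
428.000000,0.196398,0.765420
430.000000,0.233676,0.805322
432.000000,0.274111,0.842042
434.000000,0.317332,0.875278
436.000000,0.362889,0.904793
438.000000,0.410271,0.930411
440.000000,0.458918,0.952024
442.000000,0.508242,0.969578
444.000000,0.557641,0.983078
446.000000,0.606518,0.992576
448.000000,0.654293,0.998171
450.000000,0.700418,1.000000
452.000000,0.744388,0.998233
454.000000,0.785747,0.993066
456.000000,0.824100,0.984720
458.000000,0.859112,0.973429
460.000000,0.890513,0.959439
462.000000,0.918097,0.943003
464.000000,0.941723,0.924379
466.000000,0.961309,0.903820
468.000000,0.976832,0.881577
470.000000,0.988322,0.857894
472.000000,0.995854,0.833006
474.000000,0.999546,0.807137
476.000000,0.999554,0.780499
478.000000,0.996061,0.753290
480.000000,0.989276,0.725696
482.000000,0.979427,0.697885
484.000000,0.966755,0.670014
486.000000,0.951511,0.642224
488.000000,0.933949,0.614642
490.000000,0.914325,0.587379
492.000000,0.892893,0.560537
494.000000,0.869900,0.534200
496.000000,0.845586,0.508445
498.000000,0.820180,0.483333
500.000000,0.793901,0.458918
502.000000,0.766954,0.435243
504.000000,0.739530,0.412340
506.000000,0.711807,0.390235
508.000000,0.683948,0.368947
510.000000,0.656101,0.348486
512.000000,0.628400,0.328857
514.000000,0.600964,0.310062
516.000000,0.573900,0.292093
518.000000,0.547300,0.274943
520.000000,0.521246,0.258599
522.000000,0.495805,0.243046
524.000000,0.471036,0.228265
526.000000,0.446986,0.214235
528.000000,0.423693,0.200936
530.000000,0.401186,0.188344
532.000000,0.379488,0.176434
534.000000,0.358612,0.165181
536.000000,0.338567,0.154559
538.000000,0.319356,0.144544
540.000000,0.300974,0.135108
542.000000,0.283417,0.126226
544.000000,0.266671,0.117873
546.000000,0.250725,0.110023
548.000000,0.235560,0.102651
550.000000,0.221157,0.095733
552.000000,0.207496,0.089246
554.000000,0.194553,0.083167
556.000000,0.182305,0.077474
558.000000,0.170727,0.072145
560.000000,0.159793,0.067160
562.000000,0.149478,0.062500
564.000000,0.139755,0.058145
566.000000,0.130600,0.054078
568.000000,0.121985,0.050281
570.000000,0.113887,0.046739
572.000000,0.106279,0.043434
574.000000,0.099137,0.040354
576.000000,0.092437,0.037483
578.000000,0.086157,0.034809
580.000000,0.080274,0.032318
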