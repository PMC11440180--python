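"""Group comparisons, correlations and spheroid depth profiles.

Cell-level parameters are summarized by medians and interquartile ranges;
two-group differences use the two-sided Mann-Whitney U test (consistent
with median/IQR reporting of skewed single-cell distributions); pairwise
correlation is Pearson's r by default with a Spearman option.  No multiple-
testing correction is applied by default; Holm's step-down is available.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError

__all__ = ["compare_groups", "correlate", "depth_profile", "CorrelationResult"]


def _require_column(table: pd.DataFrame, parameter: str) -> pd.Series:
    if parameter not in table.columns:
        raise DomainError(
            f"unknown parameter {parameter!r}; available columns: "
            f"{sorted(table.columns)}"
        )
    return pd.to_numeric(table[parameter], errors="coerce")


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    reference_group: str = "control",
    group_column: str = "group",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-group median/IQR with Mann-Whitney U tests against a reference.

    Returns one row per group with columns ``n, median, q25, q75,
    p_value`` (NaN for the reference itself) and the test name.  With
    ``correction='holm'`` p-values are Holm-adjusted across the pairwise
    tests.
    """
    if group_column not in table.columns:
        raise DomainError(f"table has no {group_column!r} column")
    values = _require_column(table, parameter)
    groups = table[group_column]
    names = list(pd.unique(groups))
    if reference_group not in names:
        raise DomainError(
            f"reference group {reference_group!r} not present; groups: {names}"
        )
    if len(names) < 2:
        raise DomainError("need at least two groups to compare")
    ref = values[groups == reference_group].dropna().to_numpy()
    rows = []
    for name in names:
        x = values[groups == name].dropna().to_numpy()
        if x.size < 3:
            raise DomainError(f"group {name!r} has fewer than 3 cells")
        row = {
            "parameter": parameter,
            "group": name,
            "n": int(x.size),
            "median": float(np.median(x)),
            "q25": float(np.percentile(x, 25)),
            "q75": float(np.percentile(x, 75)),
            "test": "mannwhitneyu",
            "p_value": np.nan,
        }
        if name != reference_group:
            row["p_value"] = float(
                sps.mannwhitneyu(x, ref, alternative="two-sided").pvalue
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if correction == "holm":
        mask = out["p_value"].notna()
        p = out.loc[mask, "p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        out.loc[mask, "p_value"] = adj
    elif correction is not None:
        raise DomainError(f"unknown correction {correction!r} (use None or 'holm')")
    return out


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    method: str


def correlate(
    table: pd.DataFrame,
    x_parameter: str,
    y_parameter: str,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation between two cell-table parameters (Pearson or Spearman)."""
    x = _require_column(table, x_parameter)
    y = _require_column(table, y_parameter)
    ok = x.notna() & y.notna() & np.isfinite(x) & np.isfinite(y)
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if x.size < 3:
        raise DomainError("need at least 3 paired finite values")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise DomainError(f"unknown method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size), method)


def depth_profile(
    table: pd.DataFrame,
    parameter: str,
    bin_width_um: float = 10.0,
    depth_column: str = "border_distance_um",
) -> pd.DataFrame:
    """Median/IQR of a parameter in distance-to-border bins.

    Bins of width ``bin_width_um`` start at depth 0; bins with fewer than
    3 cells are flagged ``low_n``.
    """
    if depth_column not in table.columns:
        raise DomainError(f"table has no {depth_column!r} column")
    if bin_width_um <= 0:
        raise DomainError("bin_width_um must be positive")
    values = _require_column(table, parameter)
    depth = pd.to_numeric(table[depth_column], errors="coerce")
    ok = values.notna() & depth.notna()
    if not ok.any():
        raise DomainError(f"no finite values in {depth_column!r}")
    values, depth = values[ok], depth[ok]
    idx = np.floor(depth.to_numpy() / bin_width_um).astype(int)
    rows = []
    for b in np.unique(idx):
        x = values.to_numpy()[idx == b]
        rows.append(
            {
                "depth_min_um": b * bin_width_um,
                "depth_max_um": (b + 1) * bin_width_um,
                "n": int(x.size),
                "median": float(np.median(x)),
                "q25": float(np.percentile(x, 25)),
                "q75": float(np.percentile(x, 75)),
                "low_n": bool(x.size < 3),
            }
        )
    return pd.DataFrame(rows).sort_values("depth_min_um", ignore_index=True)
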