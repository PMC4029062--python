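"""Agreement between composite and component linkage maps.

Concordance is quantified over the markers shared by two maps: root-mean-
squared error of positions per linkage group, Spearman rank correlation of
marker orders, and paired Wilcoxon signed-rank comparison of per-LG metrics
between two map-merging methods.  A marker assigned to different LGs by the
two maps is reported as a conflict and excluded from the metrics.  Because a
linkage group has no intrinsic orientation, the comparison orientation
(as-is vs flipped) is chosen per LG to maximize |rho| and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LinkageMap

__all__ = [
    "ConcordanceResult",
    "map_concordance",
    "map_rmse",
    "order_correlation",
    "compare_merge_metrics",
]


@dataclass
class ConcordanceResult:
    per_lg: pd.DataFrame  # lg, n_shared, rmse, spearman_rho, spearman_p, flipped
    conflicts: pd.DataFrame  # markers with discordant LG assignment

    def summary(self) -> str:
        lines = ["Map concordance (shared markers only)",
                 "  LG  n_shared  rmse_cm  rho      flipped"]
        for r in self.per_lg.itertuples(index=False):
            lines.append(
                f"  {r.lg:<3d} {r.n_shared:<9d} {r.rmse:<8.3f} "
                f"{r.spearman_rho:<8.4f} {r.flipped}"
            )
        if len(self.conflicts):
            lines.append(f"  {len(self.conflicts)} marker(s) with conflicting LG assignment")
        return "\n".join(lines)


def _shared(map_a: LinkageMap, map_b: LinkageMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = map_a.table.rename(columns={"lg": "lg_a", "position_cm": "pos_a"})
    b = map_b.table.rename(columns={"lg": "lg_b", "position_cm": "pos_b"})
    m = a.merge(b, on="marker_id", how="inner")
    conflicts = m[m["lg_a"] != m["lg_b"]]
    return m[m["lg_a"] == m["lg_b"]], conflicts


def map_concordance(
    map_a: LinkageMap, map_b: LinkageMap, min_shared_rho: int = 3
) -> ConcordanceResult:
    """Per-LG RMSE and Spearman order correlation between two maps."""
    shared, conflicts = _shared(map_a, map_b)
    rows = []
    for lg, g in shared.groupby("lg_a"):
        if len(g) < 1:
            continue
        pos_a = g["pos_a"].to_numpy()
        pos_b = g["pos_b"].to_numpy()
        flipped = False
        rho = rho_p = np.nan
        if len(g) >= min_shared_rho:
            full_b = map_b.positions(int(lg))
            length_b = float(full_b.max()) if len(full_b) else float(pos_b.max())
            r_fwd, p_fwd = stats.spearmanr(pos_a, pos_b)
            r_rev, p_rev = stats.spearmanr(pos_a, length_b - pos_b)
            # maximize |rho|; on ties (e.g. a perfectly reversed LG) prefer
            # the orientation with positive rho
            gap = abs(r_rev) - abs(r_fwd)
            if gap > 1e-12 or (abs(gap) <= 1e-12 and r_rev > r_fwd):
                flipped = True
                rho, rho_p = r_rev, p_rev
                pos_b = length_b - pos_b
            else:
                rho, rho_p = r_fwd, p_fwd
        else:
            warnings.warn(f"LG{lg}: fewer than {min_shared_rho} shared markers; "
                          "rank correlation skipped")
        rmse = float(np.sqrt(np.mean((pos_a - pos_b) ** 2)))
        rows.append(
            {
                "lg": int(lg),
                "n_shared": len(g),
                "rmse": rmse,
                "spearman_rho": float(rho),
                "spearman_p": float(rho_p),
                "flipped": flipped,
            }
        )
    if not rows:
        warnings.warn("no linkage group shares markers between the maps")
    return ConcordanceResult(
        pd.DataFrame(rows, columns=["lg", "n_shared", "rmse", "spearman_rho",
                                    "spearman_p", "flipped"]),
        conflicts,
    )


def map_rmse(map_a: LinkageMap, map_b: LinkageMap) -> pd.Series:
    """Per-LG RMSE (cM) of shared-marker positions, lg -> rmse."""
    res = map_concordance(map_a, map_b)
    return res.per_lg.set_index("lg")["rmse"]


def order_correlation(map_a: LinkageMap, map_b: LinkageMap) -> pd.Series:
    """Per-LG Spearman rank correlation of shared-marker positions (ties
    mid-ranked), lg -> rho.  LGs with < 3 shared markers are skipped."""
    res = map_concordance(map_a, map_b)
    ok = res.per_lg[res.per_lg["n_shared"] >= 3]
    return ok.set_index("lg")["spearman_rho"]


def compare_merge_metrics(metrics_a, metrics_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-LG metrics from
    two map-merging methods (exact null distribution for n <= 25).

    With all differences zero the comparison is vacuous and p = 1.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors differ in length")
    if len(a) < 5:
        raise ValueError("need >= 5 paired observations")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; test is vacuous, p = 1")
        return 1.0
    method = "exact" if len(a) <= 25 else "auto"
    try:
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)
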