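"""Linkage disequilibrium: Rogers-Huff r2 on unphased dosages, genome-wide
pair scans, the long-distance null model, inter-chromosomal testing and the
Hill-Weir drift-recombination decay fit.

r2 between two loci with unknown phase is estimated as the squared Pearson
correlation of genotype dosages over pairwise-complete individuals (the
composite-LD formulation).  The expected r2 under drift-recombination
equilibrium for population recombination parameter C = 4*Ne*c and sample size
n is

    E(r2) = (10 + C) / ((2 + C)(11 + C))
            * [1 + (3 + C)(12 + 12C + C^2) / (n (2 + C)(11 + C))]

and the decay fit replaces C with C_per_bp * distance, estimating C_per_bp by
nonlinear least squares (statsmodels-style model/results objects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import GenotypeMatrix, LinkageMap

__all__ = [
    "rogers_huff_r2",
    "pairwise_r2",
    "ld_scan",
    "NullModelResult",
    "long_distance_null",
    "InterchromTestResult",
    "interchrom_test",
    "hill_weir_expected_r2",
    "LDDecayModel",
    "LDDecayResults",
    "fit_decay",
    "corroborate_pairs",
]


def rogers_huff_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls.

    Missing calls are NaN (or the -1 sentinel).  Returns NaN when fewer than
    two shared calls remain or either marker is monomorphic among them;
    callers exclude such pairs from scans.
    """
    a = np.asarray(dosage_a, dtype=float).copy()
    b = np.asarray(dosage_b, dtype=float).copy()
    a[a < 0] = np.nan
    b[b < 0] = np.nan
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def pairwise_r2(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r2 and shared-call counts, exact pairwise-complete Pearson.

    Returns (r2, n_shared) square matrices (NaN where undefined).  Uses
    masked cross-products so missing data never biases the moments.
    """
    x = gm.dosage.astype(np.float64)
    v = (gm.dosage != -1).astype(np.float64)
    x = x * v  # zero out missing
    n = v @ v.T
    sx = x @ v.T
    sxx = (x * x) @ v.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_a = n * sxx - sx**2
        var_b = var_a.T
        denom = var_a * var_b
        r2 = np.where(denom > 0, cov**2 / denom, np.nan)
        r2[n < 2] = np.nan
    return r2, n.astype(np.int64)


def ld_scan(
    gm: GenotypeMatrix,
    lmap: LinkageMap,
    maf_min: float = 0.0,
) -> pd.DataFrame:
    """r2 for all pairwise combinations of mapped markers, within and between
    chromosomes.

    Returns a table with columns marker_a, marker_b, lg_a, lg_b, dist_cm (NaN
    for inter-chromosomal pairs; 0 for co-located markers, e.g. SNPs from the
    same contig), r2, maf_a, maf_b, n_shared.  Pairs with undefined r2
    (monomorphic among shared calls) are excluded.  ``maf_min`` drops markers
    below the MAF threshold before pairing; the default applies no filter.
    """
    shared = [m for m in lmap.table["marker_id"] if m in set(gm.markers)]
    sub = gm.subset_markers(shared)
    xf = sub.dosage_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_alt = np.nanmean(xf, axis=1) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    if maf_min > 0:
        keep = np.where(maf >= maf_min)[0]
        shared = [shared[i] for i in keep]
        sub = sub.subset_markers(shared)
        maf = maf[keep]
    r2, nsh = pairwise_r2(sub)
    lg = lmap.lg_of().loc[shared].to_numpy()
    pos = lmap.position_of().loc[shared].to_numpy()
    iu, ju = np.triu_indices(len(shared), k=1)
    same_lg = lg[iu] == lg[ju]
    dist = np.where(same_lg, np.abs(pos[iu] - pos[ju]), np.nan)
    out = pd.DataFrame(
        {
            "marker_a": np.asarray(shared, dtype=object)[iu],
            "marker_b": np.asarray(shared, dtype=object)[ju],
            "lg_a": lg[iu],
            "lg_b": lg[ju],
            "dist_cm": dist,
            "r2": r2[iu, ju],
            "maf_a": maf[iu],
            "maf_b": maf[ju],
            "n_shared": nsh[iu, ju],
        }
    )
    return out[~out["r2"].isna()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Long-distance null model and inter-chromosomal test
# ---------------------------------------------------------------------------

@dataclass
class NullModelResult:
    """Long-distance LD null distribution with its filter audit trail.

    ``audit`` records the count entering and leaving every filter so the
    bookkeeping (input = retained + each exclusion) is checkable.
    """

    values: np.ndarray
    retained: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)


def long_distance_null(
    pairs: pd.DataFrame,
    component_maps: dict[str, LinkageMap] | None = None,
    r2_min: float = 0.1,
    maf_min: float = 0.20,
    near_cutoff_cm: float = 1.0,
) -> NullModelResult:
    """Build the long-distance (non-physical) LD null distribution.

    Starting from intra-chromosomal pairs at composite distance > 0 with
    r2 > ``r2_min``, drop pairs that component maps reveal to be physically
    close: markers co-located (0 cM) or within ``near_cutoff_cm`` on any
    component map carrying both, and pairs whose markers never co-occur on a
    single component map (their long composite distance cannot be verified).
    Finally drop pairs where either MAF <= ``maf_min``.  The surviving r2
    values are the null distribution for inter-chromosomal LD.
    """
    intra = pairs[(pairs["lg_a"] == pairs["lg_b"]) & (pairs["dist_cm"] > 0)]
    cand = intra[intra["r2"] > r2_min].reset_index(drop=True)
    audit = {"input_above_r2_min": len(cand)}

    if component_maps:
        comp_pos = [m.position_of() for m in component_maps.values()]
        comp_dist = np.full(len(cand), np.nan)
        for k, row in cand.iterrows():
            dists = [
                abs(pos[row.marker_a] - pos[row.marker_b])
                for pos in comp_pos
                if row.marker_a in pos.index and row.marker_b in pos.index
            ]
            if dists:
                comp_dist[k] = min(dists)
        on_same = ~np.isnan(comp_dist)
        zero = on_same & (comp_dist == 0)
        near = on_same & (comp_dist > 0) & (comp_dist <= near_cutoff_cm)
        keep = on_same & ~zero & ~near
        audit.update(
            same_component_map=int(on_same.sum()),
            excluded_cross_map=int((~on_same).sum()),
            excluded_zero_cm=int(zero.sum()),
            excluded_near_cm=int(near.sum()),
        )
        cand = cand[keep].reset_index(drop=True)
    audit["retained_before_maf"] = len(cand)
    low_maf = (cand["maf_a"] <= maf_min) | (cand["maf_b"] <= maf_min)
    audit["excluded_maf"] = int(low_maf.sum())
    cand = cand[~low_maf].reset_index(drop=True)
    audit["retained"] = len(cand)
    return NullModelResult(cand["r2"].to_numpy(), cand, audit)


@dataclass
class InterchromTestResult:
    threshold: float  # Bonferroni-adjusted null quantile actually applied
    unadjusted_bound: float  # (1 - alpha) null quantile
    n_tests: int
    significant: pd.DataFrame


def interchrom_test(
    inter_pairs: pd.DataFrame,
    null_values: np.ndarray,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> InterchromTestResult:
    """Test inter-chromosomal r2 against the long-distance null distribution.

    The critical value is the empirical (1 - alpha) quantile of the null
    (linear interpolation), Bonferroni-adjusted over the number of
    inter-chromosomal pairs tested when ``bonferroni`` is set.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    inter = inter_pairs[inter_pairs["lg_a"] != inter_pairs["lg_b"]]
    n_tests = len(inter)
    unadj = float(np.quantile(null_values, 1.0 - alpha))
    level = alpha / n_tests if (bonferroni and n_tests) else alpha
    thr = float(np.quantile(null_values, 1.0 - level))
    sig = inter[inter["r2"] > thr].reset_index(drop=True)
    return InterchromTestResult(thr, unadj, n_tests, sig)


# ---------------------------------------------------------------------------
# Hill-Weir expectation and decay fit
# ---------------------------------------------------------------------------

def hill_weir_expected_r2(C, n: int):
    """Expected r2 under drift-recombination equilibrium, adjusted for sample
    size n (number of diploid individuals genotyped)."""
    C = np.asarray(C, dtype=float)
    a = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    b = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    out = a * b
    return float(out) if out.ndim == 0 else out


class LDDecayModel:
    """Nonlinear least-squares fit of the drift-recombination decay curve.

    Models observed r2 at physical distance d (bp) as E(r2 | C_per_bp * d, n)
    and estimates the per-bp population recombination parameter C_per_bp.
    """

    def __init__(self, distances_bp, r2, n: int):
        self.d = np.asarray(distances_bp, dtype=float)
        self.r2 = np.asarray(r2, dtype=float)
        if len(self.d) != len(self.r2):
            raise ValueError("distances and r2 differ in length")
        if len(self.d) < 5:
            raise ValueError("need >= 5 pairs for a decay fit")
        if n < 2:
            raise ValueError("n must be >= 2")
        self.n = int(n)

    def predict(self, c_per_bp: float) -> np.ndarray:
        return hill_weir_expected_r2(c_per_bp * self.d, self.n)

    def _rss(self, c: float) -> float:
        return float(np.sum((self.r2 - self.predict(c)) ** 2))

    def fit(self) -> "LDDecayResults":
        # coarse positive grid for a starting value, then unconstrained
        # refinement (the estimate may legitimately come out negative on flat
        # or rising data, which is flagged rather than clipped).
        grid = np.concatenate([[0.0], np.logspace(-9, 1, 41)])
        c0 = grid[int(np.argmin([self._rss(c) for c in grid]))]
        res = optimize.least_squares(
            lambda c: self.r2 - self.predict(c[0]), x0=[c0], method="lm"
        )
        c_hat = float(res.x[0])
        rss = float(np.sum(res.fun**2))
        dof = max(len(self.d) - 1, 1)
        jac = np.atleast_2d(res.jac)
        try:
            cov = np.linalg.inv(jac.T @ jac) * rss / dof
            se = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            se = float("nan")
        return LDDecayResults(
            model=self,
            c_per_bp=c_hat,
            bse=se,
            rss=rss,
            converged=bool(res.success),
            negative=c_hat < 0,
        )


@dataclass
class LDDecayResults:
    """Fitted decay parameters; ``negative`` flags a physically meaningless
    (but honestly reported) estimate, as happens when r2 shows no decay."""

    model: LDDecayModel
    c_per_bp: float
    bse: float
    rss: float
    converged: bool
    negative: bool

    @property
    def n(self) -> int:
        return self.model.n

    def predict(self, distances_bp) -> np.ndarray:
        return hill_weir_expected_r2(self.c_per_bp * np.asarray(distances_bp, float), self.n)

    def summary(self) -> str:
        lines = [
            "LD decay fit (drift-recombination equilibrium expectation)",
            f"  pairs: {len(self.model.d)}    sample size n: {self.n}",
            f"  C_per_bp: {self.c_per_bp:.6g}  (SE {self.bse:.3g})",
            f"  RSS: {self.rss:.6g}    converged: {self.converged}",
        ]
        if self.negative:
            lines.append("  WARNING: estimate is negative; no usable decay signal")
        return "\n".join(lines)


def fit_decay(distances_bp, r2, n: int) -> LDDecayResults:
    """Convenience wrapper: ``LDDecayModel(distances_bp, r2, n).fit()``."""
    return LDDecayModel(distances_bp, r2, n).fit()


# ---------------------------------------------------------------------------
# Corroboration of long-distance pairs by intragenic SNPs
# ---------------------------------------------------------------------------

def corroborate_pairs(
    retained: pd.DataFrame,
    gm: GenotypeMatrix,
    contig_of: dict[str, str],
    agree_tol: float = 0.1,
) -> pd.DataFrame:
    """Cross-check retained long-distance pairs with sibling SNPs.

    For each pair (a, b), every other genotyped SNP from the same contig as a
    (and as b) is correlated with the partner marker; the pair is ``confirmed``
    when at least one sibling shows r2 within ``agree_tol`` of the pair's own.
    """
    idx = {m: i for i, m in enumerate(gm.markers)}
    by_contig: dict[str, list[str]] = {}
    for m, c in contig_of.items():
        by_contig.setdefault(c, []).append(m)

    rows = []
    for row in retained.itertuples(index=False):
        support, agree = 0, 0
        for anchor, partner in ((row.marker_a, row.marker_b), (row.marker_b, row.marker_a)):
            contig = contig_of.get(anchor)
            if contig is None or partner not in idx:
                continue
            for sib in by_contig.get(contig, []):
                if sib == anchor or sib not in idx:
                    continue
                r2s = rogers_huff_r2(gm.dosage[idx[sib]], gm.dosage[idx[partner]])
                if np.isnan(r2s):
                    continue
                support += 1
                if abs(r2s - row.r2) <= agree_tol:
                    agree += 1
        rows.append(
            {
                "marker_a": row.marker_a,
                "marker_b": row.marker_b,
                "r2": row.r2,
                "support_n": support,
                "support_agree": agree,
                "confirmed": agree > 0,
            }
        )
    return pd.DataFrame(rows)
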