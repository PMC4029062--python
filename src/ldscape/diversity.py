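"""Sample and marker QC, per-marker diversity statistics and per-LG diversity
comparisons.

Per biallelic marker the table reports the reference-allele frequency p, minor
allele frequency MAF = min(p, 1-p), observed heterozygosity Ho (fraction of
heterozygous calls) and Nei's expected heterozygosity He = 2p(1-p), whose
maximum is 0.5 for a biallelic locus.  Departure from Hardy-Weinberg
equilibrium is assessed by the exact conditional test (enumeration over
heterozygote counts given the allele counts), with a chi-square alternative
for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, LinkageMap

__all__ = [
    "QCResult",
    "call_rate_filter",
    "DuplicatePair",
    "detect_duplicates",
    "diversity_table",
    "hwe_exact_test",
    "hwe_chi2_test",
    "bonferroni_alpha",
    "ConversionReport",
    "conversion_report",
    "HeByLGResult",
    "he_by_lg_comparison",
]


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    call_rates: pd.Series
    flagged_samples: list[str]
    duplicate_pairs: list["DuplicatePair"] = field(default_factory=list)


def call_rate_filter(
    gm: GenotypeMatrix, min_rate: float
) -> tuple[QCResult, GenotypeMatrix]:
    """Drop samples whose call rate falls below ``min_rate`` and list them."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    rates = gm.call_rate_per_sample()
    flagged = rates.index[rates < min_rate].tolist()
    if len(flagged) == gm.n_samples:
        raise ValueError("call-rate filter would remove every sample")
    return QCResult(rates, flagged), gm.drop_samples(flagged)


@dataclass(frozen=True)
class DuplicatePair:
    sample_a: str
    sample_b: str
    identity: float
    n_shared: int


def detect_duplicates(
    gm: GenotypeMatrix,
    identity_threshold: float = 0.995,
    min_shared: int = 100,
) -> list[DuplicatePair]:
    """All unordered sample pairs with genotype identity >= threshold over
    shared non-missing calls.

    Pairs sharing fewer than ``min_shared`` calls (including zero) are never
    reported as duplicates — a verdict needs data — and a warning is emitted
    for pairs with no shared calls at all.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    v = (gm.dosage != MISSING).astype(np.float64)
    shared = v.T @ v
    matches = np.zeros_like(shared)
    for g in (0, 1, 2):
        a = ((gm.dosage == g) & (gm.dosage != MISSING)).astype(np.float64)
        matches += a.T @ a
    out: list[DuplicatePair] = []
    n = gm.n_samples
    iu, ju = np.triu_indices(n, k=1)
    zero_shared = shared[iu, ju] == 0
    if zero_shared.any():
        warnings.warn(
            f"{int(zero_shared.sum())} sample pair(s) share no non-missing "
            "calls; excluded from duplicate detection"
        )
    for i, j in zip(iu, ju):
        ns = int(shared[i, j])
        if ns < min_shared:
            continue
        ident = matches[i, j] / ns
        if ident >= identity_threshold:
            out.append(DuplicatePair(gm.samples[i], gm.samples[j], float(ident), ns))
    return out


# ---------------------------------------------------------------------------
# Diversity table
# ---------------------------------------------------------------------------

def diversity_table(
    gm: GenotypeMatrix,
    unbiased_he: bool = False,
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Per-marker diversity statistics: n_called, p, maf, ho, he, hwe_p.

    p is the reference-allele frequency over called genotypes; He is plain
    2p(1-p) by default (``unbiased_he`` applies the 2n/(2n-1) small-sample
    correction).  Markers with zero calls get NaN statistics with a warning.
    """
    if hwe_method not in ("exact", "chi2"):
        raise ValueError("hwe_method must be 'exact' or 'chi2'")
    d = gm.dosage
    called = d != MISSING
    n_called = called.sum(axis=1)
    n_het = ((d == 1) & called).sum(axis=1)
    n_alt_hom = ((d == 2) & called).sum(axis=1)
    n_ref_hom = ((d == 0) & called).sum(axis=1)
    if (n_called == 0).any():
        bad = [m for m, k in zip(gm.markers, n_called) if k == 0]
        warnings.warn(f"{len(bad)} marker(s) with zero calls: statistics NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (n_het + 2 * n_alt_hom) / (2 * n_called)
        p = 1.0 - p_alt
        maf = np.minimum(p, 1.0 - p)
        ho = n_het / n_called
        he = 2.0 * p * (1.0 - p)
        if unbiased_he:
            he = he * (2 * n_called) / (2 * n_called - 1)
    test = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test
    hwe_p = np.array(
        [
            test(int(aa), int(ab), int(bb)) if k > 0 else np.nan
            for aa, ab, bb, k in zip(n_ref_hom, n_het, n_alt_hom, n_called)
        ]
    )
    return pd.DataFrame(
        {
            "marker_id": gm.markers,
            "n_called": n_called,
            "p": p,
            "maf": maf,
            "ho": ho,
            "he": he,
            "hwe_p": hwe_p,
        }
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def _hwe_log_prob(n_ab: int, n: int, n_a: int) -> float:
    """log P(heterozygote count = n_ab | n genotypes, n_a copies of allele A)."""
    n_aa = (n_a - n_ab) // 2
    n_bb = n - n_aa - n_ab
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_ab + 1)
        - gammaln(n_bb + 1)
        + n_ab * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value by conditional enumeration.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (two-sided,
    the standard exact SNP-HWE construction).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:  # monomorphic: only one table possible
        return 1.0
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    logp = np.array([_hwe_log_prob(int(h), n, n_a) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.where(hets == n_ab)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test (no continuity
    correction); faster, approximate alternative to the exact test."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def bonferroni_alpha(nominal_alpha: float, n_tests: int) -> float:
    """Experiment-wise significance level: nominal alpha / number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return nominal_alpha / n_tests


# ---------------------------------------------------------------------------
# Assay conversion bookkeeping
# ---------------------------------------------------------------------------

_CLASSES = ("snp", "indel")
_OUTCOMES = ("failed", "monomorphic", "polymorphic")


@dataclass
class ConversionReport:
    """Cross-tabulation of assay outcomes by marker class with conversion
    rates (polymorphic / total, %) per class and overall."""

    counts: pd.DataFrame  # index: class, columns: outcome

    @property
    def rates_pct(self) -> pd.Series:
        totals = self.counts.sum(axis=1)
        return 100.0 * self.counts["polymorphic"] / totals

    @property
    def overall_rate_pct(self) -> float:
        return float(
            100.0 * self.counts["polymorphic"].sum() / self.counts.to_numpy().sum()
        )


def conversion_report(manifest: pd.DataFrame) -> ConversionReport:
    """Tabulate an assay manifest with columns marker_id, class, outcome."""
    if len(manifest) == 0:
        raise ValueError("empty assay manifest")
    bad_class = set(manifest["class"]) - set(_CLASSES)
    if bad_class:
        raise ValueError(f"unknown marker class(es): {sorted(bad_class)}")
    bad_out = set(manifest["outcome"]) - set(_OUTCOMES)
    if bad_out:
        raise ValueError(f"unknown outcome(s): {sorted(bad_out)}")
    counts = (
        manifest.groupby(["class", "outcome"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(_CLASSES), columns=list(_OUTCOMES), fill_value=0)
    )
    return ConversionReport(counts)


# ---------------------------------------------------------------------------
# He by linkage group: ANOVA + Tukey HSD with letter groupings
# ---------------------------------------------------------------------------

@dataclass
class HeByLGResult:
    anova_f: float
    anova_p: float
    group_means: pd.Series
    tukey: pd.DataFrame  # pairwise comparisons with reject flag
    letters: dict[int, str]  # compact letter display per LG

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA of He across linkage groups: "
            f"F = {self.anova_f:.4g}, p = {self.anova_p:.4g}",
            "LG   mean He   group",
        ]
        for lg, m in self.group_means.items():
            lines.append(f"{lg:<4d} {m:.4f}    {self.letters[lg]}")
        return "\n".join(lines)


def _compact_letters(levels: list[int], distinct: set[tuple[int, int]]) -> dict[int, str]:
    """Insert-and-absorb compact letter display: levels not significantly
    different share at least one letter; significantly different pairs never
    share a letter."""
    groups: list[set[int]] = [set(levels)]
    for a, b in sorted(distinct):
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            ga, gb = g - {b}, g - {a}
            for cand in (ga, gb):
                if not any(cand <= other for other in groups):
                    groups.append(cand)
    groups.sort(key=lambda g: min(levels.index(x) for x in g))
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lv in g:
            letters[lv] += ch
    return letters


def he_by_lg_comparison(
    diversity: pd.DataFrame, lmap: LinkageMap, alpha: float = 0.05
) -> HeByLGResult:
    """One-way ANOVA of per-marker He across LGs plus Tukey HSD groupings.

    Only markers present on the map are used.  Requires >= 2 LGs with >= 2
    mapped markers each.
    """
    merged = diversity.merge(
        lmap.table[["marker_id", "lg"]], on="marker_id", how="inner"
    ).dropna(subset=["he"])
    sizes = merged.groupby("lg").size()
    ok_lgs = sizes.index[sizes >= 2]
    if len(ok_lgs) < 2:
        raise ValueError("need >= 2 linkage groups with >= 2 mapped markers each")
    merged = merged[merged["lg"].isin(ok_lgs)]
    groups = [g["he"].to_numpy() for _, g in merged.groupby("lg")]
    grand = np.concatenate(groups)
    ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ssb < 1e-30:  # identical group means: F = 0 exactly, p = 1
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*groups)
    levels = sorted(ok_lgs.tolist())
    if np.concatenate(groups).var() < 1e-30:
        tukey_df = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj", "reject"])
        distinct: set[tuple[int, int]] = set()
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(
            merged["he"].to_numpy(), merged["lg"].to_numpy(), alpha=alpha
        )
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        distinct = {
            tuple(sorted((int(r["group1"]), int(r["group2"]))))
            for _, r in tukey_df.iterrows()
            if bool(r["reject"])
        }
    letters = _compact_letters(levels, distinct)
    return HeByLGResult(
        anova_f=float(f_stat),
        anova_p=float(p_val),
        group_means=merged.groupby("lg")["he"].mean(),
        tukey=tukey_df,
        letters=letters,
    )
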