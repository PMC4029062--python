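"""Synthetic linkage maps and genotype matrices with the statistical structure
the downstream analyses assume.

The generator emulates a conifer-style dataset: a dozen linkage groups of
115-182 cM carrying a few hundred SNPs each, genotyped on ~186 unrelated
diploid individuals.  Three features of such data are reproduced
mechanistically rather than painted on:

* marker clustering — background markers are uniform on each LG, with optional
  Gaussian clusters (recombination cold spots) and marker-free gaps (hot
  spots) planted at known locations;
* an ascertained allele-frequency spectrum — candidate allele frequencies are
  drawn uniformly and accepted only if a small simulated discovery panel of
  gametes shows MAF at or above a cut-off (default 0.33), imitating
  array-design ascertainment that shifts the MAF spectrum upward;
* linkage disequilibrium decaying with genetic distance — individuals are
  built from gametes that recombine a finite pool of founder haplotypes along
  the map (Haldane mapping function, no interference), so nearby markers share
  founder origin and correlate while distant markers do not.

Every generator is seed-deterministic: the same configuration and seed produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, LinkageMap
from .ld import hill_weir_expected_r2

__all__ = [
    "ClusterSpec",
    "GapSpec",
    "SimulationConfig",
    "simulate_map",
    "simulate_genotypes",
    "inject_duplicates",
    "simulate_decay_pairs",
    "jittered_component_maps",
]


@dataclass(frozen=True)
class ClusterSpec:
    """A planted marker cluster (recombination cold spot)."""

    center_cm: float
    sd_cm: float
    n_extra: int


@dataclass(frozen=True)
class GapSpec:
    """A planted marker-free interval (recombination hot spot)."""

    start_cm: float
    end_cm: float


@dataclass
class SimulationConfig:
    """Study-shape parameters for the synthetic dataset.

    Defaults mirror the archetype dataset: 12 LGs spanning 115-182 cM, ~150
    markers per LG, 186 individuals, discovery-panel ascertainment at
    MAF >= 0.33 over 12 gametes.  ``clusters`` and ``gaps`` map LG id to the
    features planted on that LG.
    """

    n_lg: int = 12
    lg_lengths: list[float] | None = None  # default: linspace(115, 182, n_lg)
    n_markers_per_lg: int = 150
    #: distribute the genome-wide total (n_lg * n_markers_per_lg) over LGs
    #: multinomially in proportion to their lengths (uniform placement over
    #: the whole genome); with False every LG gets exactly n_markers_per_lg
    markers_proportional_to_length: bool = True
    clusters: dict[int, list[ClusterSpec]] = field(default_factory=dict)
    gaps: dict[int, list[GapSpec]] = field(default_factory=dict)
    n_individuals: int = 186
    maf_ascertainment_min: float = 0.33
    discovery_gametes: int = 12
    n_founder_haplotypes: int = 16
    missing_rate: float = 0.08  # yields ~92% mean call rate
    seed: int = 0

    def resolved_lengths(self) -> dict[int, float]:
        if self.lg_lengths is not None:
            if len(self.lg_lengths) != self.n_lg:
                raise ValueError("lg_lengths must have n_lg entries")
            lens = list(self.lg_lengths)
        else:
            lens = np.linspace(115.0, 182.0, self.n_lg).tolist()
        return {lg: float(l) for lg, l in zip(range(1, self.n_lg + 1), lens)}

    def validate(self) -> None:
        if self.n_lg < 1 or self.n_markers_per_lg < 1 or self.n_individuals < 1:
            raise ValueError("n_lg, n_markers_per_lg, n_individuals must be >= 1")
        if self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes must be >= 2")
        if not 0 < self.maf_ascertainment_min <= 0.5:
            raise ValueError("maf_ascertainment_min must be in (0, 0.5]")
        lens = self.resolved_lengths()
        for lg, specs in self.gaps.items():
            length = lens[lg]
            covered = 0.0
            for g in specs:
                if not (0 <= g.start_cm < g.end_cm <= length):
                    raise ValueError(f"gap {g} outside [0, {length}] on LG{lg}")
                covered += g.end_cm - g.start_cm
            if covered >= length:
                raise ValueError(f"gaps cover all of LG{lg}")
        for lg, specs in self.clusters.items():
            length = lens[lg]
            for c in specs:
                if not 0 <= c.center_cm <= length:
                    raise ValueError(f"cluster {c} outside [0, {length}] on LG{lg}")


def _in_gap(pos: np.ndarray, gaps: list[GapSpec]) -> np.ndarray:
    hit = np.zeros(pos.shape, dtype=bool)
    for g in gaps:
        hit |= (pos > g.start_cm) & (pos < g.end_cm)
    return hit


def simulate_map(config: SimulationConfig, rng: np.random.Generator | None = None) -> LinkageMap:
    """Simulate a linkage map: uniform background plus clusters, minus gaps."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = config.resolved_lengths()
    if config.markers_proportional_to_length and config.n_lg > 1:
        lens = np.array(list(lengths.values()))
        counts = rng.multinomial(config.n_lg * config.n_markers_per_lg,
                                 lens / lens.sum())
        n_background = dict(zip(lengths, counts))
    else:
        n_background = {lg: config.n_markers_per_lg for lg in lengths}
    entries: list[tuple[str, int, float]] = []
    for lg, length in lengths.items():
        pos = rng.uniform(0.0, length, n_background[lg])
        for c in config.clusters.get(lg, []):
            extra = rng.normal(c.center_cm, c.sd_cm, c.n_extra)
            pos = np.concatenate([pos, np.clip(extra, 0.0, length)])
        gaps = config.gaps.get(lg, [])
        if gaps:
            pos = pos[~_in_gap(pos, gaps)]
        pos = np.sort(pos)
        for k, p in enumerate(pos):
            entries.append((f"LG{lg}_M{k + 1:04d}", lg, float(p)))
    return LinkageMap.from_entries(entries)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _ascertained_frequencies(
    n: int, maf_min: float, discovery_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform(0,1) allele frequencies accepted only when a simulated
    discovery panel of gametes shows MAF >= maf_min."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 1.0, 2 * (n - filled) + 8)
        k = rng.binomial(discovery_gametes, cand)
        maf = np.minimum(k, discovery_gametes - k) / discovery_gametes
        ok = cand[maf >= maf_min]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _haldane_recomb_fraction(d_cm: np.ndarray) -> np.ndarray:
    """Map distance (cM) -> recombination fraction, Haldane (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


def _simulate_lg_gametes(
    pos: np.ndarray,
    founders: np.ndarray,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gametes (n_gametes x m) formed by recombining founder haplotypes along
    the map: a copying chain that redraws the founder with the interval's
    Haldane recombination probability."""
    n_founders, m = founders.shape
    c = _haldane_recomb_fraction(np.diff(pos))
    fidx = np.empty((n_gametes, m), dtype=np.int64)
    fidx[:, 0] = rng.integers(n_founders, size=n_gametes)
    for j in range(1, m):
        redraw = rng.random(n_gametes) < c[j - 1]
        fidx[:, j] = np.where(
            redraw, rng.integers(n_founders, size=n_gametes), fidx[:, j - 1]
        )
    return founders[fidx, np.arange(m)]


def simulate_genotypes(
    lmap: LinkageMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_haplotypes: bool = False,
):
    """Simulate unphased dosages on ``lmap`` for ``config.n_individuals``.

    Per LG: founder haplotypes carry alleles drawn independently at the
    ascertained frequencies; each individual receives two gametes recombined
    from the founder pool, so expected genotype frequencies are Hardy-Weinberg
    and r2 between markers decays with genetic distance.  With
    ``return_haplotypes`` the two gamete matrices (markers x individuals) are
    returned alongside, for haplotype-truth LD validation.
    """
    if config.n_founder_haplotypes < 2:
        raise ValueError("n_founder_haplotypes must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_individuals
    hap1_blocks, hap2_blocks, markers = [], [], []
    for lg in lmap.lg_ids:
        pos = lmap.positions(lg)
        m = len(pos)
        freqs = _ascertained_frequencies(
            m, config.maf_ascertainment_min, config.discovery_gametes, rng
        )
        founders = (rng.random((config.n_founder_haplotypes, m)) < freqs).astype(np.int8)
        gam = _simulate_lg_gametes(pos, founders, 2 * n, rng)
        hap1_blocks.append(gam[:n].T)
        hap2_blocks.append(gam[n:].T)
        markers.extend(lmap.markers_on(lg))
    hap1 = np.vstack(hap1_blocks)
    hap2 = np.vstack(hap2_blocks)
    dosage = (hap1 + hap2).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = MISSING
    samples = [f"ind{j + 1:04d}" for j in range(n)]
    gm = GenotypeMatrix(markers, samples, dosage)
    if return_haplotypes:
        return gm, hap1, hap2
    return gm


def inject_duplicates(
    gm: GenotypeMatrix,
    k_pairs: int,
    seed: int | np.random.Generator = 0,
    missing_flip_rate: float = 0.0,
) -> GenotypeMatrix:
    """Append ``k_pairs`` relabelled copies of existing samples (mislabelling
    mimic).  ``missing_flip_rate`` optionally blanks a fraction of the copied
    calls so the pair differs in missingness but never in genotype."""
    if k_pairs > gm.n_samples:
        raise ValueError("k_pairs cannot exceed the number of samples")
    if k_pairs == 0:
        return gm
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(gm.n_samples, size=k_pairs, replace=False)
    dup = gm.dosage[:, chosen].copy()
    if missing_flip_rate > 0:
        blank = rng.random(dup.shape) < missing_flip_rate
        dup[blank] = MISSING
    new_ids = [f"dup_of_{gm.samples[j]}" for j in chosen]
    return GenotypeMatrix(
        list(gm.markers),
        list(gm.samples) + new_ids,
        np.hstack([gm.dosage, dup]),
    )


def simulate_decay_pairs(
    c_per_bp: float,
    n: int,
    distances_bp: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """(distance, r2) pairs on the drift-recombination expectation curve.

    r2 = E(r2 | C = c_per_bp * d, n) plus clipped Gaussian noise; with
    ``noise_sd`` 0 the points lie exactly on the curve.
    """
    if c_per_bp < 0:
        raise ValueError("c_per_bp must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    d = np.asarray(distances_bp, dtype=float)
    r2 = hill_weir_expected_r2(c_per_bp * d, n)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        r2 = np.clip(r2 + rng.normal(0.0, noise_sd, d.shape), 0.0, 1.0)
    return pd.DataFrame({"distance_bp": d, "r2": r2})


def jittered_component_maps(
    lmap: LinkageMap,
    n_maps: int = 3,
    keep_frac: float = 0.7,
    jitter_sd_cm: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, LinkageMap]:
    """Component-map stand-ins: random subsets of the composite map with
    Gaussian position jitter, for concordance and null-model filters."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, LinkageMap] = {}
    t = lmap.table
    for k in range(n_maps):
        keep = rng.random(len(t)) < keep_frac
        sub = t[keep].copy()
        sub["position_cm"] = np.clip(
            sub["position_cm"] + rng.normal(0.0, jitter_sd_cm, len(sub)), 0.0, None
        )
        sub = sub.sort_values(["lg", "position_cm"], kind="stable").reset_index(drop=True)
        out[f"component{k + 1}"] = LinkageMap(sub)
    return out
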