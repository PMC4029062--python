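"""Empirical variogram of expected heterozygosity along linkage groups.

The variogram gamma(h) is half the variance of differences in He between
marker pairs separated by map distance h:

    gamma(h) = 1/(2 N(h)) * sum_{(i,j): |s_i - s_j| in bin h} (z_i - z_j)^2

with N(h) the number of pairs in the distance bin.  Pairs are formed within
linkage groups only; bins are half-open [k*lag, (k+1)*lag) up to a maximum
lag, and co-located pairs (0 cM) fall in the first bin.  Besides this
classical (Matheron) estimator, the Cressie-Hawkins robust estimator based on
fourth powers of mean square-root differences is available to damp outliers:

    gamma_CH(h) = 0.5 * (mean |z_i - z_j|^{1/2})^4 / (0.457 + 0.494 / N(h))

Significance is assessed by permutation: He values are shuffled across mapped
positions genome-wide, giving a per-bin 95% envelope and the probability of a
permuted value exceeding the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import LinkageMap

__all__ = [
    "empirical_variogram",
    "pangenomic_variogram",
    "permutation_envelope",
    "HeVariogram",
    "VariogramResults",
]


def _pair_arrays(
    lmap: LinkageMap, max_lag: float, lag_size: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Within-LG marker pairs with distance < n_bins*lag_size.

    Returns (idx_i, idx_j, bin_index, lg) into the map's marker order; pairs
    are never formed across linkage groups.
    """
    n_bins = int(np.ceil(max_lag / lag_size))
    offsets: dict[int, int] = {}
    start = 0
    for lg in lmap.lg_ids:
        offsets[lg] = start
        start += len(lmap.markers_on(lg))
    ii, jj, bb, ll = [], [], [], []
    for lg in lmap.lg_ids:
        pos = lmap.positions(lg)
        iu, ju = np.triu_indices(len(pos), k=1)
        d = np.abs(pos[iu] - pos[ju])
        binidx = np.floor(d / lag_size).astype(np.int64)
        keep = binidx < n_bins
        ii.append(iu[keep] + offsets[lg])
        jj.append(ju[keep] + offsets[lg])
        bb.append(binidx[keep])
        ll.append(np.full(int(keep.sum()), lg, dtype=np.int64))
    return (
        np.concatenate(ii),
        np.concatenate(jj),
        np.concatenate(bb),
        np.concatenate(ll),
    )


def _gamma_from_pairs(
    z: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    bins: np.ndarray,
    n_bins: int,
    estimator: str,
) -> tuple[np.ndarray, np.ndarray]:
    n_pairs = np.bincount(bins, minlength=n_bins).astype(float)
    diff = z[ii] - z[jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "classical":
            s = np.bincount(bins, weights=diff**2, minlength=n_bins)
            gamma = s / (2.0 * n_pairs)
        elif estimator == "robust":
            s = np.bincount(bins, weights=np.sqrt(np.abs(diff)), minlength=n_bins)
            mean_root = s / n_pairs
            gamma = 0.5 * mean_root**4 / (0.457 + 0.494 / n_pairs)
        else:
            raise ValueError("estimator must be 'classical' or 'robust'")
    gamma[n_pairs == 0] = np.nan
    return gamma, n_pairs


def _he_vector(lmap: LinkageMap, he_values: Mapping[str, float] | pd.Series) -> np.ndarray:
    if isinstance(he_values, pd.Series):
        he_values = he_values.to_dict()
    missing = [m for m in lmap.table["marker_id"] if m not in he_values]
    if missing:
        raise ValueError(
            f"he value missing for {len(missing)} mapped marker(s), "
            f"e.g. {missing[:3]}"
        )
    return np.array([he_values[m] for m in lmap.table["marker_id"]], dtype=float)


def empirical_variogram(
    lmap: LinkageMap,
    he_values: Mapping[str, float] | pd.Series,
    max_lag: float = 10.0,
    lag_size: float = 0.15,
    estimator: str = "classical",
    by_lg: bool = False,
) -> pd.DataFrame:
    """Empirical variogram of He against map distance.

    Pairs are formed within LGs only.  With ``by_lg`` the result carries one
    variogram per LG (column ``lg``); otherwise all within-LG pairs are pooled
    into a single pangenomic variogram.  Bins with no pairs hold NaN; an
    entirely empty result triggers a warning.
    """
    z = _he_vector(lmap, he_values)
    n_bins = int(np.ceil(max_lag / lag_size))
    centers = (np.arange(n_bins) + 0.5) * lag_size
    ii, jj, bins, pair_lg = _pair_arrays(lmap, max_lag, lag_size)
    frames = []
    scopes = lmap.lg_ids if by_lg else [None]
    for scope in scopes:
        sel = slice(None) if scope is None else pair_lg == scope
        gamma, n_pairs = _gamma_from_pairs(
            z, ii[sel], jj[sel], bins[sel], n_bins, estimator
        )
        df = pd.DataFrame({"lag_cm": centers, "gamma": gamma, "n_pairs": n_pairs.astype(int)})
        if scope is not None:
            df.insert(0, "lg", scope)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if (out["n_pairs"] == 0).all():
        import warnings

        warnings.warn("no marker pairs in any distance bin")
    return out


def pangenomic_variogram(per_lg: pd.DataFrame, estimator: str = "classical") -> pd.DataFrame:
    """Pool per-LG variogram tables (from ``empirical_variogram(by_lg=True)``)
    into shared bins.  Pairs are never formed across LGs; pooling combines the
    within-LG pair sets.

    For the classical estimator the pooled gamma is the N(h)-weighted mean of
    per-LG gammas (exact, since both are pair averages of squared
    differences).  The robust estimator does not pool exactly from per-LG
    summaries; recompute it from the map instead (``empirical_variogram``
    without ``by_lg``).
    """
    if estimator != "classical":
        raise ValueError(
            "exact pooling from summaries is only defined for the classical "
            "estimator; recompute the robust variogram from the pooled pairs"
        )
    def agg(g: pd.DataFrame) -> pd.Series:
        n = g["n_pairs"].sum()
        gamma = np.nan if n == 0 else float(
            np.nansum(g["gamma"] * g["n_pairs"]) / n
        )
        return pd.Series({"gamma": gamma, "n_pairs": int(n)})

    out = per_lg.groupby("lag_cm", sort=True).apply(agg, include_groups=False).reset_index()
    out["n_pairs"] = out["n_pairs"].astype(int)
    return out


def permutation_envelope(
    lmap: LinkageMap,
    he_values: Mapping[str, float] | pd.Series,
    max_lag: float = 10.0,
    lag_size: float = 0.15,
    estimator: str = "classical",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation envelope and exceedance probabilities for the pangenomic
    variogram.

    He values are shuffled across mapped positions genome-wide (positions kept
    fixed), the variogram recomputed per permutation; the envelope is the
    (alpha/2, 1-alpha/2) percentile band per bin and ``p`` the fraction of
    permutations with gamma >= the observed value.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = _he_vector(lmap, he_values)
    n_bins = int(np.ceil(max_lag / lag_size))
    centers = (np.arange(n_bins) + 0.5) * lag_size
    ii, jj, bins, _ = _pair_arrays(lmap, max_lag, lag_size)
    obs, n_pairs = _gamma_from_pairs(z, ii, jj, bins, n_bins, estimator)
    perms = np.empty((n_perm, n_bins))
    for r in range(n_perm):
        zp = rng.permutation(z)
        perms[r], _ = _gamma_from_pairs(zp, ii, jj, bins, n_bins, estimator)
    has_pairs = n_pairs > 0
    lower = np.full(n_bins, np.nan)
    upper = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    lower[has_pairs] = np.percentile(perms[:, has_pairs], 100 * alpha / 2, axis=0)
    upper[has_pairs] = np.percentile(perms[:, has_pairs], 100 * (1 - alpha / 2), axis=0)
    p[has_pairs] = (perms[:, has_pairs] >= obs[None, has_pairs]).mean(axis=0)
    return pd.DataFrame(
        {
            "lag_cm": centers,
            "gamma": obs,
            "n_pairs": n_pairs.astype(int),
            "envelope_lower": lower,
            "envelope_upper": upper,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------------

class HeVariogram:
    """Variogram model of He along a linkage map (statsmodels-style)."""

    def __init__(
        self,
        lmap: LinkageMap,
        he_values: Mapping[str, float] | pd.Series,
        max_lag: float = 10.0,
        lag_size: float = 0.15,
        estimator: str = "classical",
    ):
        self.lmap = lmap
        self.he_values = he_values
        self.max_lag = max_lag
        self.lag_size = lag_size
        self.estimator = estimator

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int | np.random.Generator = 0,
    ) -> "VariogramResults":
        table = permutation_envelope(
            self.lmap, self.he_values, self.max_lag, self.lag_size,
            self.estimator, n_perm, alpha, seed,
        )
        per_lg = empirical_variogram(
            self.lmap, self.he_values, self.max_lag, self.lag_size,
            self.estimator, by_lg=True,
        )
        return VariogramResults(self, table, per_lg, n_perm, alpha)


@dataclass
class VariogramResults:
    model: HeVariogram
    table: pd.DataFrame  # pangenomic variogram with envelope and p
    per_lg: pd.DataFrame
    n_perm: int
    alpha: float

    @property
    def fraction_in_envelope(self) -> float:
        t = self.table[self.table["n_pairs"] > 0]
        inside = (t["gamma"] >= t["envelope_lower"]) & (
            t["gamma"] <= t["envelope_upper"]
        )
        return float(inside.mean())

    def summary(self) -> str:
        t = self.table[self.table["n_pairs"] > 0]
        return "\n".join(
            [
                f"He variogram ({self.model.estimator} estimator), "
                f"lag {self.model.lag_size} cM up to {self.model.max_lag} cM",
                f"  bins with pairs: {len(t)} / {len(self.table)}"
                f"    total pairs: {int(t['n_pairs'].sum())}",
                f"  permutations: {self.n_perm}"
                f"    fraction of bins inside {100 * (1 - self.alpha):.0f}% "
                f"envelope: {self.fraction_in_envelope:.3f}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        t = self.table
        ax.fill_between(t["lag_cm"], t["envelope_lower"], t["envelope_upper"],
                        alpha=0.3, color="tab:blue", label="permutation envelope")
        ax.plot(t["lag_cm"], t["gamma"], "r.-", lw=0.8, ms=4, label="empirical")
        ax.set_xlabel("map distance (cM)")
        ax.set_ylabel(r"$\hat\gamma(h)$")
        ax.legend(fontsize=7)
        return ax
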