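"""End-to-end orchestration: simulate -> qc -> diversity -> recomb ->
variogram -> ld -> concordance.

Each stage reads only the outputs of its predecessors from the output
directory and writes plain TSV/JSON, so any stage can be re-run in isolation
and reproduces byte-identical results under the same seed.  The run seed is
split into independent per-stage substreams, and a run record (config, seed,
package version, per-stage defaults) is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import map_concordance
from .diversity import (
    call_rate_filter,
    detect_duplicates,
    diversity_table,
    he_by_lg_comparison,
)
from .io import (
    LinkageMap,
    read_genotypes,
    read_map,
    write_genotypes,
    write_map,
    write_spots_bed,
)
from .landscape import MarkerDensityModel
from .ld import LDDecayModel, interchrom_test, ld_scan, long_distance_null
from .simulate import (
    ClusterSpec,
    GapSpec,
    SimulationConfig,
    inject_duplicates,
    jittered_component_maps,
    simulate_genotypes,
    simulate_map,
)
from .variogram import HeVariogram

log = logging.getLogger("ldscape.pipeline")

STAGES = ("simulate", "qc", "diversity", "recomb", "variogram", "ld", "concordance")


@dataclass
class PipelineConfig:
    """Full pipeline configuration with every stage default explicit."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_duplicate_pairs: int = 3
    n_component_maps: int = 3
    # qc
    min_call_rate: float = 0.80
    duplicate_threshold: float = 0.995
    duplicate_min_shared: int = 100
    # recomb
    recomb_n_rep: int = 999
    recomb_frac: float = 0.70
    recomb_grid_step: float = 0.1
    recomb_alpha: float = 0.05
    # variogram
    vario_max_lag: float = 10.0
    vario_lag_size: float = 0.15
    vario_estimator: str = "classical"
    vario_n_perm: int = 1000
    # ld
    ld_r2_min: float = 0.1
    ld_maf_min_null: float = 0.20
    ld_near_cutoff_cm: float = 1.0
    ld_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        clusters = {
            int(lg): [ClusterSpec(**c) for c in specs]
            for lg, specs in sim_raw.pop("clusters", {}).items()
        }
        gaps = {
            int(lg): [GapSpec(**g) for g in specs]
            for lg, specs in sim_raw.pop("gaps", {}).items()
        }
        sim = SimulationConfig(clusters=clusters, gaps=gaps, **sim_raw)
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, STAGES.index(stage)]))


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir: Path, cfg: PipelineConfig) -> None:
    rng = _stage_rng(cfg.seed, "simulate")
    lmap = simulate_map(cfg.simulation, rng)
    gm = simulate_genotypes(lmap, cfg.simulation, rng)
    gm = inject_duplicates(gm, cfg.n_duplicate_pairs, rng)
    comp = jittered_component_maps(lmap, cfg.n_component_maps, seed=rng)
    write_map(lmap, outdir / "map.tsv")
    write_genotypes(gm, outdir / "genotypes.tsv")
    for name, m in comp.items():
        write_map(m, outdir / f"map_{name}.tsv")
    log.info("simulate: %d markers, %d samples", lmap.n_markers, gm.n_samples)


def stage_qc(outdir: Path, cfg: PipelineConfig) -> None:
    gm = read_genotypes(outdir / "genotypes.tsv")
    qc, filtered = call_rate_filter(gm, cfg.min_call_rate)
    dups = detect_duplicates(
        filtered, cfg.duplicate_threshold, cfg.duplicate_min_shared
    )
    # mirror the mislabelled-tree treatment: drop both members of each pair
    drop = sorted({s for d in dups for s in (d.sample_a, d.sample_b)})
    filtered = filtered.drop_samples(drop)
    qc.call_rates.rename("call_rate").to_frame().assign(
        flagged=lambda df: df.index.isin(qc.flagged_samples)
    ).to_csv(outdir / "qc_samples.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        [dataclasses.asdict(d) for d in dups],
        columns=["sample_a", "sample_b", "identity", "n_shared"],
    ).to_csv(outdir / "qc_duplicates.tsv", sep="\t", index=False)
    write_genotypes(filtered, outdir / "genotypes_qc.tsv")
    log.info("qc: flagged %d low-call samples, %d duplicate pairs",
             len(qc.flagged_samples), len(dups))


def stage_diversity(outdir: Path, cfg: PipelineConfig) -> None:
    gm = read_genotypes(outdir / "genotypes_qc.tsv")
    lmap = read_map(outdir / "map.tsv")
    div = diversity_table(gm)
    div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    res = he_by_lg_comparison(div, lmap)
    (outdir / "he_by_lg.txt").write_text(res.summary() + "\n")
    log.info("diversity: mean He %.4f over %d markers",
             float(div["he"].mean()), len(div))


def stage_recomb(outdir: Path, cfg: PipelineConfig) -> None:
    lmap = read_map(outdir / "map.tsv")
    rng = _stage_rng(cfg.seed, "recomb")
    res = MarkerDensityModel(
        lmap,
        grid_step=cfg.recomb_grid_step,
        n_rep=cfg.recomb_n_rep,
        frac=cfg.recomb_frac,
        alpha=cfg.recomb_alpha,
    ).fit(rng)
    res.to_frame().to_csv(outdir / "landscape.tsv", sep="\t", index=False)
    write_spots_bed(res.spots, outdir / "spots.tsv")
    (outdir / "landscape_summary.txt").write_text(res.summary() + "\n")
    log.info("recomb: %d cold, %d hot spots", res.n_spots("cold"), res.n_spots("hot"))


def stage_variogram(outdir: Path, cfg: PipelineConfig) -> None:
    lmap = read_map(outdir / "map.tsv")
    div = pd.read_csv(outdir / "diversity.tsv", sep="\t")
    he = div.set_index("marker_id")["he"]
    shared = lmap.subset([m for m in lmap.table["marker_id"] if m in he.index])
    rng = _stage_rng(cfg.seed, "variogram")
    res = HeVariogram(
        shared, he, cfg.vario_max_lag, cfg.vario_lag_size, cfg.vario_estimator
    ).fit(n_perm=cfg.vario_n_perm, seed=rng)
    res.table.to_csv(outdir / "variogram.tsv", sep="\t", index=False)
    res.per_lg.to_csv(outdir / "variogram_per_lg.tsv", sep="\t", index=False)
    log.info("variogram: %.1f%% of bins inside envelope",
             100 * res.fraction_in_envelope)


def stage_ld(outdir: Path, cfg: PipelineConfig) -> None:
    gm = read_genotypes(outdir / "genotypes_qc.tsv")
    lmap = read_map(outdir / "map.tsv")
    comp = {
        p.stem.removeprefix("map_"): read_map(p)
        for p in sorted(outdir.glob("map_component*.tsv"))
    }
    pairs = ld_scan(gm, lmap)
    intra = pairs[pairs["lg_a"] == pairs["lg_b"]]
    intra.to_csv(outdir / "ld_intra.tsv", sep="\t", index=False)
    null = long_distance_null(
        pairs, comp or None, cfg.ld_r2_min, cfg.ld_maf_min_null,
        cfg.ld_near_cutoff_cm,
    )
    inter = pairs[pairs["lg_a"] != pairs["lg_b"]]
    report: dict = {"null_audit": null.audit}
    if len(null.values):
        test = interchrom_test(inter, null.values, cfg.ld_alpha)
        test.significant.to_csv(outdir / "ld_interchrom.tsv", sep="\t", index=False)
        report.update(
            interchrom_threshold=test.threshold,
            interchrom_unadjusted_bound=test.unadjusted_bound,
            interchrom_n_tests=test.n_tests,
            interchrom_significant=len(test.significant),
        )
    else:
        log.warning("ld: empty long-distance null; inter-chromosomal test skipped")
    # decay of mean r2 with genetic distance on the intra-chromosomal pairs
    ok = intra.dropna(subset=["dist_cm"])
    fit = LDDecayModel(ok["dist_cm"].to_numpy(), ok["r2"].to_numpy(), gm.n_samples).fit()
    report["decay"] = {
        "c_per_cm": fit.c_per_bp,  # distance unit here is cM
        "se": fit.bse,
        "rss": fit.rss,
        "converged": fit.converged,
        "negative": fit.negative,
        "n_pairs": len(ok),
        "n": fit.n,
    }
    _write_json(report, outdir / "ld_report.json")
    log.info("ld: %d pairs, null size %d", len(pairs), len(null.values))


def stage_concordance(outdir: Path, cfg: PipelineConfig) -> None:
    lmap = read_map(outdir / "map.tsv")
    frames = []
    for p in sorted(outdir.glob("map_component*.tsv")):
        res = map_concordance(lmap, read_map(p))
        df = res.per_lg.copy()
        df.insert(0, "component", p.stem.removeprefix("map_"))
        frames.append(df)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "concordance.tsv", sep="\t", index=False
        )
        log.info("concordance: %d component maps", len(frames))


_STAGE_FN = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "diversity": stage_diversity,
    "recomb": stage_recomb,
    "variogram": stage_variogram,
    "ld": stage_ld,
    "concordance": stage_concordance,
}


def run_stage(stage: str, outdir: str | Path, cfg: PipelineConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _STAGE_FN[stage](outdir, cfg)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage in order, writing all result tables plus a run record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "ldscape",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": list(STAGES),
    }
    _write_json(record, outdir / "run_record.json")
    for stage in STAGES:
        log.info("running stage %s", stage)
        _STAGE_FN[stage](outdir, cfg)
    return outdir
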