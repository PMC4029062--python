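"""Core domain types and file I/O for linkage maps, genotype matrices and result tables.

The two central containers are :class:`LinkageMap` (ordered marker positions in
centimorgans per linkage group) and :class:`GenotypeMatrix` (markers x individuals
matrix of unphased allele dosages 0/1/2 with a single missing sentinel).

Supported on-disk formats are plain TSV for maps and dosage matrices, VCF (GT
field only) for genotypes, and the GenePop text format for interoperability with
classical population-genetics software.  Spot calls are written as BED-like
intervals on the genetic (cM) axis, 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "LinkageMap",
    "GenotypeMatrix",
    "MISSING",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "write_genepop",
    "read_genepop",
    "write_spots_bed",
]

#: Sentinel for a missing dosage, uniform across all input formats.
MISSING: int = -1


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# LinkageMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageMap:
    """Ordered marker positions (cM) on K linkage groups.

    ``table`` has columns ``marker_id`` (unique), ``lg`` (positive int) and
    ``position_cm`` (float >= 0), sorted by (lg, position_cm).  Tied positions
    are allowed and preserved: co-segregating markers (e.g. SNPs from the same
    contig) legitimately sit 0 cM apart.  Positions are used as given; the
    length of a linkage group is the maximum position on it.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"marker_id", "lg", "position_cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise LoadError(f"map table lacks column(s): {sorted(missing)}")
        t = self.table
        dup = t["marker_id"][t["marker_id"].duplicated()]
        if len(dup):
            raise LoadError(f"duplicated marker_id(s): {sorted(set(dup))}")
        if (t["position_cm"] < 0).any():
            bad = t.loc[t["position_cm"] < 0, "marker_id"].tolist()
            raise LoadError(f"negative position for marker(s): {bad}")
        if (t["lg"] < 1).any() or not np.issubdtype(t["lg"].dtype, np.integer):
            raise LoadError("lg labels must be positive integers")
        k = int(t["lg"].max())
        present = set(t["lg"].unique())
        holes = set(range(1, k + 1)) - present
        if holes:
            warnings.warn(f"linkage group label(s) {sorted(holes)} absent from map")
        srt = t.sort_values(["lg", "position_cm"], kind="stable").reset_index(drop=True)
        if not srt[["marker_id"]].equals(t[["marker_id"]].reset_index(drop=True)):
            warnings.warn("map rows were not position-sorted; sorted on load")
        object.__setattr__(self, "table", srt)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, int, float]]
    ) -> "LinkageMap":
        df = pd.DataFrame(entries, columns=["marker_id", "lg", "position_cm"])
        df["lg"] = df["lg"].astype(np.int64)
        df["position_cm"] = df["position_cm"].astype(float)
        return cls(df)

    # -- accessors ---------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def lg_ids(self) -> list[int]:
        return sorted(self.table["lg"].unique().tolist())

    @property
    def lg_lengths(self) -> dict[int, float]:
        """Length of each LG in cM (maximum position on the LG)."""
        return self.table.groupby("lg")["position_cm"].max().to_dict()

    @property
    def total_length(self) -> float:
        return float(sum(self.lg_lengths.values()))

    def positions(self, lg: int) -> np.ndarray:
        return self.table.loc[self.table["lg"] == lg, "position_cm"].to_numpy()

    def markers_on(self, lg: int) -> list[str]:
        return self.table.loc[self.table["lg"] == lg, "marker_id"].tolist()

    def position_of(self) -> pd.Series:
        """marker_id -> position_cm Series."""
        return self.table.set_index("marker_id")["position_cm"]

    def lg_of(self) -> pd.Series:
        """marker_id -> lg Series."""
        return self.table.set_index("marker_id")["lg"]

    def subset(self, marker_ids: Iterable[str]) -> "LinkageMap":
        keep = set(marker_ids)
        return LinkageMap(self.table[self.table["marker_id"].isin(keep)].copy())

    def mean_spacing_cm(self) -> float:
        """Map length per marker (cM/marker), the map-density figure of merit."""
        return self.total_length / self.n_markers


def read_map(path: str | Path, dialect: str = "tsv") -> LinkageMap:
    """Read a linkage map from delimited text with a header row.

    Expected columns: ``marker_id``, ``lg``, ``position_cm``.  Rows that are
    out of position order are sorted (a warning notes the change); duplicate
    marker ids or non-numeric positions abort the load naming the offender.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise LoadError(f"unknown map dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype={"marker_id": str})
    required = {"marker_id", "lg", "position_cm"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing column(s) {sorted(missing)}")
    for col, kind in (("lg", np.int64), ("position_cm", float)):
        try:
            df[col] = df[col].astype(kind)
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            rows = bad.index.tolist()[:5]
            raise LoadError(f"{path}: non-numeric {col} at row(s) {rows}") from exc
    return LinkageMap(df)


def write_map(lmap: LinkageMap, path: str | Path) -> None:
    lmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Unphased biallelic dosage matrix, markers x individuals.

    ``dosage[i, j]`` is the ALT-allele count (0/1/2) of individual ``j`` at
    marker ``i``, or :data:`MISSING` (-1).  Half-called VCF genotypes (e.g.
    ``./1``) are conservatively treated as missing.
    """

    markers: list[str]
    samples: list[str]
    dosage: np.ndarray  # int8, shape (n_markers, n_samples)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.markers), len(self.samples)):
            raise LoadError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise LoadError(
                f"dosage {self.dosage[i, j]} outside {{0,1,2,missing}} at "
                f"marker {self.markers[i]!r}, sample {self.samples[j]!r}"
            )
        if len(set(self.markers)) != len(self.markers):
            raise LoadError("duplicated marker ids in genotype matrix")
        if len(set(self.samples)) != len(self.samples):
            raise LoadError("duplicated sample ids in genotype matrix")

    # -- basic views -------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def call_rate_per_sample(self) -> pd.Series:
        return pd.Series(self.called.mean(axis=0), index=self.samples, name="call_rate")

    def call_rate_per_marker(self) -> pd.Series:
        return pd.Series(self.called.mean(axis=1), index=self.markers, name="call_rate")

    def dosage_float(self) -> np.ndarray:
        """Float view with NaN at missing calls."""
        x = self.dosage.astype(float)
        x[~self.called] = np.nan
        return x

    # -- subsetting --------------------------------------------------------

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {m: i for i, m in enumerate(self.markers)}
        rows = [idx[m] for m in marker_ids]
        return GenotypeMatrix(list(marker_ids), list(self.samples), self.dosage[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: j for j, s in enumerate(self.samples)}
        cols = [idx[s] for s in sample_ids]
        return GenotypeMatrix(list(self.markers), list(sample_ids), self.dosage[:, cols])

    def drop_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.samples if s not in drop]
        return self.subset_samples(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.markers, columns=self.samples)


def _genotypes_from_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    x = df.to_numpy(dtype=float)
    out = np.full(x.shape, MISSING, dtype=np.int8)
    called = ~np.isnan(x)
    vals = x[called]
    if not np.isin(vals, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))
        raise LoadError(f"{path}: dosage value(s) {bad} outside {{0,1,2,NA}}")
    out[called] = vals.astype(np.int8)
    return GenotypeMatrix(
        [str(m) for m in df.index], [str(s) for s in df.columns], out
    )


def _genotypes_from_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[str] = []
    rows: list[np.ndarray] = []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise LoadError(
                f"{path}: record {rec.ID or rec.CHROM + ':' + str(rec.POS)} "
                f"is not biallelic (ALT={rec.ALT})"
            )
        name = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if any(a < 0 for a in alleles):
                continue  # any missing allele -> missing dosage
            row[j] = sum(int(a) for a in alleles)
        markers.append(name)
        rows.append(row)
    if not rows:
        raise LoadError(f"{path}: VCF contains no records")
    return GenotypeMatrix(markers, samples, np.vstack(rows))


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from a dosage TSV (markers x samples, NA missing) or a VCF.

    VCF dosage is the count of ALT alleles in the GT field; a genotype with any
    missing allele becomes a missing dosage.
    """
    if format == "tsv":
        return _genotypes_from_tsv(path)
    if format == "vcf":
        return _genotypes_from_vcf(path)
    raise LoadError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.to_dataframe().astype(object)
    df[gm.dosage == MISSING] = "NA"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def write_genepop(
    gm: GenotypeMatrix,
    path: str | Path,
    grouping: Mapping[str, str] | None = None,
    title: str = "ldscape export",
) -> None:
    """Write biallelic genotypes in GenePop format.

    The reference allele is coded 01, the alternate 02, missing as 0000; a
    dosage d thus becomes ``01``x(2-d) + ``02``xd.  ``grouping`` maps sample id
    to population label (one "Pop" block per label, insertion order); default
    is a single population.
    """
    pops: dict[str, list[str]] = {}
    for s in gm.samples:
        pops.setdefault(grouping[s] if grouping else "pop1", []).append(s)
    code = {MISSING: "0000", 0: "0101", 1: "0102", 2: "0202"}
    col = {s: j for j, s in enumerate(gm.samples)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for m in gm.markers:
            fh.write(m + "\n")
        for members in pops.values():
            fh.write("Pop\n")
            for s in members:
                geno = " ".join(code[int(d)] for d in gm.dosage[:, col[s]])
                fh.write(f"{s} , {geno}\n")


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Parse a GenePop file written by :func:`write_genepop` back to dosages.

    Dosage is the count of allele 02; 0000 is missing.  Handles one-locus-per-
    line headers and 4-digit diploid codes, which is what the writer emits.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise LoadError(f"{path}: truncated GenePop file")
    markers: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        markers.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    samples: list[str] = []
    cols: list[np.ndarray] = []
    for line in lines[i:]:
        if line.strip().lower() == "pop" or not line.strip():
            continue
        name, _, geno = line.partition(",")
        codes = geno.split()
        if len(codes) != len(markers):
            raise LoadError(f"{path}: sample {name.strip()!r} has {len(codes)} loci, "
                            f"expected {len(markers)}")
        col = np.empty(len(markers), dtype=np.int8)
        for k, c in enumerate(codes):
            if c == "0000":
                col[k] = MISSING
            else:
                a, b = c[:2], c[2:]
                col[k] = (a == "02") + (b == "02")
        samples.append(name.strip())
        cols.append(col)
    return GenotypeMatrix(markers, samples, np.column_stack(cols))


# ---------------------------------------------------------------------------
# Spot intervals (BED-like on the cM axis)
# ---------------------------------------------------------------------------

def write_spots_bed(spots: pd.DataFrame, path: str | Path) -> None:
    """Write hot/cold-spot calls as BED-like text: lg, start_cm, end_cm, type.

    Coordinates are genetic (cM), 0-based half-open.
    """
    spots[["lg", "start_cm", "end_cm", "type"]].to_csv(
        path, sep="\t", index=False
    )
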