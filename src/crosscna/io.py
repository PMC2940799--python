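"""Tabular formats: probe maps, aCGH cohorts, ortholog tables, region calls.

All genomic coordinates are 0-based half-open base pairs, in memory and in
every file this module reads or writes (BED output is therefore written
without any shift).

File formats
------------
aCGH data TSV      ``probe_id  chrom  mid_bp  <sample1>  <sample2> ...``
annotation TSV     ``sample_id  group  tumor_type``
ortholog TSV       ``pair_id  geneA_id  chromA  startA  endA  strandA
                   geneB_id  chromB  startB  endB  strandB``
region TSV         ``group  chrom  start  end  direction  peak_pos  peak_height``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import chrom_sort_key
from .regions import Region

log = logging.getLogger(__name__)

ORTHOLOG_COLUMNS = [
    "pair_id",
    "geneA_id", "chromA", "startA", "endA", "strandA",
    "geneB_id", "chromB", "startB", "endB", "strandB",
]

REGION_COLUMNS = ["group", "chrom", "start", "end", "direction", "peak_pos", "peak_height"]


@dataclass(frozen=True)
class ProbeMap:
    """Ordered probe midpositions for one genome.

    ``table`` has columns ``probe_id, chrom, mid_bp`` sorted by natural
    chromosome order, then position. Probe ids are unique; midpositions are
    strictly increasing within a chromosome.
    """

    table: pd.DataFrame
    chrom_lengths: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        df = self.table
        missing = {"probe_id", "chrom", "mid_bp"} - set(df.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe id {dup!r}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["mid_bp"] = df["mid_bp"].astype(np.int64)
        order = df["chrom"].map(chrom_sort_key)
        df = df.iloc[np.lexsort((df["mid_bp"].to_numpy(), order.to_numpy()))]
        df = df.reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["mid_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe midpositions not strictly increasing on chromosome {chrom}")
        object.__setattr__(self, "table", df)

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "mid_bp"].to_numpy()

    def probe_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def chrom_extent(self, chrom: str) -> int:
        """Chromosome length if known, else the last probe position."""
        if self.chrom_lengths is not None and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        return int(self.positions(chrom).max())


@dataclass
class ACGHGroup:
    """An aCGH cohort: samples x probes log2-ratio matrix plus annotations.

    ``values`` is indexed by sample id with one column per probe id, in the
    probe map's order. ``samples`` is indexed by sample id with ``group`` and
    ``tumor_type`` columns. Missing log2 ratios are NaN and are excluded from
    kernel sums and aberrant-fraction denominators downstream. ``events`` is
    an optional ground-truth table attached by the simulator.
    """

    probes: ProbeMap
    values: pd.DataFrame
    samples: pd.DataFrame
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        probe_ids = self.probes.table["probe_id"].tolist()
        if list(self.values.columns) != probe_ids:
            try:
                self.values = self.values[probe_ids]
            except KeyError as exc:
                raise ValueError("value matrix columns do not match probe map") from exc
        if self.values.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        if not self.values.index.equals(self.samples.index):
            try:
                self.samples = self.samples.loc[self.values.index]
            except KeyError:
                missing = set(self.values.index) - set(self.samples.index)
                raise ValueError(f"samples missing from annotations: {sorted(missing)[:5]}")

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, group: str) -> "ACGHGroup":
        """Samples whose ``group`` annotation equals *group*."""
        keep = self.samples.index[self.samples["group"] == group]
        if len(keep) == 0:
            raise ValueError(f"no samples in group {group!r}")
        events = None
        if self.events is not None:
            events = self.events[self.events["sample_id"].isin(keep)].reset_index(drop=True)
        return ACGHGroup(self.probes, self.values.loc[keep], self.samples.loc[keep], events)

    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))


@dataclass(frozen=True)
class OrthologTable:
    """Ortholog pairs between species A and species B, one row per pair.

    A gene id may appear in several rows (many-to-many homology); duplicate
    (geneA, geneB) pairs are collapsed at load time.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ORTHOLOG_COLUMNS))

    def __post_init__(self) -> None:
        df = self.table
        missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
        df = df[ORTHOLOG_COLUMNS].copy()
        for side in "AB":
            df[f"chrom{side}"] = df[f"chrom{side}"].astype(str)
            df[f"start{side}"] = df[f"start{side}"].astype(np.int64)
            df[f"end{side}"] = df[f"end{side}"].astype(np.int64)
            bad = df[f"start{side}"] >= df[f"end{side}"]
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"gene with start >= end in species {side} at row {row}")
            strands = set(df[f"strand{side}"].unique())
            unknown = strands - {"+", "-"}
            if unknown:
                raise ValueError(f"unknown strand symbol(s) {sorted(unknown)} in species {side}")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    def genes(self, side: str) -> pd.DataFrame:
        """Deduplicated gene table for species ``"A"`` or ``"B"``.

        Columns: ``gene_id, chrom, start, end, strand``.
        """
        if side not in ("A", "B"):
            raise ValueError("side must be 'A' or 'B'")
        cols = [f"gene{side}_id", f"chrom{side}", f"start{side}", f"end{side}", f"strand{side}"]
        out = self.table[cols].copy()
        out.columns = ["gene_id", "chrom", "start", "end", "strand"]
        return out.drop_duplicates("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# aCGH cohort I/O


def read_acgh(data_path: str | Path, annot_path: str | Path,
              chrom_lengths: Mapping[str, int] | None = None) -> ACGHGroup:
    """Load an aCGH data TSV plus its sample-annotation TSV.

    Probes are sorted by (natural chromosome order, midposition); cells that
    do not parse as numbers become NaN. Raises on duplicate probe ids and on
    samples present in the data but absent from the annotations.
    """
    raw = pd.read_csv(data_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "mid_bp"):
        if col not in raw.columns:
            raise ValueError(f"aCGH file missing column {col!r}")
    annot = pd.read_csv(annot_path, sep="\t", dtype=str)
    if "sample_id" not in annot.columns:
        raise ValueError("annotation file missing column 'sample_id'")
    annot = annot.set_index("sample_id")
    if "tumor_type" not in annot.columns:
        annot["tumor_type"] = "unknown"
    annot["tumor_type"] = annot["tumor_type"].fillna("unknown")

    sample_cols = [c for c in raw.columns if c not in ("probe_id", "chrom", "mid_bp")]
    unknown = [s for s in sample_cols if s not in annot.index]
    if unknown:
        raise ValueError(f"sample {unknown[0]!r} present in data but absent from annotations")

    probes = ProbeMap(raw[["probe_id", "chrom", "mid_bp"]], chrom_lengths=chrom_lengths)
    ratios = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    n_bad = int(ratios.isna().sum().sum())
    # realign to the sorted probe order
    ratios.index = raw["probe_id"]
    values = ratios.loc[probes.table["probe_id"]].T
    values.index.name = "sample_id"
    log.info("read_acgh: %d probes, %d samples, %d missing cells",
             probes.n_probes, len(sample_cols), n_bad)
    return ACGHGroup(probes, values, annot.loc[values.index, ["group", "tumor_type"]])


def write_acgh(group: ACGHGroup, data_path: str | Path, annot_path: str | Path,
               float_fmt: str = "%.6f") -> None:
    """Write a cohort as the data + annotation TSV pair read by :func:`read_acgh`."""
    out = group.probes.table.copy()
    mat = group.values.T  # probes x samples
    out = pd.concat([out.set_index(mat.index), mat], axis=1)
    out.to_csv(data_path, sep="\t", index=False, float_format=float_fmt)
    annot = group.samples.reset_index()
    annot.columns = ["sample_id", "group", "tumor_type"]
    annot.to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortholog table I/O


def read_orthologs(path: str | Path) -> OrthologTable:
    """Load an 11-column ortholog TSV; duplicate (geneA, geneB) pairs collapse."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "geneA_id": str, "geneB_id": str,
                                            "chromA": str, "chromB": str,
                                            "strandA": str, "strandB": str})
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ortholog file missing columns: {sorted(missing)}")
    n_dup = int(df.duplicated(["geneA_id", "geneB_id"]).sum())
    if n_dup:
        log.info("read_orthologs: collapsed %d duplicate pair rows", n_dup)
        df = df.drop_duplicates(["geneA_id", "geneB_id"])
    return OrthologTable(df.reset_index(drop=True))


def write_orthologs(table: OrthologTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region I/O


def write_regions(regions: Sequence[Region], path: str | Path, style: str = "tsv") -> None:
    """Serialize called regions as ``tsv`` (full columns) or ``bed``.

    BED output is 0-based half-open with the direction in the name field and
    the peak height in the score field.
    """
    path = Path(path)
    if style == "tsv":
        rows = [
            {"group": r.group, "chrom": r.chrom, "start": r.start, "end": r.end,
             "direction": r.direction, "peak_pos": r.peak_pos, "peak_height": r.peak_height}
            for r in regions
        ]
        pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)
    elif style == "bed":
        with open(path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{int(round(r.start))}\t{int(round(r.end))}"
                         f"\t{r.direction}\t{r.peak_height:.6g}\n")
    else:
        raise ValueError(f"unknown region style {style!r}")


def read_regions(path: str | Path) -> list[Region]:
    """Read back a region TSV written by :func:`write_regions`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "direction": str})
    out = []
    for row in df.itertuples(index=False):
        group = "" if pd.isna(row.group) else str(row.group)
        out.append(Region(chrom=str(row.chrom), start=float(row.start), end=float(row.end),
                          direction=str(row.direction), peak_pos=float(row.peak_pos),
                          peak_height=float(row.peak_height), group=group))
    return out
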