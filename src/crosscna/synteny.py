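"""Cross-species mapping of significant regions through ortholog pairs.

Given regions called independently in two species and a table of ortholog
pairs, the pipeline is: assign genes to the regions they overlap (any
overlap of >= 1 bp), retain ortholog pairs whose two genes sit in regions
of the same direction, then cluster retained pairs by their (species-A
region, species-B region) combination into syntenic overlaps. Overlap
bounds span the first gene's start to the last gene's end in each species;
a +-1 inversion flag records whether gene order is preserved (+1) or
reversed (-1) between the species, undefined (None) when a species
contributes a single gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import OrthologTable
from .regions import Region

log = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = ["gene_id", "region_id", "direction"]


@dataclass(frozen=True)
class SyntenicOverlap:
    """A paired two-species region with gene/pair counts and inversion flag."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    direction: str
    n_genes_a: int
    n_genes_b: int
    n_pairs: int
    inversion: int | None
    region_a_id: int
    region_b_id: int
    genes_a: tuple[str, ...] = ()
    genes_b: tuple[str, ...] = ()

    @property
    def singleton(self) -> bool:
        """True when only one ortholog pair supports the overlap (full
        tables keep these; abbreviated tables drop them)."""
        return self.n_pairs == 1


def genes_in_regions(genes: pd.DataFrame, regions: Sequence[Region]) -> pd.DataFrame:
    """Assign genes to every region their [start, end) overlaps by >= 1 bp.

    *genes* needs columns ``gene_id, chrom, start, end``. Returns one row
    per (gene, region) hit with the region's index and direction; a gene may
    hit several regions.
    """
    out = []
    chrom_arr = genes["chrom"].astype(str).to_numpy()
    start_arr = genes["start"].to_numpy()
    end_arr = genes["end"].to_numpy()
    ids = genes["gene_id"].to_numpy()
    for rid, region in enumerate(regions):
        hit = (chrom_arr == region.chrom) & (start_arr < region.end) & (region.start < end_arr)
        for gid in ids[hit]:
            out.append({"gene_id": gid, "region_id": rid, "direction": region.direction})
    return pd.DataFrame(out, columns=ASSIGNMENT_COLUMNS)


def conserved_pairs(orthologs: OrthologTable, assign_a: pd.DataFrame,
                    assign_b: pd.DataFrame) -> pd.DataFrame:
    """Ortholog pairs whose two genes sit in same-direction regions.

    Directions must match exactly (gain with gain, loss with loss; for
    differential regions, identical contrast labels). Returns the ortholog
    rows joined with both region ids and the shared direction; a pair
    landing in several region combinations yields one row per combination.
    """
    df = orthologs.table
    a = assign_a.rename(columns={"gene_id": "geneA_id", "region_id": "region_a_id"})
    b = assign_b.rename(columns={"gene_id": "geneB_id", "region_id": "region_b_id"})
    merged = df.merge(a, on="geneA_id").merge(b, on="geneB_id",
                                              suffixes=("_a", "_b"))
    merged = merged[merged["direction_a"] == merged["direction_b"]]
    merged = merged.rename(columns={"direction_a": "direction"}).drop(columns="direction_b")
    return merged.reset_index(drop=True)


def inversion_flag(pairs_in_overlap: pd.DataFrame) -> int | None:
    """Sign of the rank correlation between the species' gene-start orders.

    None when either species contributes a single gene; an exactly tied
    correlation returns +1 with a warning.
    """
    genes_a = pairs_in_overlap.drop_duplicates("geneA_id")
    genes_b = pairs_in_overlap.drop_duplicates("geneB_id")
    if len(genes_a) < 2 or len(genes_b) < 2:
        return None
    rho = stats.spearmanr(pairs_in_overlap["startA"], pairs_in_overlap["startB"]).statistic
    if not np.isfinite(rho) or rho == 0:
        warnings.warn("tied gene order between species; inversion flag set to +1",
                      stacklevel=2)
        return 1
    return 1 if rho > 0 else -1


def cluster_overlaps(pairs: pd.DataFrame) -> list[SyntenicOverlap]:
    """Group conserved pairs sharing one (region_A, region_B) combination.

    Bounds run from the minimum gene start to the maximum gene end in each
    species; counts cover distinct genes per species and distinct pairs.
    Singleton overlaps (one ortholog pair) are kept and flagged.
    """
    if len(pairs) == 0:
        return []
    out = []
    for (rid_a, rid_b), grp in pairs.groupby(["region_a_id", "region_b_id"], sort=True):
        grp = grp.drop_duplicates(["geneA_id", "geneB_id"])
        out.append(SyntenicOverlap(
            chrom_a=str(grp["chromA"].iloc[0]),
            start_a=int(grp["startA"].min()), end_a=int(grp["endA"].max()),
            chrom_b=str(grp["chromB"].iloc[0]),
            start_b=int(grp["startB"].min()), end_b=int(grp["endB"].max()),
            direction=str(grp["direction"].iloc[0]),
            n_genes_a=int(grp["geneA_id"].nunique()),
            n_genes_b=int(grp["geneB_id"].nunique()),
            n_pairs=len(grp),
            inversion=inversion_flag(grp),
            region_a_id=int(rid_a), region_b_id=int(rid_b),
            genes_a=tuple(dict.fromkeys(grp["geneA_id"])),
            genes_b=tuple(dict.fromkeys(grp["geneB_id"])),
        ))
    return out


def map_regions(orthologs: OrthologTable, regions_a: Sequence[Region],
                regions_b: Sequence[Region]) -> list[SyntenicOverlap]:
    """Full pipeline: gene assignment, direction-matched pairs, clustering."""
    assign_a = genes_in_regions(orthologs.genes("A"), regions_a)
    assign_b = genes_in_regions(orthologs.genes("B"), regions_b)
    return cluster_overlaps(conserved_pairs(orthologs, assign_a, assign_b))


def overlaps_to_frame(overlaps: Sequence[SyntenicOverlap],
                      include_singletons: bool = True) -> pd.DataFrame:
    """Tabular view of syntenic overlaps (abbreviated tables drop singletons)."""
    rows = []
    for ov in overlaps:
        if ov.singleton and not include_singletons:
            continue
        rows.append({
            "speciesA_region": f"{ov.chrom_a}:{ov.start_a}-{ov.end_a}",
            "speciesB_region": f"{ov.chrom_b}:{ov.start_b}-{ov.end_b}",
            "direction": ov.direction,
            "n_genes_A": ov.n_genes_a, "n_genes_B": ov.n_genes_b,
            "n_pairs": ov.n_pairs,
            "inversion": "NA" if ov.inversion is None else ov.inversion,
            "genes_A": ",".join(ov.genes_a), "genes_B": ",".join(ov.genes_b),
        })
    return pd.DataFrame(rows, columns=[
        "speciesA_region", "speciesB_region", "direction", "n_genes_A",
        "n_genes_B", "n_pairs", "inversion", "genes_A", "genes_B"])


def write_overlaps(overlaps: Sequence[SyntenicOverlap], path: str | Path,
                   include_singletons: bool = True) -> None:
    overlaps_to_frame(overlaps, include_singletons).to_csv(path, sep="\t", index=False)
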