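"""Candidate-gene annotation of selected scan regions.

Each selected SNP is mapped against a local gene-interval set: a SNP whose
position falls inside a gene is "within-gene"; otherwise the nearest gene
boundary on the chromosome within a flanking limit (default 2.0 Mb) gives
an upstream/downstream call with its distance; beyond the limit the SNP is
unannotated.  "Upstream" means the SNP lies before the gene start in
chromosome coordinates and "downstream" after the gene end -- a fixed
coordinate convention, strand is ignored.  Distance is SNP to the nearer
gene boundary; kb labels are truncated (not rounded) to two decimals.

Ties (two genes equally near) go to the gene with the smaller start
coordinate; a SNP inside several overlapping genes is likewise assigned
the smallest-start gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneIntervalSet
from .traits import TRAIT_NAMES

__all__ = ["annotate_regions", "summarize_candidates", "format_kb", "region_report"]

ANNOTATION_COLUMNS = [
    "trait",
    "chrom",
    "pos",
    "snp_id",
    "relation",
    "distance_bp",
    "gene",
    "gene_start",
    "gene_end",
    "pct_var",
]


def format_kb(distance_bp: int) -> str:
    """Distance in kb, truncated to 2 decimals (74,579 bp -> '74.57')."""
    return f"{math.floor(distance_bp / 10) / 100:.2f}"


def _annotate_one(pos: int, genes: pd.DataFrame, flank_bp: int):
    """(relation, distance, gene row or None) for one SNP position against
    the genes of its chromosome (sorted by start)."""
    if not len(genes):
        return "none", None, None
    inside = genes[(genes["start"] <= pos) & (pos <= genes["end"])]
    if len(inside):
        row = inside.sort_values(["start", "gene"]).iloc[0]
        return "within-gene", 0, row
    dist_start = genes["start"] - pos  # >0 when SNP is upstream of the gene
    dist_end = pos - genes["end"]  # >0 when SNP is downstream
    dist = np.maximum(dist_start, dist_end)
    order = np.lexsort((genes["start"].to_numpy(), dist.to_numpy()))
    best = order[0]
    d = int(dist.iloc[best])
    if d > flank_bp:
        return "none", None, None
    row = genes.iloc[best]
    relation = "upstream" if pos < row["start"] else "downstream"
    return relation, d, row


def annotate_regions(
    regions: pd.DataFrame,
    genes: GeneIntervalSet,
    flank_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Annotate a per-SNP region table (trait, chrom, pos, snp_id, pct_var).

    Caller is responsible for both inputs using the same assembly
    coordinates.  Returns one row per input SNP with relation
    {within-gene, upstream, downstream, none}, boundary distance (0 when
    within), gene symbol (empty when none) and the gene interval.
    """
    by_chrom = {
        str(c): g.sort_values("start").reset_index(drop=True)
        for c, g in genes.entries.groupby("chrom", sort=False)
    }
    rows = []
    for _, r in regions.iterrows():
        chrom_genes = by_chrom.get(str(r["chrom"]), pd.DataFrame(columns=genes.entries.columns))
        relation, dist, gene = _annotate_one(int(r["pos"]), chrom_genes, flank_bp)
        rows.append(
            {
                "trait": r["trait"],
                "chrom": r["chrom"],
                "pos": int(r["pos"]),
                "snp_id": r["snp_id"],
                "relation": relation,
                "distance_bp": 0 if relation == "within-gene" else dist,
                "gene": gene["gene"] if gene is not None else "",
                "gene_start": int(gene["start"]) if gene is not None else pd.NA,
                "gene_end": int(gene["end"]) if gene is not None else pd.NA,
                "pct_var": float(r["pct_var"]),
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def region_report(annotations: pd.DataFrame) -> pd.DataFrame:
    """Shape annotations into the seven-column candidate-region table
    (gene location printed as 'start-end' for within-gene hits and
    '<kb> kb upstream/downstream gene' for flanking hits)."""
    rows = []
    for _, r in annotations.iterrows():
        if r["relation"] == "within-gene":
            loc = f"{r['gene_start']:,}-{r['gene_end']:,}"
        elif r["relation"] in ("upstream", "downstream"):
            loc = f"{format_kb(int(r['distance_bp']))} kb {r['relation']} gene"
        else:
            loc = ""
        rows.append(
            {
                "trait": r["trait"],
                "chrom": r["chrom"],
                "snp_pos": r["pos"],
                "snp_id": r["snp_id"],
                "gene_location": loc,
                "candidate_gene": r["gene"],
                "pct_var": r["pct_var"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait",
            "chrom",
            "snp_pos",
            "snp_id",
            "gene_location",
            "candidate_gene",
            "pct_var",
        ],
    )


def summarize_candidates(
    annotations: pd.DataFrame, trait_order=TRAIT_NAMES
) -> pd.DataFrame:
    """Gene x trait overlap summary: one row per (chromosome, gene) with
    the traits whose selected regions hit it, in the canonical trait order;
    a gene hit by every trait is summarized as 'Six traits' when six traits
    are analyzed."""
    hits = annotations[annotations["gene"] != ""]
    if not len(hits):
        return pd.DataFrame(
            columns=["chrom", "gene", "gene_start", "gene_end", "traits"]
        )
    order = {t: i for i, t in enumerate(trait_order)}
    rows = []
    for (chrom, gene), grp in hits.groupby(["chrom", "gene"], sort=False):
        traits = sorted(set(grp["trait"]), key=lambda t: order.get(t, len(order)))
        if len(trait_order) == 6 and set(traits) == set(trait_order):
            label = "Six traits"
        else:
            label = ", ".join(traits)
        rows.append(
            {
                "chrom": chrom,
                "gene": gene,
                "gene_start": int(grp["gene_start"].iloc[0]),
                "gene_end": int(grp["gene_end"].iloc[0]),
                "traits": label,
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "gene_start"]).reset_index(drop=True)
    return out[["chrom", "gene", "gene_start", "gene_end", "traits"]]
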