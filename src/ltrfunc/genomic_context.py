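"""Genomic environment of functional vs silent LTRs.

Characterises each LTR against a gene annotation: intragenic/intergenic
status (>= 1 bp intersection with a gene on either strand), orientation
relative to the host gene, intron overlap (overlaps the gene but none of
its exons), nearest-gene distances split by direction and relative
orientation, and the gene-density ratio around promoter vs silent LTRs.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import annotation_frame, locus_intervals

__all__ = ["classify_context", "density_ratio", "DISTANCE_BINS"]

#: default distance-profile bin edges, bp
DISTANCE_BINS = [1_000, 2_000, 5_000, 10_000, 25_000, 50_000, 100_000]


def _gene_tables(gene_annotation: pd.DataFrame):
    genes = gene_annotation[gene_annotation["feature"] == "gene"].reset_index(drop=True)
    exons = gene_annotation[gene_annotation["feature"] == "exon"]
    for gid, sub in exons.groupby("gene_id"):
        parent = genes[genes["gene_id"] == gid]
        if parent.empty:
            raise ValueError(f"exon without parent gene {gid!r}")
        g = parent.iloc[0]
        if (sub["start"] < g["start"]).any() or (sub["end"] > g["end"]).any():
            raise ValueError(f"malformed gene model: exon outside gene {gid!r}")
    return genes, exons


def classify_context(ltrs: pd.DataFrame, gene_annotation: pd.DataFrame) -> pd.DataFrame:
    """Context record per LTR.

    ``ltrs``: frame with ``ltr_id chrom start end strand`` (see
    :func:`ltr_intervals`).  Returns one row per LTR with status,
    orientation vs the host gene (largest overlap wins when several genes
    contain the LTR), intron overlap, and the four nearest distances
    upstream/downstream x sense/antisense (np.inf at contig ends).
    """
    genes, exons = _gene_tables(gene_annotation)
    gene_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        gene_trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end), i) for i, r in sub.iterrows())
    for chrom, sub in exons.groupby("chrom"):
        exon_trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end), r.gene_id) for _, r in sub.iterrows())
    has_exons = not exons.empty
    genes_by_chrom = {c: s.sort_values("start") for c, s in genes.groupby("chrom")}

    rows = []
    for ltr in ltrs.itertuples(index=False):
        chrom, start, end, strand = ltr.chrom, int(ltr.start), int(ltr.end), ltr.strand
        hits = gene_trees.get(chrom, IntervalTree()).overlap(start, end)
        if hits:
            best = max(hits, key=lambda iv: min(iv.end, end) - max(iv.begin, start))
            host = genes.loc[best.data]
            orientation = "sense" if host["strand"] == strand else "antisense"
            if has_exons:
                exon_hits = exon_trees.get(chrom, IntervalTree()).overlap(start, end)
                in_exon = any(iv.data == host["gene_id"] for iv in exon_hits)
                intron = not in_exon
            else:
                intron = False
            status = "intragenic"
        else:
            status, orientation, intron = "intergenic", "NA", False

        dists = {f"{side}_{orient}": np.inf
                 for side in ("upstream", "downstream")
                 for orient in ("sense", "antisense")}
        for g in genes_by_chrom.get(chrom, pd.DataFrame()).itertuples(index=False):
            if g.end <= start:
                side, gap = "upstream", start - g.end
            elif g.start >= end:
                side, gap = "downstream", g.start - end
            else:
                continue  # overlapping gene has no flanking distance
            if strand == "-":  # sides are relative to LTR orientation
                side = "downstream" if side == "upstream" else "upstream"
            orient = "sense" if g.strand == strand else "antisense"
            key = f"{side}_{orient}"
            dists[key] = min(dists[key], gap)

        rows.append({"ltr_id": ltr.ltr_id, "status": status,
                     "orientation_vs_gene": orientation,
                     "intron_overlap": bool(intron), **dists})
    return pd.DataFrame(rows)


def ltr_intervals(annotation) -> pd.DataFrame:
    """LTR spans (hull of each LTR's probesets), keyed by (locus_id, role)."""
    df = locus_intervals(annotation_frame(annotation), by="ltr_id")
    return df


def density_ratio(ltrs: pd.DataFrame, gene_annotation: pd.DataFrame,
                  profiles: pd.DataFrame, window_bp: int = 100_000) -> dict:
    """Gene-density ratio of promoter vs silent LTR neighbourhoods.

    Density is the mean count of distinct genes overlapping a
    ``window_bp`` window centred on each LTR midpoint, over the LTRs whose
    cross-sample profile is constitutively "Pr" (resp. "Silent").
    """
    genes, _ = _gene_tables(gene_annotation)
    trees = {chrom: IntervalTree.from_tuples(
        (int(r.start), int(r.end), i) for i, r in sub.iterrows())
        for chrom, sub in genes.groupby("chrom")}

    cat = dict(zip(profiles["ltr_id"], profiles["category"]))
    half = window_bp // 2
    counts: dict[str, list[int]] = {"Pr": [], "Silent": []}
    for ltr in ltrs.itertuples(index=False):
        category = cat.get(ltr.ltr_id)
        if category not in counts:
            continue
        mid = (int(ltr.start) + int(ltr.end)) // 2
        lo, hi = max(mid - half, 0), mid + half
        hits = trees.get(ltr.chrom, IntervalTree()).overlap(lo, hi)
        counts[category].append(len({iv.data for iv in hits}))
    if not counts["Pr"] or not counts["Silent"]:
        raise ValueError("need at least one constitutive promoter and one "
                         "constitutive silent LTR")
    mean_pr = float(np.mean(counts["Pr"]))
    mean_silent = float(np.mean(counts["Silent"]))
    return {
        "mean_genes_promoter": mean_pr,
        "mean_genes_silent": mean_silent,
        "ratio": mean_pr / mean_silent if mean_silent else np.inf,
        "n_promoter_ltrs": len(counts["Pr"]),
        "n_silent_ltrs": len(counts["Silent"]),
    }
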