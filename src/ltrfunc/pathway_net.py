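"""Integration of HERV/MaLR loci into gene pathways by co-expression.

Upstream pathway-activation calls (an external tool's output, consumed as a
table) name the significantly activated/inhibited pathways.  Genes
belonging to exactly one significant pathway anchor the analysis; every
expressed HERV/MaLR probeset is correlated (Pearson, log2 scale, all
samples pooled) with those genes, probeset hits are collapsed to locus
level by maximum correlation, and edges at r >= 0.8 build a bipartite
locus <-> pathway network through the genes.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .annotation_io import annotation_frame, locus_intervals

__all__ = ["select_exclusive_genes", "correlate_herv_genes", "build_network",
           "proximity_annotate"]


def select_exclusive_genes(pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Genes appearing in exactly one *significant* pathway.

    ``pathway_table`` columns: gene_symbol, pathway_id, pathway_significant
    (bool), optional z_score.  Returns gene_symbol -> pathway_id rows.
    """
    required = {"gene_symbol", "pathway_id", "pathway_significant"}
    missing = required - set(pathway_table.columns)
    if missing:
        raise ValueError(f"pathway table missing column(s) {sorted(missing)}")
    dup = pathway_table.duplicated(["gene_symbol", "pathway_id"])
    if dup.any():
        raise ValueError("duplicate (gene, pathway) pairs in pathway table")
    sig = pathway_table[pathway_table["pathway_significant"].astype(bool)]
    counts = sig.groupby("gene_symbol")["pathway_id"].nunique()
    exclusive = counts[counts == 1].index
    out = (sig[sig["gene_symbol"].isin(exclusive)]
           [["gene_symbol", "pathway_id"]].drop_duplicates())
    return out.reset_index(drop=True)


def correlate_herv_genes(matrix: pd.DataFrame, herv_probesets,
                         gene_probesets: pd.DataFrame, annotation,
                         r_min: float = 0.8) -> pd.DataFrame:
    """Locus-level HERV-gene co-expression edges at ``r >= r_min``.

    ``gene_probesets`` maps probeset_id -> gene_symbol (DataFrame with those
    columns); ``herv_probesets`` is an iterable of expressed retroelement
    probeset ids.  Pearson correlation is computed across all samples;
    probeset-level hits collapse to one edge per (locus, gene) keeping the
    maximum correlation.  Constant profiles are skipped with a warning.
    """
    ann = annotation_frame(annotation).set_index("probeset_id")
    herv_ids = [p for p in herv_probesets if p in matrix.index]
    gene_ids = [p for p in gene_probesets["probeset_id"] if p in matrix.index]
    if not herv_ids or not gene_ids:
        return pd.DataFrame(columns=["herv_locus_id", "gene_symbol", "correlation"])

    h = matrix.loc[herv_ids].to_numpy(dtype=float)
    g = matrix.loc[gene_ids].to_numpy(dtype=float)
    h_sd = h.std(axis=1)
    g_sd = g.std(axis=1)
    if (h_sd == 0).any() or (g_sd == 0).any():
        warnings.warn(f"skipping {int((h_sd == 0).sum() + (g_sd == 0).sum())} "
                      "constant profile(s) with undefined correlation",
                      stacklevel=2)
    hc = (h - h.mean(axis=1, keepdims=True))
    gc = (g - g.mean(axis=1, keepdims=True))
    n = matrix.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (hc @ gc.T) / n / np.outer(h.std(axis=1), g.std(axis=1))
    r[~np.isfinite(r)] = np.nan

    gene_of = dict(zip(gene_probesets["probeset_id"], gene_probesets["gene_symbol"]))
    rows = []
    hi, gi = np.where(r >= r_min)
    for i, j in zip(hi, gi):
        pid = herv_ids[i]
        rows.append({
            "herv_locus_id": ann.loc[pid, "locus_id"],
            "herv_probeset_id": pid,
            "gene_symbol": gene_of[gene_ids[j]],
            "correlation": float(r[i, j]),
        })
    if not rows:
        return pd.DataFrame(columns=["herv_locus_id", "gene_symbol", "correlation"])
    edges = pd.DataFrame(rows)
    # locus-level collapse: keep the best probeset per (locus, gene)
    edges = (edges.sort_values("correlation", ascending=False, kind="mergesort")
             .drop_duplicates(["herv_locus_id", "gene_symbol"])
             .reset_index(drop=True))
    return edges[["herv_locus_id", "gene_symbol", "correlation"]]


def build_network(edges: pd.DataFrame, exclusive_genes: pd.DataFrame,
                  annotation=None):
    """Bipartite locus <-> pathway network via the exclusive genes.

    Returns ``(graph, membership, summary)``: a networkx graph whose locus
    and pathway nodes carry ``bipartite`` attributes, a per-locus
    pathway-count table (with exclusive/shared split), and totals per
    repertoire that sum to the overall locus count.
    """
    pathway_of = dict(zip(exclusive_genes["gene_symbol"], exclusive_genes["pathway_id"]))
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        pathway = pathway_of.get(row.gene_symbol)
        if pathway is None:
            continue
        g.add_node(row.herv_locus_id, bipartite="locus")
        g.add_node(pathway, bipartite="pathway")
        if g.has_edge(row.herv_locus_id, pathway):
            g[row.herv_locus_id][pathway]["genes"].add(row.gene_symbol)
        else:
            g.add_edge(row.herv_locus_id, pathway, genes={row.gene_symbol})

    loci = [n for n, d in g.nodes(data=True) if d["bipartite"] == "locus"]
    membership = pd.DataFrame({
        "herv_locus_id": loci,
        "n_pathways": [g.degree(n) for n in loci],
    }).sort_values("herv_locus_id", kind="mergesort").reset_index(drop=True)
    membership["exclusive"] = membership["n_pathways"] == 1

    summary = {
        "n_loci": len(loci),
        "n_pathways": sum(1 for _, d in g.nodes(data=True) if d["bipartite"] == "pathway"),
        "n_exclusive": int(membership["exclusive"].sum()),
        "n_shared": int((~membership["exclusive"]).sum()),
    }
    if annotation is not None:
        ann = annotation_frame(annotation)
        rep_of = dict(zip(ann["locus_id"], ann["repertoire"]))
        reps = pd.Series([rep_of.get(l, "unknown") for l in loci])
        summary["per_repertoire"] = reps.value_counts().to_dict()
    return g, membership, summary


def proximity_annotate(edges: pd.DataFrame, annotation,
                       gene_annotation: pd.DataFrame,
                       max_dist: int = 40_000) -> pd.DataFrame:
    """Flag edges whose HERV locus lies within ``max_dist`` bp of any gene.

    Distance is the minimal gap between the locus interval (hull of its
    probesets) and any gene interval on the same chromosome (0 when
    overlapping, inclusive <= max_dist, infinite across chromosomes).
    """
    from intervaltree import IntervalTree

    loci = locus_intervals(annotation).set_index("locus_id")
    genes = gene_annotation[gene_annotation["feature"] == "gene"]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        ivs = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        by_chrom[chrom] = sorted(ivs)
        trees[chrom] = IntervalTree.from_tuples(ivs)

    out = edges.copy()
    dists = []
    for locus in out["herv_locus_id"]:
        if locus not in loci.index:
            raise ValueError(f"locus {locus!r} absent from annotation")
        row = loci.loc[locus]
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        if chrom not in trees:
            dists.append(np.inf)
            continue
        if trees[chrom].overlap(start, end):
            dists.append(0)
            continue
        best = np.inf
        for gs, ge in by_chrom[chrom]:
            gap = gs - end if gs >= end else start - ge
            best = min(best, max(gap, 0))
        dists.append(best)
    out["gene_distance_bp"] = dists
    out["near_gene"] = [d <= max_dist for d in out["gene_distance_bp"]]
    return out
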