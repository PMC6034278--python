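"""End-to-end pipeline orchestration with a single config and seed.

Stages run in order simulate? -> call -> ltr-function -> de -> phenotype ->
network -> context.  Every output is a TSV (network additionally GraphML,
dendrogram additionally Newick), the run report embeds the exact config,
and a manifest records a sha256 checksum per output so two runs with the
same config and seed can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_io as aio
from . import diffexpr, expression_call, genomic_context, ltr_function, pathway_net
from .synthetic_chip import SimParams, generate_annotation, generate_design, generate_intensities

log = logging.getLogger("ltrfunc")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All paths and stage parameters of one pipeline run."""

    outdir: str = "ltrfunc_out"
    seed: int = 0
    demo: bool = True
    annotation_path: str | None = None
    matrix_path: str | None = None
    sheet_path: str | None = None
    gene_annotation_path: str | None = None
    pathway_table_path: str | None = None
    sim: SimParams = field(default_factory=SimParams)
    call: expression_call.CallConfig = field(default_factory=expression_call.CallConfig)
    function: ltr_function.FunctionConfig = field(default_factory=ltr_function.FunctionConfig)
    de: diffexpr.DeConfig = field(default_factory=diffexpr.DeConfig)
    r_min: float = 0.8
    max_gene_dist: int = 40_000

    def __post_init__(self) -> None:
        if not self.demo:
            for name in ("annotation_path", "matrix_path", "sheet_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} is required when demo is off")
                if not Path(path).exists():
                    raise ValueError(f"{name}: no such file {path!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimParams(**kwargs["sim"])
        if "call" in kwargs:
            kwargs["call"] = expression_call.CallConfig(**kwargs["call"])
        if "function" in kwargs:
            kwargs["function"] = ltr_function.FunctionConfig(**kwargs["function"])
        if "de" in kwargs:
            kwargs["de"] = diffexpr.DeConfig(**kwargs["de"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"config": config.to_dict(), "stages": {}}
    outputs: list[Path] = []

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        return time.time()

    def done(name, t, **info):
        report["stages"][name].update(seconds=round(time.time() - t, 3), **info)

    # --- inputs -----------------------------------------------------------
    if config.demo:
        t = stage("simulate")
        params = dataclasses.replace(config.sim, seed=config.seed)
        records, truth, sheet, matrix = (None,) * 4
        records, truth = generate_annotation(params)
        sheet = generate_design(5, ("NS", "LPS", "ET"), 3)
        matrix = generate_intensities(records, truth, sheet, params)
        annotation = aio.annotation_frame(records)
        aio.write_annotation(records, out / "annotation.tsv")
        aio.write_sample_sheet(sheet, out / "sample_sheet.tsv")
        aio.write_matrix(matrix, out / "matrix.tsv")
        truth.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
        truth.ltrs.to_csv(out / "truth_ltrs.tsv", sep="\t", index=False)
        outputs += [out / "annotation.tsv", out / "sample_sheet.tsv",
                    out / "matrix.tsv", out / "truth_loci.tsv", out / "truth_ltrs.tsv"]
        done("simulate", t, n_probesets=len(annotation), n_samples=len(sheet))
    else:
        t = stage("load")
        records = aio.read_annotation(config.annotation_path)
        annotation = aio.annotation_frame(records)
        sheet = aio.read_sample_sheet(config.sheet_path)
        matrix = aio.read_matrix(config.matrix_path, sheet)
        truth = None
        done("load", t, n_probesets=len(annotation), n_samples=len(sheet))

    # --- expression calling ----------------------------------------------
    t = stage("call")
    threshold = expression_call.calibrate_threshold(matrix, annotation, sheet, config.call)
    calls = expression_call.call_active(matrix, config.call)
    summary = expression_call.summarize_transcriptome(calls, annotation)
    structure = expression_call.structure_distribution(calls, annotation)
    calls.table.to_csv(out / "activity_calls.tsv", sep="\t")
    summary.to_csv(out / "transcriptome_summary.tsv", sep="\t", index=False)
    structure.to_csv(out / "structure_distribution.tsv", sep="\t")
    outputs += [out / "activity_calls.tsv", out / "transcriptome_summary.tsv",
                out / "structure_distribution.tsv"]
    done("call", t, calibrated_threshold_log2=threshold,
         n_active=int(calls.table["active"].sum()))

    # --- LTR function ----------------------------------------------------
    t = stage("ltr-function")
    fn_calls, tally = ltr_function.call_all_functions(matrix, annotation, sheet, config.function)
    profiles, combos = ltr_function.profile_functions(fn_calls)
    det = ltr_function.determinism_summary(profiles)
    fn_out = fn_calls.copy()
    fn_out["ltr_id"] = ["|".join(t_) for t_ in fn_out["ltr_id"]]
    fn_out.to_csv(out / "ltr_function_calls.tsv", sep="\t", index=False)
    prof_out = profiles.copy()
    prof_out["ltr_id"] = ["|".join(t_) for t_ in prof_out["ltr_id"]]
    prof_out["functions_observed"] = [
        ",".join(sorted(fs)) for fs in prof_out["functions_observed"]]
    prof_out.to_csv(out / "ltr_profiles.tsv", sep="\t", index=False)
    combos.to_csv(out / "ltr_combinations.tsv", sep="\t", index=False)
    outputs += [out / "ltr_function_calls.tsv", out / "ltr_profiles.tsv",
                out / "ltr_combinations.tsv"]
    done("ltr-function", t, n_ltrs=int(profiles.shape[0]),
         n_excluded=det["n_excluded"],
         constitutive_fraction=det["constitutive_fraction"],
         pr_pa_switch_fraction=det["pr_pa_switch_fraction"])

    # --- differential expression + phenotype ------------------------------
    t = stage("de")
    de_lps = diffexpr.moderated_t(matrix, sheet, ("LPS", "NS"), config.de)
    de_et = diffexpr.moderated_t(matrix, sheet, ("ET", "LPS"), config.de)
    del_lps = diffexpr.aggregate_loci(de_lps, annotation, config.de)
    del_et = diffexpr.aggregate_loci(de_et, annotation, config.de)
    de_lps.to_csv(out / "de_LPS_vs_NS.tsv", sep="\t")
    de_et.to_csv(out / "de_ET_vs_LPS.tsv", sep="\t")
    del_lps["table"].to_csv(out / "del_LPS_vs_NS.tsv", sep="\t", index=False)
    del_et["table"].to_csv(out / "del_ET_vs_LPS.tsv", sep="\t", index=False)
    outputs += [out / "de_LPS_vs_NS.tsv", out / "de_ET_vs_LPS.tsv",
                out / "del_LPS_vs_NS.tsv", out / "del_ET_vs_LPS.tsv"]
    done("de", t, n_del_lps=del_lps["n_del"], n_deg_lps=del_lps["n_deg"],
         n_del_et=del_et["n_del"], n_deg_et=del_et["n_deg"])

    t = stage("phenotype")
    pheno, pheno_locus = diffexpr.classify_phenotype(de_lps, de_et, annotation, config.de)
    pheno.to_csv(out / "phenotype_probesets.tsv", sep="\t")
    pheno_locus.to_csv(out / "phenotype_loci.tsv", sep="\t", index=False)
    outputs += [out / "phenotype_probesets.tsv", out / "phenotype_loci.tsv"]
    done("phenotype", t,
         **pheno["phenotype"].value_counts().to_dict())

    t = stage("cluster")
    clust = diffexpr.top_variance_cluster(matrix, config.de)
    newick = diffexpr.linkage_to_newick(clust["linkage"], clust["samples"])
    (out / "dendrogram.nwk").write_text(newick + "\n")
    clust["ordered_matrix"].to_csv(out / "heatmap_matrix.tsv", sep="\t")
    outputs += [out / "dendrogram.nwk", out / "heatmap_matrix.tsv"]
    done("cluster", t, n_selected=clust["selected"].shape[0])

    # --- pathway network --------------------------------------------------
    t = stage("network")
    if config.pathway_table_path:
        ptable = pd.read_csv(config.pathway_table_path, sep="\t")
    else:
        # demo mode: derive a pathway table from the DE gene phenotypes so
        # the stage always has input — each phenotype class forms a pathway
        gene_ps = annotation[annotation["repertoire"] == "gene"]
        gp = pheno.loc[pheno.index.intersection(gene_ps["probeset_id"])]
        locus_of = dict(zip(gene_ps["probeset_id"], gene_ps["locus_id"]))
        rows = [{"gene_symbol": locus_of[p], "pathway_id": f"pw_{c}",
                 "pathway_significant": True}
                for p, c in gp["phenotype"].items() if c != "unclassified"]
        ptable = pd.DataFrame(rows).drop_duplicates() if rows else pd.DataFrame(
            columns=["gene_symbol", "pathway_id", "pathway_significant"])
    exclusive = pathway_net.select_exclusive_genes(ptable) if len(ptable) else \
        pd.DataFrame(columns=["gene_symbol", "pathway_id"])
    gene_ps = annotation[annotation["repertoire"] == "gene"]
    gene_probesets = pd.DataFrame({
        "probeset_id": gene_ps["probeset_id"],
        "gene_symbol": gene_ps["locus_id"],
    })
    gene_probesets = gene_probesets[
        gene_probesets["gene_symbol"].isin(exclusive["gene_symbol"])]
    herv_active = calls.table.index[
        calls.table["active"]
        & calls.table.index.isin(
            annotation.loc[annotation["repertoire"] != "gene", "probeset_id"])]
    edges = pathway_net.correlate_herv_genes(
        matrix, herv_active, gene_probesets, annotation, r_min=config.r_min)
    graph, membership, net_summary = pathway_net.build_network(
        edges, exclusive, annotation)
    if len(edges):
        edges_flagged = pathway_net.proximity_annotate(
            edges, annotation,
            _genes_as_annotation(annotation), max_dist=config.max_gene_dist)
    else:
        edges_flagged = edges.assign(gene_distance_bp=[], near_gene=[])
    edges_flagged.to_csv(out / "herv_gene_edges.tsv", sep="\t", index=False)
    membership.to_csv(out / "locus_pathway_membership.tsv", sep="\t", index=False)
    import networkx as nx
    for _, _, d in graph.edges(data=True):
        d["genes"] = ",".join(sorted(d["genes"]))
    nx.write_graphml(graph, out / "network.graphml")
    outputs += [out / "herv_gene_edges.tsv", out / "locus_pathway_membership.tsv",
                out / "network.graphml"]
    done("network", t, **{k: v for k, v in net_summary.items() if k != "per_repertoire"})

    # --- genomic context --------------------------------------------------
    t = stage("context")
    if config.gene_annotation_path:
        gene_ann = aio.read_gene_annotation(config.gene_annotation_path)
    else:
        gene_ann = _genes_as_annotation(annotation)
    ltr_iv = genomic_context.ltr_intervals(annotation)
    ltr_iv = ltr_iv[ltr_iv["repertoire"] == "HERV_prototypes"]
    context = genomic_context.classify_context(ltr_iv, gene_ann)
    ctx_out = context.copy()
    ctx_out["ltr_id"] = ["|".join(t_) for t_ in ctx_out["ltr_id"]]
    ctx_out.to_csv(out / "genomic_context.tsv", sep="\t", index=False)
    outputs.append(out / "genomic_context.tsv")
    done("context", t, n_intragenic=int((context["status"] == "intragenic").sum()),
         n_intergenic=int((context["status"] == "intergenic").sum()))

    # --- manifest ---------------------------------------------------------
    manifest = {p.name: _sha256(p) for p in outputs}
    report["manifest"] = manifest
    report["total_seconds"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _genes_as_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene probesets of the chip rendered as a gene-annotation frame."""
    gene_ps = annotation[annotation["repertoire"] == "gene"]
    if gene_ps.empty:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                     "strand", "feature"])
    loci = gene_ps.groupby("locus_id").agg(
        chrom=("chrom", "first"), start=("start", "min"),
        end=("end", "max"), strand=("strand", "first")).reset_index()
    return pd.DataFrame({
        "gene_id": loci["locus_id"], "chrom": loci["chrom"],
        "start": loci["start"], "end": loci["end"],
        "strand": loci["strand"], "feature": "gene"})
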