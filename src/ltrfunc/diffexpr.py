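"""Moderated-t differential expression and endotoxin-tolerance phenotyping.

The contrast model is the classical two-group comparison with an
empirical-Bayes variance squeeze: per probeset the pooled residual variance
s^2 (d residual degrees of freedom) is shrunk towards a chip-wide prior
s0^2 with d0 prior degrees of freedom,

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d),
    t_mod    = log2FC / (s_post * sqrt(1/nA + 1/nB)),  df = d + d0.

(d0, s0^2) are fitted by moment matching on log s^2: under the scaled-F
sampling model, e = log s^2 - digamma(d/2) + log(d/2) has
var(e) = trigamma(d/2) + trigamma(d0/2) and
E[e] = log s0^2 - digamma(d0/2) + log(d0/2), so d0 follows from inverting
the trigamma function (Newton iteration) and s0^2 from the mean.  When the
observed var(e) does not exceed trigamma(d/2) the prior is effectively
infinitely informative: d0 = inf and every probeset uses s0^2.

Significance uses Benjamini-Hochberg adjusted p-values with the strict
cutoffs adj-p < 0.05 and |log2FC| > 1.  Probesets are then classified
against the endotoxin-tolerance design from the two contrasts LPS vs NS and
ET vs LPS: tolerisable (up after LPS, down again after priming),
non-tolerisable (up after LPS, not down after priming) or down-modulated
(down after LPS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy

from .annotation_io import LtrRole, annotation_frame, validate_sample_sheet

__all__ = ["DeConfig", "moderated_t", "bh_adjust", "call_de", "aggregate_loci",
           "classify_phenotype", "top_variance_cluster", "linkage_to_newick",
           "ddct", "trigamma_inverse", "fit_variance_prior"]


@dataclass
class DeConfig:
    alpha: float = 0.05
    lfc_min: float = 1.0
    top_variance_fraction: float = 0.01
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.linkage not in ("complete", "average"):
            raise ValueError("linkage must be 'complete' or 'average'")
        if not 0 < self.top_variance_fraction <= 1:
            raise ValueError("top_variance_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# empirical-Bayes machinery
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x for tiny x
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y  # asymptotic trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0^2) on the log-variance distribution.

    Rows with zero variance carry no information about the prior scale and
    are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        return np.inf, 0.0
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if pos.size > 1 else 0.0
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def moderated_t(matrix: pd.DataFrame, sheet: pd.DataFrame,
                contrast: tuple[str, str],
                config: DeConfig | None = None) -> pd.DataFrame:
    """Per-probeset moderated t for ``contrast = (test, reference)``.

    log2FC = mean(test) - mean(reference).  Returns a DataFrame indexed by
    probeset with columns ``log2fc s2 s2_post t_mod df_total p adj_p
    significant direction``.
    """
    config = config or DeConfig()
    sheet = validate_sample_sheet(sheet)
    test, ref = contrast
    cols_a = sheet.loc[sheet["condition"] == test, "sample_id"].tolist()
    cols_b = sheet.loc[sheet["condition"] == ref, "sample_id"].tolist()
    for name, cols in ((test, cols_a), (ref, cols_b)):
        if len(cols) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 samples")
        missing = set(cols) - set(matrix.columns)
        if missing:
            raise ValueError(f"matrix lacks sample(s) {sorted(missing)[:3]}")

    a = matrix[cols_a].to_numpy(dtype=float)
    b = matrix[cols_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    d = na + nb - 2
    rss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = rss / d

    d0, s0 = fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0),
                     np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total if np.isfinite(df_total) else np.inf)
    adj = bh_adjust(p)

    out = pd.DataFrame({
        "log2fc": lfc, "s2": s2, "s2_post": s2_post, "t_mod": t,
        "df_total": df_total, "p": p, "adj_p": adj,
    }, index=matrix.index)
    out["significant"] = (out["adj_p"] < config.alpha) & (out["log2fc"].abs() > config.lfc_min)
    out["direction"] = np.where(~out["significant"], "ns",
                                np.where(out["log2fc"] > 0, "up", "down"))
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def call_de(results: pd.DataFrame, config: DeConfig | None = None):
    """Filter DE results at the strict cutoffs; returns (subset, counts)."""
    config = config or DeConfig()
    sig = results[(results["adj_p"] < config.alpha)
                  & (results["log2fc"].abs() > config.lfc_min)].copy()
    sig["direction"] = np.where(sig["log2fc"] > 0, "up", "down")
    counts = {"n_up": int((sig["direction"] == "up").sum()),
              "n_down": int((sig["direction"] == "down").sum())}
    return sig, counts


def aggregate_loci(de_results: pd.DataFrame, annotation,
                   config: DeConfig | None = None) -> dict:
    """Collapse significant probesets to distinct loci (DELs / DEGs).

    Returns a dict with the locus table and the partition bookkeeping: DEL
    counts per repertoire (summing to the total), solo-LTR vs proviral
    share, and per-chromosome tallies.
    """
    config = config or DeConfig()
    ann = annotation_frame(annotation).set_index("probeset_id")
    sig = de_results[de_results["significant"]] if "significant" in de_results else de_results
    missing = sig.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"unannotated probeset(s): {list(missing[:3])}")
    hit = ann.loc[sig.index].copy()
    hit["direction"] = sig["direction"]

    rows = []
    for locus, sub in hit.groupby("locus_id"):
        solo_only = (sub["ltr_role"] == LtrRole.SOLO.value).all() and \
            (sub["ltr_role"] != LtrRole.NONE.value).any()
        rows.append({
            "locus_id": locus,
            "repertoire": sub["repertoire"].iloc[0],
            "group": sub["group"].iloc[0],
            "chrom": sub["chrom"].iloc[0],
            "n_probesets": len(sub),
            "structure": "solo_LTR" if solo_only else "proviral_or_internal",
            "direction": "mixed" if sub["direction"].nunique() > 1
                         else sub["direction"].iloc[0],
        })
    table = pd.DataFrame(rows, columns=["locus_id", "repertoire", "group", "chrom",
                                        "n_probesets", "structure", "direction"])
    retro = table[table["repertoire"] != "gene"]
    genes = table[table["repertoire"] == "gene"]
    per_rep = retro.groupby("repertoire").size().to_dict()
    return {
        "table": table,
        "n_del": len(retro),
        "n_deg": len(genes),
        "per_repertoire": per_rep,
        "solo_ltr_fraction": (float((retro["structure"] == "solo_LTR").mean())
                              if len(retro) else np.nan),
        "per_chromosome": retro.groupby("chrom").size().to_dict(),
    }


# ---------------------------------------------------------------------------
# tolerisability phenotype
# ---------------------------------------------------------------------------

def classify_phenotype(de_lps_vs_ns: pd.DataFrame, de_et_vs_lps: pd.DataFrame,
                       annotation=None, config: DeConfig | None = None):
    """Tolerisable / non-tolerisable / down-modulated per probeset.

    * tolerisable: significant up in LPS vs NS AND significant down in
      ET vs LPS (induced by LPS, blunted after priming);
    * non_tolerisable: significant up in LPS vs NS, not significant down in
      ET vs LPS (induced in both settings);
    * down_modulated: significant down in LPS vs NS;
    * unclassified otherwise.

    With ``annotation`` a locus-level table is also returned (majority vote
    over the locus's classified probesets; ties -> unclassified).
    """
    a, b = de_lps_vs_ns, de_et_vs_lps
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            only = set(a.index) ^ set(b.index)
            raise ValueError(f"probeset(s) present in one contrast only: "
                             f"{sorted(only)[:3]}")
        b = b.loc[a.index]
    up1 = (a["direction"] == "up").to_numpy()
    down1 = (a["direction"] == "down").to_numpy()
    down2 = (b["direction"] == "down").to_numpy()
    cls = np.where(up1 & down2, "tolerisable",
                   np.where(up1 & ~down2, "non_tolerisable",
                            np.where(down1, "down_modulated", "unclassified")))
    table = pd.DataFrame({"phenotype": cls}, index=a.index)
    if annotation is None:
        return table
    ann = annotation_frame(annotation).set_index("probeset_id")
    merged = table.join(ann[["locus_id"]], how="left")
    if merged["locus_id"].isna().any():
        raise ValueError("phenotype table contains unannotated probesets")
    locus_rows = []
    for locus, sub in merged.groupby("locus_id"):
        informative = sub[sub["phenotype"] != "unclassified"]
        if informative.empty:
            locus_rows.append({"locus_id": locus, "phenotype": "unclassified"})
            continue
        counts = informative["phenotype"].value_counts()
        top = counts[counts == counts.max()]
        locus_rows.append({"locus_id": locus,
                           "phenotype": top.index[0] if len(top) == 1 else "unclassified"})
    return table, pd.DataFrame(locus_rows)


# ---------------------------------------------------------------------------
# top-variance hierarchical clustering
# ---------------------------------------------------------------------------

def top_variance_cluster(matrix: pd.DataFrame, config: DeConfig | None = None):
    """Cluster samples on the top-variance probesets.

    Probesets are ranked by variance across samples and the top
    ``top_variance_fraction`` retained (constant probesets among them are
    dropped with a warning since the correlation distance is undefined).
    Sample-sample distance is 1 - Pearson correlation; agglomeration uses
    the configured linkage.  Returns a dict with the selected (ordered)
    matrix, the scipy linkage, the leaf order and sample labels.
    """
    import warnings

    config = config or DeConfig()
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    var = matrix.var(axis=1, ddof=1)
    k = max(1, int(np.ceil(config.top_variance_fraction * len(matrix))))
    top = matrix.loc[var.sort_values(ascending=False, kind="mergesort").index[:k]]
    keep = top.var(axis=1, ddof=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant probeset(s) "
                      "with undefined correlation", stacklevel=2)
        top = top[keep]
    if top.empty:
        raise ValueError("no non-constant probesets selected")
    corr = np.corrcoef(top.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = hierarchy.linkage(condensed, method=config.linkage)
    leaves = hierarchy.leaves_list(link)
    return {
        "selected": top,
        "linkage": link,
        "leaf_order": leaves,
        "samples": list(matrix.columns),
        "ordered_matrix": top.iloc[:, leaves],
    }


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (merge heights as
    branch lengths)."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# relative qPCR quantification
# ---------------------------------------------------------------------------

def ddct(ct_target: pd.Series, ct_refs: pd.DataFrame | pd.Series,
         conditions: pd.Series, calibrator_condition: str = "NS") -> pd.Series:
    """2**-ddCt fold changes against housekeeping references.

    dCt = Ct_target - mean(Ct_refs) per sample (the arithmetic mean of the
    reference Cts equals geometric-mean normalisation of expression);
    ddCt = dCt - mean(dCt | calibrator condition); FC = 2**-ddCt, so the
    calibrator condition averages to 1.
    """
    ct_target = pd.Series(ct_target, dtype=float)
    refs = pd.DataFrame(ct_refs)
    conditions = pd.Series(conditions).reindex(ct_target.index)
    if not np.isfinite(ct_target).all() or not np.isfinite(refs.to_numpy()).all():
        raise ValueError("Ct values must be finite")
    cal = conditions == calibrator_condition
    if not cal.any():
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    dct = ct_target - refs.reindex(ct_target.index).mean(axis=1)
    ddct_ = dct - dct[cal].mean()
    return np.power(2.0, -ddct_)
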