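"""Per-sample LTR function assignment and cross-sample combination profiling.

An attributable LTR (one with distinguishable U3 and U5 probesets) is
classified in each sample from its U3 and U5 log2 signals with a dedicated
lower positive threshold (2**4.5) and a 3x fold change between subdomains:

* promoter (Pr): U5 over threshold and at least FC-fold above U3 — the
  transcript initiates in the LTR, so only R/U5 are covered;
* polyA (pA): the mirror case, U3 over threshold and FC-fold above U5;
* readthrough (RdT): both subdomains over threshold, no significant fold
  change — the LTR is transcribed end to end within a longer unit;
* Silent: both subdomains at or under the threshold;
* Undetermined: every remaining configuration.

Across the 45 samples each LTR is then summarised by the *set* of functions
it ever displayed ("operational determinism" profiling): LTRs that were
undetermined in any sample are excluded and counted separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import annotation_frame, attributable_ltrs, validate_sample_sheet

__all__ = ["FunctionConfig", "FUNCTION_LABELS", "assign_function",
           "assign_function_array", "summarize_ltr", "call_all_functions",
           "profile_functions", "determinism_summary", "category_name"]

FUNCTION_LABELS = ["Pr", "pA", "RdT", "Silent", "Undetermined"]

#: canonical ordering used when naming combination categories
_COMBO_ORDER = ["Silent", "pA", "Pr", "RdT"]


@dataclass
class FunctionConfig:
    function_threshold_log2: float = 4.5
    fold_change: float = 3.0

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")


def assign_function(u3_log2: float, u5_log2: float,
                    config: FunctionConfig | None = None) -> str:
    """Classify one (U3, U5) signal pair; exactly one label fires.

    The fold change is compared on the log2 scale (difference vs
    log2(fold_change)); "at least FC-fold" is inclusive, so a pair exactly
    FC apart is Pr/pA, not RdT.
    """
    config = config or FunctionConfig()
    if not (math.isfinite(u3_log2) and math.isfinite(u5_log2)):
        raise ValueError("non-finite U3/U5 signal")
    th = config.function_threshold_log2
    lfc = math.log2(config.fold_change)
    if u5_log2 > th and u5_log2 - u3_log2 >= lfc:
        return "Pr"
    if u3_log2 > th and u3_log2 - u5_log2 >= lfc:
        return "pA"
    if u3_log2 > th and u5_log2 > th and abs(u3_log2 - u5_log2) < lfc:
        return "RdT"
    if u3_log2 <= th and u5_log2 <= th:
        return "Silent"
    return "Undetermined"


def assign_function_array(u3: np.ndarray, u5: np.ndarray,
                          config: FunctionConfig | None = None) -> np.ndarray:
    """Vectorised version of :func:`assign_function` (same rule)."""
    config = config or FunctionConfig()
    u3 = np.asarray(u3, dtype=float)
    u5 = np.asarray(u5, dtype=float)
    if not (np.isfinite(u3).all() and np.isfinite(u5).all()):
        raise ValueError("non-finite U3/U5 signal")
    th = config.function_threshold_log2
    lfc = math.log2(config.fold_change)
    out = np.full(u3.shape, "Undetermined", dtype=object)
    d = u5 - u3
    out[(u3 > th) & (u5 > th) & (np.abs(d) < lfc)] = "RdT"
    out[(u3 <= th) & (u5 <= th)] = "Silent"
    # written pA before Pr so that at fold_change == 1 (degenerate, lfc == 0)
    # the tie at d == 0 resolves to Pr, matching the scalar rule order
    out[(u3 > th) & (-d >= lfc)] = "pA"
    out[(u5 > th) & (d >= lfc)] = "Pr"
    return out


def summarize_ltr(matrix: pd.DataFrame, annotation, sample_id: str,
                  config: FunctionConfig | None = None) -> pd.DataFrame:
    """Per-LTR (u3_log2, u5_log2) for one sample: median across the LTR's
    U3 probesets and across its U5 probesets."""
    u3, u5 = _subdomain_medians(matrix, annotation)
    if sample_id not in matrix.columns:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    out = pd.DataFrame({"u3_log2": u3[sample_id], "u5_log2": u5[sample_id]})
    out.index.name = "ltr_id"
    return out


def _subdomain_medians(matrix: pd.DataFrame, annotation):
    """(LTR x sample) median U3 and U5 matrices over attributable LTRs."""
    ann = annotation_frame(annotation)
    attributable = attributable_ltrs(ann)
    if not attributable:
        raise ValueError("no attributable LTR (need both U3 and U5 probesets)")
    ltr = ann[ann["region"].isin(["U3", "U5"])].copy()
    ltr["ltr_id"] = list(zip(ltr["locus_id"], ltr["ltr_role"]))
    ltr = ltr[ltr["ltr_id"].isin(attributable)]
    missing = set(ltr["probeset_id"]) - set(matrix.index)
    if missing:
        raise ValueError(f"matrix lacks probeset(s) {sorted(missing)[:3]}")
    sub = matrix.loc[ltr["probeset_id"]]
    med = sub.groupby([ltr["ltr_id"].to_numpy(), ltr["region"].to_numpy()]).median()
    u3 = med.xs("U3", level=1)
    u5 = med.xs("U5", level=1)
    common = u3.index.intersection(u5.index)
    return u3.loc[common], u5.loc[common]


def call_all_functions(matrix: pd.DataFrame, annotation, sheet: pd.DataFrame,
                       config: FunctionConfig | None = None):
    """One function call per attributable LTR per sample.

    Returns ``(calls, tally)``: a long DataFrame ``ltr_id sample_id function
    u3_log2 u5_log2`` and a per-sample tally of counts and percentages per
    label.
    """
    config = config or FunctionConfig()
    sheet = validate_sample_sheet(sheet)
    samples = [s for s in sheet["sample_id"] if s in matrix.columns]
    if len(samples) != len(sheet):
        missing = set(sheet["sample_id"]) - set(matrix.columns)
        raise ValueError(f"matrix lacks sample(s) {sorted(missing)[:3]}")
    u3, u5 = _subdomain_medians(matrix[samples], annotation)

    labels = assign_function_array(u3.to_numpy(), u5.to_numpy(), config)
    n_ltr, n_s = labels.shape
    calls = pd.DataFrame({
        "ltr_id": np.repeat(u3.index.to_numpy(), n_s),
        "sample_id": np.tile(np.asarray(samples, dtype=object), n_ltr),
        "function": labels.ravel(),
        "u3_log2": u3.to_numpy().ravel(),
        "u5_log2": u5.to_numpy().ravel(),
    })
    tally = (calls.groupby(["sample_id", "function"]).size()
             .unstack(fill_value=0)
             .reindex(columns=FUNCTION_LABELS, fill_value=0))
    pct = tally.div(tally.sum(axis=1), axis=0) * 100.0
    tally = pd.concat({"count": tally, "pct": pct}, axis=1)
    return calls, tally


def category_name(functions: frozenset | set) -> str:
    """Canonical combination name: singletons bare, larger sets joined with
    '/' in the fixed order Silent, pA, Pr, RdT."""
    ordered = [f for f in _COMBO_ORDER if f in functions]
    if not ordered:
        raise ValueError("empty function set")
    return "/".join(ordered)


def profile_functions(calls: pd.DataFrame):
    """Cross-sample combination profile per LTR.

    LTRs classified Undetermined in at least one sample are excluded from
    the combination analysis (flagged ``excluded``); the rest are
    categorised by the set of functions observed across samples.  Returns
    ``(profiles, combo_counts)``.
    """
    n_samples = calls["sample_id"].nunique()
    per_ltr = calls.groupby("ltr_id")
    sizes = per_ltr.size()
    if (sizes != n_samples).any():
        bad = sizes.index[sizes != n_samples][0]
        raise ValueError(f"LTR {bad!r} lacks calls for every sample")
    rows = []
    for ltr_id, sub in per_ltr:
        observed = set(sub["function"])
        excluded = "Undetermined" in observed
        observed.discard("Undetermined")
        rows.append({
            "ltr_id": ltr_id,
            "functions_observed": frozenset(observed),
            "category": category_name(observed) if observed else "Undetermined",
            "n_functions": len(observed),
            "excluded": excluded,
        })
    profiles = pd.DataFrame(rows)
    kept = profiles[~profiles["excluded"]]
    combo_counts = (kept.groupby("category").size().rename("n_ltrs")
                    .sort_values(ascending=False).reset_index())
    return profiles, combo_counts


def determinism_summary(profiles: pd.DataFrame) -> dict:
    """Fractions over non-excluded LTRs: constitutive (a single function in
    every sample), shifting (>= 2 functions), and the promoter<->polyA
    switch (profiles containing both Pr and pA) — the event the combination
    analysis shows to be extremely rare."""
    kept = profiles[~profiles["excluded"]]
    if kept.empty:
        raise ValueError("no non-excluded LTR profiles")
    n = len(kept)
    constitutive = int((kept["n_functions"] == 1).sum())
    shifting = int((kept["n_functions"] >= 2).sum())
    pr_pa = int(kept["functions_observed"].map(
        lambda fs: "Pr" in fs and "pA" in fs).sum())
    counts = kept.groupby("category").size().to_dict()
    return {
        "n_profiled": n,
        "n_excluded": int(profiles["excluded"].sum()),
        "constitutive_fraction": constitutive / n,
        "shifting_fraction": shifting / n,
        "pr_pa_switch_fraction": pr_pa / n,
        "counts": counts,
    }
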