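"""Positive-intensity threshold calibration and expression calling.

A probeset is called transcriptionally active when its normalised intensity
exceeds 2**5.5 in at least 14 of the 45 samples, all conditions pooled.
The threshold itself is calibrated as the lowest intensity at which every
repertoire shows acceptable replicate variability: the 75th percentile of
the coefficient of variation (computed on linear-scale values within
donor x condition replicate groups) must fall below 10% among probesets at
or above that intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import LtrRole, annotation_frame, validate_sample_sheet

__all__ = ["CallConfig", "ActivityCalls", "replicate_cv", "calibrate_threshold",
           "call_active", "summarize_transcriptome", "structure_distribution"]


@dataclass
class CallConfig:
    activity_threshold_log2: float = 5.5
    min_samples: int = 14
    n_samples: int = 45
    cv_limit: float = 0.10
    cv_percentile: float = 75.0
    bin_width_log2: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_samples <= self.n_samples:
            raise ValueError("require 0 < min_samples <= n_samples")
        if not 0 < self.cv_percentile < 100:
            raise ValueError("cv_percentile must be in (0, 100)")
        if self.bin_width_log2 <= 0:
            raise ValueError("bin_width_log2 must be positive")


@dataclass
class ActivityCalls:
    """Per-probeset activity: ``n_over`` samples above threshold and the
    resulting active flag (active iff n_over >= min_samples)."""

    table: pd.DataFrame  # index probeset_id, columns n_over:int, active:bool
    threshold_log2: float
    min_samples: int


def replicate_cv(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Mean linear-scale CV across donor x condition replicate groups.

    CV is sd/mean of 2**x within each replicate group; groups with fewer
    than two samples are ignored.
    """
    sheet = validate_sample_sheet(sheet)
    linear = np.power(2.0, matrix.to_numpy())
    groups = sheet.groupby(["donor", "condition"])["sample_id"].apply(list)
    col_idx = {s: i for i, s in enumerate(matrix.columns)}
    cvs = []
    for samples in groups:
        idx = [col_idx[s] for s in samples if s in col_idx]
        if len(idx) < 2:
            continue
        sub = linear[:, idx]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cvs.append(np.where(mean > 0, sd / mean, np.nan))
    if not cvs:
        raise ValueError("no replicate group with >= 2 samples in the sheet")
    return pd.Series(np.nanmean(np.column_stack(cvs), axis=1), index=matrix.index)


def calibrate_threshold(matrix: pd.DataFrame, annotation, sheet: pd.DataFrame,
                        config: CallConfig | None = None) -> float:
    """Smallest intensity bin edge above which every repertoire's CV
    percentile is under the limit.

    Probesets are binned by their mean log2 intensity (bin width
    ``config.bin_width_log2``); the grid of candidate thresholds is searched
    ascending and the first bin lower edge t such that, for each repertoire
    separately, ``percentile(CV | mean >= t) < cv_limit`` is returned.
    """
    config = config or CallConfig()
    ann = annotation_frame(annotation).set_index("probeset_id")
    common = matrix.index.intersection(ann.index)
    if len(common) == 0:
        raise ValueError("matrix and annotation share no probesets")
    cv = replicate_cv(matrix.loc[common], sheet)
    mean_log2 = matrix.loc[common].mean(axis=1)
    repertoire = ann.loc[common, "repertoire"]

    w = config.bin_width_log2
    lo = np.floor(mean_log2.min() / w) * w
    hi = mean_log2.max()
    edges = np.arange(lo, hi + w, w)
    for t in edges:
        ok = True
        for _, mask in repertoire.groupby(repertoire).groups.items():
            sel = mean_log2.loc[mask] >= t
            if sel.sum() == 0:
                ok = False
                break
            pct = np.nanpercentile(cv.loc[mask][sel], config.cv_percentile)
            if not pct < config.cv_limit:
                ok = False
                break
        if ok:
            return float(t)
    raise ValueError(
        "no intensity bin satisfies the CV criterion for every repertoire; "
        "the data may span too narrow an intensity range")


def call_active(matrix: pd.DataFrame, config: CallConfig | None = None) -> ActivityCalls:
    """Count samples strictly over the threshold and flag active probesets."""
    config = config or CallConfig()
    n_over = (matrix.to_numpy() > config.activity_threshold_log2).sum(axis=1)
    table = pd.DataFrame(
        {"n_over": n_over, "active": n_over >= config.min_samples},
        index=matrix.index)
    return ActivityCalls(table=table, threshold_log2=config.activity_threshold_log2,
                         min_samples=config.min_samples)


def summarize_transcriptome(calls: ActivityCalls, annotation,
                            group_class: dict[str, str] | None = None) -> pd.DataFrame:
    """Active probeset counts and percentages per repertoire / retrovirus
    class / group.

    Rows carry a ``level`` column (repertoire, class or group); class rows
    sum their member groups, repertoire rows sum their classes, so counts
    partition exactly.
    """
    from .annotation_io import GROUP_CLASS

    group_class = group_class if group_class is not None else GROUP_CLASS
    ann = annotation_frame(annotation).set_index("probeset_id")
    missing = calls.table.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"probeset(s) without annotation: {list(missing[:3])}")
    df = ann.loc[calls.table.index].copy()
    df["active"] = calls.table["active"].to_numpy()

    def _class_of(row) -> str:
        if row.repertoire == "HERV_prototypes":
            if row.group not in group_class:
                raise ValueError(f"unknown group {row.group!r}")
            return group_class[row.group]
        return row.repertoire  # Dfam repertoires / genes: one global entity

    df["retro_class"] = [_class_of(r) for r in df.itertuples()]

    rows = []
    for (level, name), sub in (
        [(("repertoire", rep), g) for rep, g in df.groupby("repertoire")]
        + [(("class", f"{rep}:{cls}"), g)
           for (rep, cls), g in df.groupby(["repertoire", "retro_class"])]
        + [(("group", f"{rep}:{grp}"), g)
           for (rep, grp), g in df.groupby(["repertoire", "group"]) if grp != ""]
    ):
        n = len(sub)
        a = int(sub["active"].sum())
        rows.append({"level": level, "name": name, "n_probesets": n,
                     "n_active": a, "pct_active": 100.0 * a / n if n else 0.0})
    return pd.DataFrame(rows)


_STRUCTURE_OF = {
    ("solo", True): "solo_LTR",
    ("five_prime", True): "five_prime_LTR",
    ("three_prime", True): "three_prime_LTR",
}


def structure_distribution(calls: ActivityCalls, annotation) -> pd.DataFrame:
    """Chip vs transcriptome composition over structural categories of the
    prototype repertoire: solo / 5' / 3' LTRs and internal proviral genes.

    Both columns are probability vectors summing to 1.
    """
    ann = annotation_frame(annotation).set_index("probeset_id")
    proto = ann[ann["repertoire"] == "HERV_prototypes"].copy()
    if proto.empty:
        raise ValueError("no prototype-repertoire probesets")
    on_ltr = proto["ltr_role"] != LtrRole.NONE.value
    proto["structure"] = [
        _STRUCTURE_OF.get((role, is_ltr), "proviral_genes")
        for role, is_ltr in zip(proto["ltr_role"], on_ltr)]
    proto["active"] = calls.table["active"].reindex(proto.index).fillna(False).to_numpy()

    chip = proto.groupby("structure").size()
    active = proto[proto["active"]].groupby("structure").size()
    cats = ["solo_LTR", "five_prime_LTR", "three_prime_LTR", "proviral_genes"]
    chip = chip.reindex(cats, fill_value=0)
    active = active.reindex(cats, fill_value=0)
    out = pd.DataFrame({
        "chip_share": chip / chip.sum(),
        "transcriptome_share": (active / active.sum()) if active.sum() else 0.0,
    })
    out.index.name = "structure"
    return out
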