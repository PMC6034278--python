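"""Synthetic chip-data generator with planted ground truth.

Emulates the statistical structure of an LTR-retrotransposon microarray
experiment on PBMCs under an endotoxin-tolerance design: 5 donors x
{NS, LPS, ET} x triplicate (45 samples), three retroelement repertoires
plus an immunity-gene repertoire, U3/R/U5-resolved LTR probesets, a small
fraction of transcriptionally active loci, the four LTR functional classes
(silent / promoter / polyA / readthrough), and condition programs
(tolerisable / non-tolerisable / down-modulated / constitutive) with donor
random effects and multiplicative (log-normal) noise.

The planted truth is emitted alongside the data so every downstream stage
(expression calling, function assignment, differential expression,
phenotype classification, network integration) can be scored for recovery.

Signal model (log2 scale)
-------------------------
``x[p, s] = mu[p, cond(s)] + u[p, donor(s)] + e[p, s]`` where

* ``mu`` is the planted condition mean: the noise floor for inactive
  probesets, ``active_mean_log2`` for active ones, shifted by the locus
  program (+effect in LPS for tolerisable, +effect in LPS and ET for
  non-tolerisable, -effect in LPS and ET for down-modulated);
* ``u ~ N(0, donor_sd_log2^2)`` is a per-donor, per-probeset intercept —
  constant within a donor x condition triplicate, so it does not inflate
  replicate CV;
* ``e ~ N(0, sigma^2)`` with ``sigma = sqrt(ln(1 + cv^2)) / ln 2`` so that
  the *linear*-scale coefficient of variation of replicates equals
  ``noise_cv`` exactly under the log-normal model (the first-order
  approximation ``sigma ~ log2(1 + cv)`` agrees to O(cv^2)).

Planted LTR functions place the expressed subdomains at ``active_mean``
and the silent ones at the floor, which at the default geometry keeps every
class at least ``margin_log2`` away from the decision boundaries of the
function classifier, making recovery a designed property rather than luck.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import (
    Condition,
    GROUP_CLASS,
    ProbesetAnnotation,
    annotation_frame,
    validate_sample_sheet,
)

__all__ = ["SimParams", "GroundTruth", "generate_design", "generate_annotation",
           "generate_intensities", "simulate"]

FUNCTIONS = ["Silent", "Pr", "pA", "RdT"]
PROGRAMS = ["tolerisable", "non_tolerisable", "down_modulated", "constitutive"]

#: condition multiplier applied to ``effect_log2`` per program.  The
#: IFN-gamma reversal arm behaves like a fresh LPS challenge for tolerisable
#: units (tolerance is reversed) and like ET otherwise.
_PROGRAM_EFFECT = {
    "tolerisable":     {"NS": 0.0, "LPS": 1.0, "ET": 0.0, "ET_IFNG": 1.0},
    "non_tolerisable": {"NS": 0.0, "LPS": 1.0, "ET": 1.0, "ET_IFNG": 1.0},
    "down_modulated":  {"NS": 0.0, "LPS": -1.0, "ET": -1.0, "ET_IFNG": -1.0},
    "constitutive":    {"NS": 0.0, "LPS": 0.0, "ET": 0.0, "ET_IFNG": 0.0},
}

_CONDITION_ORDER = ["NS", "LPS", "ET", "ET_IFNG"]


@dataclass
class SimParams:
    """Generator knobs.  Defaults are the study conditions being emulated.

    ``n_loci`` is deliberately laptop-scale; the real chip has ~354k loci.
    ``fraction_active`` (5.6%), ``function_mix`` (70.5/15.2/11.8/2.5%) and
    the 52% gene activity are the observed study-wide rates; noise and
    effect sizes are package choices documented in the methods note.
    """

    n_loci: dict[str, int] = field(default_factory=lambda: {
        "HERV_prototypes": 400, "HERV_Dfam": 300, "MaLR_Dfam": 300, "gene": 150})
    fraction_active: float = 0.056
    gene_fraction_active: float = 0.52
    function_mix: dict[str, float] = field(default_factory=lambda: {
        "Silent": 0.705, "Pr": 0.152, "pA": 0.118, "RdT": 0.025})
    program_mix: dict[str, float] = field(default_factory=lambda: {
        "tolerisable": 0.35, "non_tolerisable": 0.25,
        "down_modulated": 0.25, "constitutive": 0.15})
    solo_fraction: float = 0.6
    attributable_fraction: float = 0.31
    conditional_fraction: float = 0.0
    noise_floor_log2: float = 3.0
    active_mean_log2: float = 8.0
    active_spread_log2: float = 1.0
    effect_log2: float = 2.0
    donor_sd_log2: float = 0.3
    noise_cv: float = 0.06
    floor_cv: float = 0.6
    cv_decay_log2: float = 0.8
    floor_spread_log2: float = 0.7
    floor_spread_max_log2: float = 2.0
    margin_log2: float = 0.5
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("function_mix", self.function_mix),
                          ("program_mix", self.program_mix)):
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative probabilities")
        for name in ("donor_sd_log2", "noise_cv", "margin_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_active", "gene_fraction_active", "solo_fraction",
                     "attributable_fraction", "conditional_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted labels emitted by the generator.

    loci
        one row per locus: ``locus_id repertoire group active program``.
    ltrs
        one row per LTR: ``locus_id ltr_role attributable function
        conditional`` (``conditional`` marks LTRs planted silent in NS and
        functional under stimulation).
    expected_means
        probesets x conditions, planted log2 mean before donor/noise terms.
    """

    loci: pd.DataFrame
    ltrs: pd.DataFrame
    expected_means: pd.DataFrame
    params: SimParams
    probesets: pd.DataFrame | None = None


def _stage_rng(params: SimParams, stage: int) -> np.random.Generator:
    """Deterministic sub-stream per pipeline stage from the single seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(stage,)))


def generate_design(n_donors: int, conditions, n_reps: int) -> pd.DataFrame:
    """Full-factorial sample sheet: donors x conditions x replicates."""
    conditions = [Condition(c).value for c in conditions]
    if not conditions:
        raise ValueError("conditions must be non-empty")
    if n_donors < 1 or n_reps < 1:
        raise ValueError("n_donors and n_reps must be >= 1")
    conditions = sorted(set(conditions), key=_CONDITION_ORDER.index)
    rows = [
        {"sample_id": f"D{d}_{cond}_R{r}", "donor": f"D{d}",
         "condition": cond, "replicate": r}
        for d in range(1, n_donors + 1)
        for cond in conditions
        for r in range(1, n_reps + 1)
    ]
    return validate_sample_sheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# annotation + truth
# ---------------------------------------------------------------------------

_PROTO_GROUPS = list(GROUP_CLASS)

# probeset layout within a locus, offsets in bp from the locus start
_SOLO_LAYOUT = [("U3", 0, 250), ("R", 250, 350), ("U5", 350, 600)]
_PROVIRUS_LEN = 7000
_SOLO_LEN = 600
_DFAM_LEN = 2000
_GENE_LEN = 5000


def _choice(rng: np.random.Generator, items: list[str], probs: list[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(items, dtype=object), size=n, p=p / p.sum())


def generate_annotation(params: SimParams) -> tuple[list[ProbesetAnnotation], GroundTruth]:
    """Emit chip annotation plus the planted truth tables.

    Prototype loci get U3/R/U5 probesets per LTR (both LTRs plus
    gag/pol/env for proviruses); Dfam loci get two LTR-part probesets and an
    internal probeset; genes get three gene-body probesets.  A planted
    fraction of prototype LTRs is *attributable* (carries both U3 and U5
    probesets); the rest lose their U5 probeset.  Coordinates are laid out
    non-overlapping per chromosome.
    """
    rng = _stage_rng(params, stage=0)
    fn_items, fn_probs = zip(*params.function_mix.items())
    pg_items, pg_probs = zip(*params.program_mix.items())

    records: list[ProbesetAnnotation] = []
    locus_rows: list[dict] = []
    ltr_rows: list[dict] = []
    # per-probeset planting info used later by generate_intensities
    ps_meta: list[dict] = []

    chrom_cursor = {f"chr{i}": 0 for i in range(1, params.n_chromosomes + 1)}
    chroms = list(chrom_cursor)

    def place(chrom: str, length: int) -> int:
        gap = int(rng.integers(1000, 50_000))
        start = chrom_cursor[chrom] + gap
        chrom_cursor[chrom] = start + length
        return start

    def add_ltr_probesets(locus_id: str, repertoire: str, group: str, role: str,
                          chrom: str, origin: int, strand: str,
                          attributable: bool, function: str, conditional: bool,
                          tag: str) -> None:
        for region, a, b in _SOLO_LAYOUT:
            if region == "U5" and not attributable:
                continue  # unattributable LTR: U5 signal indistinguishable
            pid = f"{locus_id}_{tag}{region}"
            records.append(ProbesetAnnotation(
                probeset_id=pid, locus_id=locus_id, repertoire=repertoire,
                group=group, region=region, ltr_role=role, chrom=chrom,
                start=origin + a, end=origin + b, strand=strand))
            ps_meta.append({"probeset_id": pid, "locus_id": locus_id,
                            "kind": "ltr" if attributable else "plain",
                            "region": region,
                            "function": function if attributable else "",
                            "conditional": conditional})
        ltr_rows.append({"locus_id": locus_id, "ltr_role": role,
                         "attributable": attributable, "function": function,
                         "conditional": conditional})

    for repertoire, n in params.n_loci.items():
        if n <= 0:
            continue
        if repertoire == "HERV_prototypes":
            groups = _choice(rng, _PROTO_GROUPS, [1.0] * len(_PROTO_GROUPS), n)
            solo = rng.random(n) < params.solo_fraction
        elif repertoire == "gene":
            groups = np.asarray([""] * n, dtype=object)
            solo = np.zeros(n, dtype=bool)
        else:
            groups = np.asarray([repertoire] * n, dtype=object)
            solo = np.ones(n, dtype=bool)

        base_active = rng.random(n) < (
            params.gene_fraction_active if repertoire == "gene" else params.fraction_active)

        prefix = {"HERV_prototypes": "PROT", "HERV_Dfam": "HDFM",
                  "MaLR_Dfam": "MDFM", "gene": "GENE"}[repertoire]
        for i in range(n):
            locus_id = f"{prefix}{i:06d}"
            chrom = chroms[int(rng.integers(len(chroms)))]
            strand = "+" if rng.random() < 0.5 else "-"
            group = str(groups[i])
            program = str(_choice(rng, list(pg_items), list(pg_probs), 1)[0])
            active = bool(base_active[i])

            if repertoire == "gene":
                origin = place(chrom, _GENE_LEN)
                for k in range(3):
                    pid = f"{locus_id}_gb{k}"
                    records.append(ProbesetAnnotation(
                        probeset_id=pid, locus_id=locus_id, repertoire=repertoire,
                        group=group, region="gene_body", ltr_role="none",
                        chrom=chrom, start=origin + k * 1500,
                        end=origin + k * 1500 + 500, strand=strand))
                    ps_meta.append({"probeset_id": pid, "locus_id": locus_id,
                                    "kind": "plain", "region": "gene_body",
                                    "function": "", "conditional": False})
            elif repertoire == "HERV_prototypes":
                roles = ["solo"] if solo[i] else ["five_prime", "three_prime"]
                length = _SOLO_LEN if solo[i] else _PROVIRUS_LEN
                origin = place(chrom, length)
                ltr_active = False
                for j, role in enumerate(roles):
                    attributable = bool(rng.random() < params.attributable_fraction)
                    function = (str(_choice(rng, list(fn_items), list(fn_probs), 1)[0])
                                if attributable else "")
                    conditional = bool(
                        function not in ("", "Silent")
                        and rng.random() < params.conditional_fraction)
                    ltr_origin = origin if j == 0 else origin + _PROVIRUS_LEN - _SOLO_LEN
                    add_ltr_probesets(locus_id, repertoire, group, role, chrom,
                                      ltr_origin, strand, attributable, function,
                                      conditional, tag=f"{role[:2]}_")
                    ltr_active = ltr_active or function not in ("", "Silent")
                if not solo[i]:
                    for region, a, b in (("gag", 700, 2600), ("pol", 2700, 5500),
                                         ("env", 5600, 6300)):
                        pid = f"{locus_id}_{region}"
                        records.append(ProbesetAnnotation(
                            probeset_id=pid, locus_id=locus_id,
                            repertoire=repertoire, group=group, region=region,
                            ltr_role="none", chrom=chrom, start=origin + a,
                            end=origin + b, strand=strand))
                        ps_meta.append({"probeset_id": pid, "locus_id": locus_id,
                                        "kind": "plain", "region": region,
                                        "function": "", "conditional": False})
                active = active or ltr_active
            else:  # Dfam repertoires: coarse solo LTR + internal probeset
                origin = place(chrom, _DFAM_LEN)
                for region, a, b, tag in (("LTR_part", 0, 220, "lp1"),
                                          ("LTR_part", 440, 660, "lp2")):
                    pid = f"{locus_id}_{tag}"
                    records.append(ProbesetAnnotation(
                        probeset_id=pid, locus_id=locus_id, repertoire=repertoire,
                        group=group, region=region, ltr_role="solo", chrom=chrom,
                        start=origin + a, end=origin + b, strand=strand))
                    ps_meta.append({"probeset_id": pid, "locus_id": locus_id,
                                    "kind": "plain", "region": region,
                                    "function": "", "conditional": False})
                pid = f"{locus_id}_int"
                records.append(ProbesetAnnotation(
                    probeset_id=pid, locus_id=locus_id, repertoire=repertoire,
                    group=group, region="internal", ltr_role="none", chrom=chrom,
                    start=origin + 800, end=origin + _DFAM_LEN, strand=strand))
                ps_meta.append({"probeset_id": pid, "locus_id": locus_id,
                                "kind": "plain", "region": "internal",
                                "function": "", "conditional": False})
                ltr_rows.append({"locus_id": locus_id, "ltr_role": "solo",
                                 "attributable": False, "function": "",
                                 "conditional": False})

            locus_rows.append({"locus_id": locus_id, "repertoire": repertoire,
                               "group": group, "active": active,
                               "base_active": bool(base_active[i]),
                               "program": program if active else "constitutive"})

    loci = pd.DataFrame(locus_rows)
    ltrs = pd.DataFrame(ltr_rows, columns=["locus_id", "ltr_role", "attributable",
                                           "function", "conditional"])
    meta = pd.DataFrame(ps_meta)
    expected = _expected_means(params, loci, meta, rng)
    truth = GroundTruth(loci=loci, ltrs=ltrs, expected_means=expected,
                        params=params, probesets=meta)
    return records, truth


def _expected_means(params: SimParams, loci: pd.DataFrame,
                    ps_meta: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Planted per-condition log2 mean for every probeset.

    Inactive "plain" probesets sit on a spread noise floor (floor plus a
    truncated exponential, emulating residual background/cross-hybridisation
    spread); the subdomain probesets of attributable LTRs sit exactly at the
    floor when unexpressed so that planted functions stay a margin away from
    the classifier boundaries.
    """
    floor, high, eff = params.noise_floor_log2, params.active_mean_log2, params.effect_log2
    locus_info = loci.set_index("locus_id")
    # plain probesets follow the locus's base activity; LTR-function-driven
    # transcription only raises the LTR's own subdomain probesets (so the
    # two planted layers — probeset activity rate and LTR function mix —
    # stay independently recoverable)
    active = ps_meta["locus_id"].map(locus_info["base_active"]).to_numpy(bool)
    program = ps_meta["locus_id"].map(locus_info["program"]).to_numpy(object)

    baseline = floor + np.minimum(
        rng.exponential(params.floor_spread_log2, size=len(ps_meta)),
        params.floor_spread_max_log2)
    # per-probeset baseline heterogeneity of expressed plain probesets
    # (clipped at 2 sd so activity calls stay deterministic in expectation);
    # attributable-LTR subdomains keep the exact planted levels instead
    active_base = high + np.clip(
        rng.normal(0.0, params.active_spread_log2, size=len(ps_meta)),
        -2.0 * params.active_spread_log2, 2.0 * params.active_spread_log2)

    # which subdomains an LTR function expresses
    expressed_by_fn = {"Silent": set(), "Pr": {"R", "U5"},
                       "pA": {"U3", "R"}, "RdT": {"U3", "R", "U5"}}

    out = {}
    for cond in _CONDITION_ORDER:
        shift = np.array([_PROGRAM_EFFECT[p][cond] for p in program]) * eff
        is_ltr = (ps_meta["kind"] == "ltr").to_numpy()
        mu = baseline.copy()
        plain_on = ~is_ltr & active
        mu[plain_on] = active_base[plain_on] + shift[plain_on]
        if is_ltr.any():
            fn = ps_meta["function"].to_numpy(object)
            region = ps_meta["region"].to_numpy(object)
            conditional = ps_meta["conditional"].to_numpy(bool)
            expressed = np.array([
                r in expressed_by_fn.get(f, set())
                for f, r in zip(fn, region)])
            on = is_ltr & expressed
            # conditional LTRs: silent in NS, functional under stimulation
            stim = cond != "NS"
            on_now = on & (~conditional | stim)
            mu[is_ltr] = floor
            mu[on_now] = high + np.where(conditional[on_now], 0.0, shift[on_now])
        out[cond] = mu
    return pd.DataFrame(out, index=ps_meta["probeset_id"].to_numpy())


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def generate_intensities(annotation, truth: GroundTruth, sheet: pd.DataFrame,
                         params: SimParams | None = None) -> pd.DataFrame:
    """Draw the log2 intensity matrix for a design from the planted truth."""
    params = params or truth.params
    sheet = validate_sample_sheet(sheet)
    ann = annotation_frame(annotation)
    if set(ann["probeset_id"]) != set(truth.expected_means.index):
        raise ValueError("annotation and ground truth come from different runs")

    rng = _stage_rng(params, stage=1)
    probesets = ann["probeset_id"].to_numpy()
    mu = truth.expected_means.loc[probesets]
    conds = sheet["condition"].to_numpy()
    missing = [c for c in np.unique(conds) if c not in mu.columns]
    if missing:
        raise ValueError(f"conditions {missing} unknown to the ground truth")

    base = mu[conds].to_numpy()  # P x S planted means
    donors = sheet["donor"].to_numpy()
    donor_levels = list(dict.fromkeys(donors))
    donor_eff = rng.normal(0.0, params.donor_sd_log2,
                           size=(len(probesets), len(donor_levels)))
    donor_idx = np.array([donor_levels.index(d) for d in donors])
    # intensity-dependent CV: noisy at the floor, decaying to noise_cv with
    # intensity (the planted structure the threshold calibration detects);
    # attributable-LTR subdomain probesets use the plateau CV throughout
    cv = params.noise_cv + (params.floor_cv - params.noise_cv) * np.exp(
        -np.clip(base - params.noise_floor_log2, 0.0, None) / params.cv_decay_log2)
    if truth.probesets is not None:
        is_ltr = (truth.probesets.set_index("probeset_id")
                  .loc[probesets, "kind"] == "ltr").to_numpy()
        cv[is_ltr, :] = params.noise_cv
    # exact linear-CV calibration: lognormal CV = sqrt(e^{(s ln2)^2} - 1)
    sigma = np.sqrt(np.log1p(cv ** 2)) / np.log(2)
    values = base + donor_eff[:, donor_idx] + rng.normal(0.0, 1.0, size=base.shape) * sigma
    return pd.DataFrame(values, index=pd.Index(probesets, name="probeset_id"),
                        columns=sheet["sample_id"].to_numpy())


def simulate(params: SimParams, n_donors: int = 5,
             conditions=("NS", "LPS", "ET"), n_reps: int = 3):
    """One-call generation: (annotation records, truth, sheet, matrix)."""
    records, truth = generate_annotation(params)
    sheet = generate_design(n_donors, conditions, n_reps)
    matrix = generate_intensities(records, truth, sheet, params)
    return records, truth, sheet, matrix
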