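"""Synthetic cohort generation with known ground truth.

Emulates the statistical structure the analysis assumes: age-matched
control distributions, TBV-hippocampal covariance with sex/hemisphere
slopes, lognormal (default) measurement noise, per-subfield atrophy and
metabolite effects injected into patients, CRLB and CSF-fraction
artefacts, and missing-hemisphere exclusions. All default magnitudes are
plausible placeholders (configuration, not empirical claims).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np

from .core_io import (
    METABOLITES,
    METABOLITES_REPORTED,
    SUBFIELDS,
    Cohort,
    MetabolitePanel,
    SubfieldVolumes,
    SubjectRecord,
    ValidationError,
)
from .single_case_inference import CaseTestResult, ConcordanceLabel

__all__ = ["EffectSpec", "GeneratorSpec", "generate_cohort",
           "generate_reference_cohort", "score_recovery"]

# placeholder control-level magnitudes (mm^3 and umol/g)
_DEFAULT_SUBFIELD_MEANS = {"CA1": 1300.0, "CA2": 150.0, "CA3": 250.0,
                           "DG": 650.0, "subiculum": 450.0}
_DEFAULT_METABOLITE_MEANS = {"tNAA": 11.0, "Glu": 8.5, "Gln": 3.0,
                             "tCho": 2.2, "tCr": 8.0, "Ins": 6.5,
                             "GABA": 1.2, "Lac": 0.8}
_DEFAULT_CRLB_RANGES = {**{m: (3.0, 20.0) for m in METABOLITES_REPORTED},
                        "GABA": (40.0, 90.0), "Lac": (45.0, 95.0)}


@dataclass
class EffectSpec:
    """One injected patient abnormality.

    ``target`` names a hemisphere-specific measure (``left.CA3`` or
    ``right.Gln``); ``kind`` is ``multiplicative`` (factor on the value)
    or ``sd_shift`` (shift in control-SD units); ``applies_to`` selects
    patients by attribute, e.g. ``{"eeg_laterality": "left"}`` (empty =
    all patients).
    """

    target: str
    kind: str  # "multiplicative" | "sd_shift"
    magnitude: float
    applies_to: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        hemi, _, measure = self.target.partition(".")
        if hemi not in ("left", "right") or measure not in (*SUBFIELDS, *METABOLITES):
            raise ValidationError(f"effect on unknown variable {self.target!r}")
        if self.kind not in ("multiplicative", "sd_shift"):
            raise ValidationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "multiplicative" and not self.magnitude > 0:
            raise ValidationError("multiplicative effect factor must be > 0")


@dataclass
class GeneratorSpec:
    n_controls: int = 12
    n_patients: int = 12
    n_reference: int = 25
    seed: int = 0
    control_means: dict[str, float] = field(default_factory=dict)
    control_cv: dict[str, float] = field(default_factory=dict)
    default_cv: float = 0.12
    tbv_mean_by_sex: dict[str, float] = field(
        default_factory=lambda: {"F": 1.10e6, "M": 1.25e6})
    tbv_sd: float = 8.0e4
    hippo_tbv_slope: float = 0.0020
    effects: list[EffectSpec] = field(default_factory=list)
    f_csf_shape: tuple[float, float] = (2.0, 18.0)  # beta(a, b)
    crlb_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CRLB_RANGES))
    missing_rate: float = 0.0
    noise_family: str = "lognormal"  # | "normal"
    age_mean: float = 32.0
    age_sd: float = 10.0
    patient_laterality: str | None = None  # None = random left/right

    def validate(self) -> None:
        for n in (self.n_controls, self.n_patients, self.n_reference):
            if n < 0:
                raise ValidationError("counts must be >= 0")
        if self.noise_family not in ("lognormal", "normal"):
            raise ValidationError(f"unknown noise family {self.noise_family!r}")
        if not (0 <= self.missing_rate <= 1):
            raise ValidationError("missing_rate must be a probability")
        for eff in self.effects:
            eff.validate()
        for key, cv in self.control_cv.items():
            if not cv > 0:
                raise ValidationError(f"cv for {key} must be > 0")

    def mean_of(self, measure: str) -> float:
        if measure in self.control_means:
            return self.control_means[measure]
        if measure in _DEFAULT_SUBFIELD_MEANS:
            return _DEFAULT_SUBFIELD_MEANS[measure]
        if measure in _DEFAULT_METABOLITE_MEANS:
            return _DEFAULT_METABOLITE_MEANS[measure]
        raise ValidationError(f"no configured mean for {measure!r}")

    def cv_of(self, measure: str) -> float:
        return self.control_cv.get(measure, self.default_cv)


def _noise_factors(rng: np.random.Generator, cv: float, size: int,
                   family: str) -> np.ndarray:
    """Unit-mean noise factors with the requested coefficient of variation."""
    if family == "lognormal":
        sigma = float(np.sqrt(np.log(1.0 + cv * cv)))
        return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)
    return np.maximum(rng.normal(1.0, cv, size=size), 1e-6)


def _draw_subject(rng: np.random.Generator, spec: GeneratorSpec, sid: str,
                  group: str) -> SubjectRecord:
    sex = "F" if rng.random() < 0.5 else "M"
    age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 70.0))
    tbv = float(rng.normal(spec.tbv_mean_by_sex[sex], spec.tbv_sd))
    rec = SubjectRecord(subject_id=sid, group=group, age=age, sex=sex, tbv=tbv)
    if group == "patient":
        if spec.patient_laterality is not None:
            rec.eeg_laterality = spec.patient_laterality
        else:
            rec.eeg_laterality = "left" if rng.random() < 0.5 else "right"
        onset = float(np.clip(rng.uniform(5.0, age - 1.0), 1.0, age))
        rec.age_at_onset = onset
        rec.duration = age - onset
        rec.language_dominant_hemisphere = "left" if rng.random() < 0.9 else "right"
        rec.memory_scores = {t: float(rng.normal(-0.5, 1.0))
                             for t in ("list_learning", "story_recall_delayed",
                                       "design_learning", "figure_recall")}
    return rec


def _draw_volumes(rng: np.random.Generator, spec: GeneratorSpec,
                  subj: SubjectRecord) -> dict[str, SubfieldVolumes]:
    """Subfield volumes per hemisphere; totals track TBV with the
    configured slope so head-size adjustment has something to remove."""
    out = {}
    base_total = sum(spec.mean_of(s) for s in SUBFIELDS)
    tbv_mean = float(np.mean(list(spec.tbv_mean_by_sex.values())))
    for hemi in ("left", "right"):
        target_total = base_total + spec.hippo_tbv_slope * (subj.tbv - tbv_mean)
        target_total *= float(_noise_factors(rng, spec.cv_of("total") if "total" in spec.control_cv
                                             else 0.08, 1, spec.noise_family)[0])
        target_total = max(target_total, 0.2 * base_total)
        shares = np.array([spec.mean_of(s) for s in SUBFIELDS])
        shares = shares * _noise_factors(rng, 0.05, len(SUBFIELDS), spec.noise_family)
        shares = shares / shares.sum()
        vols = {s: float(target_total * w) for s, w in zip(SUBFIELDS, shares)}
        out[hemi] = SubfieldVolumes(
            subject_id=subj.subject_id, hemisphere=hemi, volumes=vols,
            total_hippocampal_volume=float(sum(vols.values())),
        )
    return out


def _draw_mrs(rng: np.random.Generator, spec: GeneratorSpec,
              subj: SubjectRecord) -> dict[str, MetabolitePanel]:
    out = {}
    for hemi in ("left", "right"):
        conc = {}
        crlb = {}
        for m in METABOLITES:
            mean = spec.mean_of(m)
            conc[m] = float(mean * _noise_factors(rng, spec.cv_of(m), 1,
                                                  spec.noise_family)[0])
            lo, hi = spec.crlb_ranges[m]
            crlb[m] = float(rng.uniform(lo, hi))
        a, b = spec.f_csf_shape
        f_csf = float(rng.beta(a, b))
        f_gm = float((1.0 - f_csf) * rng.uniform(0.55, 0.75))
        f_wm = 1.0 - f_csf - f_gm
        out[hemi] = MetabolitePanel(
            subject_id=subj.subject_id, hemisphere=hemi,
            concentrations=conc, crlb=crlb,
            f_csf=f_csf, f_gm=f_gm, f_wm=f_wm,
        )
    return out


def _matches(subj: SubjectRecord, selector: Mapping[str, str]) -> bool:
    return all(str(getattr(subj, key, None)) == value for key, value in selector.items())


def _apply_effects(spec: GeneratorSpec, subj: SubjectRecord,
                   volumes: dict[str, SubfieldVolumes],
                   mrs: dict[str, MetabolitePanel],
                   truth: list[dict[str, Any]]) -> None:
    for eff in spec.effects:
        if not _matches(subj, eff.applies_to):
            continue
        hemi, _, measure = eff.target.partition(".")
        if measure in SUBFIELDS:
            rec = volumes[hemi]
            old = rec.volumes[measure]
            new = _apply_one(eff, old, spec.mean_of(measure), spec.cv_of(measure))
            rec.volumes[measure] = new
            rec.total_hippocampal_volume = float(sum(rec.volumes.values()))
        else:
            rec2 = mrs[hemi]
            old = rec2.concentrations[measure]
            new = _apply_one(eff, old, spec.mean_of(measure), spec.cv_of(measure))
            rec2.concentrations[measure] = new
        truth.append({
            "subject_id": subj.subject_id, "target": eff.target,
            "kind": eff.kind, "magnitude": eff.magnitude,
            "direction": "decreased" if new < old else "increased",
        })


def _apply_one(eff: EffectSpec, value: float, mean: float, cv: float) -> float:
    if eff.kind == "multiplicative":
        return float(value * eff.magnitude)
    # sd_shift: magnitude in control-SD units of the measure
    return float(max(value + eff.magnitude * mean * cv, 1e-6))


def generate_cohort(spec: GeneratorSpec) -> tuple[Cohort, dict[str, Any]]:
    """Draw a study cohort plus a ground-truth ledger.

    Deterministic given ``spec.seed``. The ledger records every injected
    effect, each patient's laterality, and the exclusions, for recovery
    scoring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cohort = Cohort()
    truth_effects: list[dict[str, Any]] = []
    exclusions: list[dict[str, str]] = []

    roster = ([("control", f"C{i + 1:02d}") for i in range(spec.n_controls)]
              + [("patient", f"P{i + 1:02d}") for i in range(spec.n_patients)])
    for group, sid in roster:
        subj = _draw_subject(rng, spec, sid, group)
        volumes = _draw_volumes(rng, spec, subj)
        mrs = _draw_mrs(rng, spec, subj)
        if group == "patient":
            _apply_effects(spec, subj, volumes, mrs, truth_effects)
        for hemi in ("left", "right"):
            if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                rec = volumes[hemi]
                rec.excluded = True
                rec.reason = "signal dropout precluded segmentation"
                rec.volumes = {}
                rec.total_hippocampal_volume = None
                exclusions.append({"subject_id": sid, "hemisphere": hemi,
                                   "table": "volumes", "reason": rec.reason})
        cohort.subjects[sid] = subj
        for hemi in ("left", "right"):
            cohort.volumes[(sid, hemi)] = volumes[hemi]
            cohort.mrs[(sid, hemi)] = mrs[hemi]

    cohort.validate()
    ledger = {
        "seed": spec.seed,
        "run_id": f"synthetic-{spec.seed}",
        "effects": truth_effects,
        "patient_laterality": {s.subject_id: s.eeg_laterality
                               for s in cohort.patients()},
        "exclusions": exclusions,
        "spec": _spec_to_jsonable(spec),
    }
    return cohort, ledger


def generate_reference_cohort(spec: GeneratorSpec) -> Cohort:
    """An independent normative cohort under the same generative law,
    for slope fitting only (never reuses the study controls)."""
    spec.validate()
    if spec.n_reference < 12:
        raise ValidationError("n_reference must be >= 12 (>= 3 per sex x hemisphere)")
    if spec.tbv_sd == 0:
        import logging
        logging.getLogger(__name__).warning(
            "tbv_sd = 0: downstream slope fitting will fail on zero TBV variance")
    rng = np.random.default_rng(spec.seed + 104729)  # decoupled stream
    cohort = Cohort()
    # force balanced sexes so all 4 slope cells are populated
    for i in range(spec.n_reference):
        sid = f"R{i + 1:02d}"
        subj = _draw_subject(rng, spec, sid, "control")
        subj.sex = "F" if i % 2 == 0 else "M"
        subj.tbv = float(rng.normal(spec.tbv_mean_by_sex[subj.sex], spec.tbv_sd))
        cohort.subjects[sid] = subj
        for hemi, rec in _draw_volumes(rng, spec, subj).items():
            cohort.volumes[(sid, hemi)] = rec
    cohort.validate()
    return cohort


def score_recovery(results: Iterable[CaseTestResult],
                   labels: Iterable[ConcordanceLabel],
                   ledger: Mapping[str, Any],
                   alpha: float = 0.05,
                   run_id: str | None = None) -> dict[str, Any]:
    """Compare battery results with the generator's ground truth.

    sensitivity: fraction of injected (patient, variable) effects detected
    at uncorrected ``alpha`` with the injected direction; specificity:
    1 - false-positive rate on untouched variables; laterality accuracy:
    fraction of effect-carrying patients labelled concordant (effects are
    injected on the EEG-onset side by the standard specs).
    """
    if run_id is not None and run_id != ledger.get("run_id"):
        raise ValidationError(
            f"run identifier mismatch: {run_id!r} vs ledger {ledger.get('run_id')!r}")
    results = [r for r in results if not r.untestable]
    injected: set[tuple[str, str]] = set()
    directions: dict[tuple[str, str], str] = {}
    for eff in ledger.get("effects", []):
        hemi, _, measure = eff["target"].partition(".")
        kind = "volume" if measure in SUBFIELDS else "conc"
        key = (eff["subject_id"], f"{hemi}.{measure}.{kind}")
        injected.add(key)
        directions[key] = eff["direction"]

    hits = misses = fp = tn = 0
    for r in results:
        key = (r.subject_id, r.variable)
        sig = r.p_uncorrected < alpha
        if key in injected:
            if sig and r.direction == directions[key]:
                hits += 1
            else:
                misses += 1
        elif not r.variable.endswith(".asymmetry"):
            # asymmetries are correlated with injected lateralized effects,
            # so they count toward neither error rate
            if sig:
                fp += 1
            else:
                tn += 1

    affected = {sid for sid, _ in injected}
    lat_hits = lat_total = 0
    for label in labels:
        if label.subject_id in affected:
            lat_total += 1
            if label.label == "concordant":
                lat_hits += 1

    def _ratio(a: int, b: int) -> float | None:
        return a / b if b else None

    return {
        "sensitivity": _ratio(hits, hits + misses),
        "specificity": _ratio(tn, tn + fp),
        "laterality_accuracy": _ratio(lat_hits, lat_total),
        "n_injected_tested": hits + misses,
        "n_clean_tested": tn + fp,
    }


def _spec_to_jsonable(spec: GeneratorSpec) -> dict[str, Any]:
    d = asdict(spec)
    d["f_csf_shape"] = list(spec.f_csf_shape)
    d["crlb_ranges"] = {k: list(v) for k, v in spec.crlb_ranges.items()}
    return d


def write_truth(ledger: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(ledger, indent=2, sort_keys=True) + "\n")
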