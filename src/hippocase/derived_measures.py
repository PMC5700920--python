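"""Deterministic per-subject corrections and indices.

Head-size covariance adjustment of total hippocampal volume, propagation
of that adjustment to subfields through a single multiplicative scaling
factor, CSF partial-volume correction of metabolite concentrations, CRLB
quality filtering, left-right asymmetry indices, ipsi/contra mapping and
the memory-impairment threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core_io import (
    METABOLITES,
    SUBFIELDS,
    Cohort,
    MetabolitePanel,
    ReferenceSlopes,
    SubfieldVolumes,
    SubjectRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: memory z-score at or below which a test is flagged impaired
MEMORY_IMPAIRMENT_Z = -1.34


@dataclass
class AdjustedVolumes:
    """Head-size-adjusted total and uniformly scaled subfield volumes."""

    subject_id: str
    hemisphere: str
    adjusted_total: float
    scaling_factor: float
    scaled_subfields: dict[str, float] = field(default_factory=dict)


@dataclass
class AsymmetrySet:
    """Per-subject left-right asymmetry indices keyed by variable name."""

    subject_id: str
    indices: dict[str, float] = field(default_factory=dict)


def fit_reference_slopes(subjects: Mapping[str, SubjectRecord],
                         volumes: Mapping[tuple[str, str], SubfieldVolumes],
                         ) -> ReferenceSlopes:
    """OLS slope of total hippocampal volume on TBV per (sex, hemisphere) cell.

    The reference cohort is independent of the study controls; each cell
    needs >= 3 subjects with both a total volume and a TBV. The cell's own
    mean TBV is stored for centering, so the adjustment is the identity at
    the reference mean.
    """
    cells: dict[tuple[str, str], tuple[list[float], list[float]]] = {}
    for (sid, hemi), rec in volumes.items():
        if rec.excluded or rec.total_hippocampal_volume is None:
            continue
        subj = subjects.get(sid)
        if subj is None or subj.tbv is None:
            continue
        x, y = cells.setdefault((subj.sex, hemi), ([], []))
        x.append(subj.tbv)
        y.append(rec.total_hippocampal_volume)

    slopes: dict[tuple[str, str], float] = {}
    tbv_mean: dict[tuple[str, str], float] = {}
    n_ref: dict[tuple[str, str], int] = {}
    for cell, (x, y) in sorted(cells.items()):
        if len(x) < 3:
            raise ValidationError(f"reference cell {cell} has only {len(x)} subjects (need >= 3)")
        xa, ya = np.asarray(x, float), np.asarray(y, float)
        if np.ptp(xa) == 0:
            raise ValidationError(f"reference cell {cell} has zero TBV variance")
        slope = float(np.polyfit(xa, ya, 1)[0])
        slopes[cell] = slope
        tbv_mean[cell] = float(xa.mean())
        n_ref[cell] = len(x)
    if not slopes:
        raise ValidationError("no usable reference subjects")
    ref = ReferenceSlopes(slopes=slopes, tbv_mean=tbv_mean, n_reference=n_ref)
    ref.validate()
    return ref


def adjust_total_volume(observed: float, tbv_subject: float,
                        slopes: ReferenceSlopes, sex: str, hemisphere: str) -> float:
    """adjusted = observed - slope * (tbv_subject - tbv_mean), per cell."""
    cell = (sex, hemisphere)
    if cell not in slopes.slopes:
        raise ValidationError(f"no reference slope for cell {cell}")
    if not observed > 0:
        raise ValidationError(f"observed volume must be > 0, got {observed}")
    adjusted = observed - slopes.slopes[cell] * (tbv_subject - slopes.tbv_mean[cell])
    if adjusted <= 0:
        raise ValidationError(
            f"adjusted volume {adjusted:.2f} <= 0 for cell {cell}: implausible slope/TBV combination"
        )
    return adjusted


def scale_subfields(raw: SubfieldVolumes, adjusted_total: float,
                    mode: str = "adjusted_over_observed") -> AdjustedVolumes:
    """Apply one multiplicative factor to every subfield.

    Default factor is adjusted/observed so the scaled total equals the
    adjusted total; ``observed_over_adjusted`` applies the inverse ratio.
    Subfield proportions are preserved exactly in either mode.
    """
    observed_total = raw.total_hippocampal_volume
    if observed_total is None:
        if any(v is not None for v in raw.volumes.values()):
            raise ValidationError(
                f"{raw.subject_id}/{raw.hemisphere}: observed total required to scale subfields"
            )
        raise ValidationError(f"{raw.subject_id}/{raw.hemisphere}: no volumes to scale")
    if adjusted_total <= 0:
        raise ValidationError("adjusted_total must be > 0")
    if mode == "adjusted_over_observed":
        factor = adjusted_total / observed_total
    elif mode == "observed_over_adjusted":
        factor = observed_total / adjusted_total
    else:
        raise ValidationError(f"unknown scaling mode {mode!r}")
    scaled = {s: factor * v for s, v in raw.volumes.items() if v is not None}
    return AdjustedVolumes(
        subject_id=raw.subject_id,
        hemisphere=raw.hemisphere,
        adjusted_total=adjusted_total,
        scaling_factor=factor,
        scaled_subfields=scaled,
    )


def csf_correct(concentration: float, f_csf: float) -> float:
    """Partial-volume correction: concentration / (1 - f_csf)."""
    if not 0 <= f_csf < 1:
        raise ValidationError(f"f_csf must lie in [0, 1), got {f_csf}")
    return concentration / (1.0 - f_csf)


def crlb_filter(panel: MetabolitePanel, threshold: float = 50.0) -> MetabolitePanel:
    """Set qc_pass[m] = (CRLB[m] <= threshold); strict > rejects."""
    for m, value in panel.crlb.items():
        if value is None:
            continue
        if value < 0:
            raise ValidationError(
                f"{panel.subject_id}/{panel.hemisphere}: negative CRLB for {m}: {value}"
            )
        panel.qc_pass[m] = value <= threshold
    return panel


def cohort_reportable_metabolites(panels: Iterable[MetabolitePanel],
                                  threshold: float = 50.0,
                                  warn_threshold: float = 25.0,
                                  ) -> list[str]:
    """Metabolites passing QC for every non-excluded panel in the cohort.

    A metabolite is reportable only if no participant's CRLB exceeds the
    rejection threshold in either hemisphere; values above the reporting
    bound (but below rejection) are logged at WARN, not rejected.
    """
    panels = [p for p in panels if not p.excluded]
    reportable = []
    for m in METABOLITES:
        crlbs = [p.crlb.get(m) for p in panels]
        known = [c for c in crlbs if c is not None]
        if not known:
            continue
        if any(c > threshold for c in known):
            logger.warning("metabolite %s rejected cohort-wide (max CRLB %.1f%% > %.0f%%)",
                           m, max(known), threshold)
            continue
        if any(c > warn_threshold for c in known):
            logger.warning("metabolite %s kept but CRLB exceeds reporting bound %.0f%% "
                           "for some participants (max %.1f%%)", m, warn_threshold, max(known))
        reportable.append(m)
    return reportable


def asymmetry_index(left_value: float, right_value: float) -> float:
    """(L - R) / [(L + R) / 2]; antisymmetric, bounded by [-2, 2] for L,R >= 0."""
    denom = (left_value + right_value) / 2.0
    if denom == 0:
        raise ValidationError("asymmetry index undefined for L + R = 0")
    return (left_value - right_value) / denom


def map_ipsi_contra(left_value: float, right_value: float,
                    eeg_laterality: str) -> tuple[float, float]:
    """Return (ipsilateral, contralateral) relative to seizure-onset side."""
    if eeg_laterality == "left":
        return left_value, right_value
    if eeg_laterality == "right":
        return right_value, left_value
    raise ValidationError(
        f"cannot map ipsi/contra for laterality {eeg_laterality!r}: "
        "subject excluded from ipsi/contra pooling"
    )


def memory_impairment_flag(z: float) -> bool:
    """True iff z <= -1.34 (inclusive threshold)."""
    if not math.isfinite(z):
        raise ValidationError(f"memory z-score must be finite, got {z}")
    return z <= MEMORY_IMPAIRMENT_Z


def voi_volume(dims: tuple[float, float, float]) -> float:
    """Cuboid VOI volume in mL from edge lengths in mm."""
    if any(d <= 0 for d in dims):
        raise ValidationError(f"VOI dimensions must be positive, got {dims}")
    return dims[0] * dims[1] * dims[2] / 1000.0


# ---------------------------------------------------------------------------
# cohort-level derivation

@dataclass
class DerivedCohort:
    """All corrected measures for a cohort, keyed for downstream statistics.

    ``values`` maps variable name -> {subject_id -> value} where variable
    names follow ``left.CA1.volume`` / ``right.Gln.conc`` /
    ``CA1.asymmetry`` / ``Gln.asymmetry`` conventions.
    """

    values: dict[str, dict[str, float]] = field(default_factory=dict)
    adjusted: dict[tuple[str, str], AdjustedVolumes] = field(default_factory=dict)
    reportable_metabolites: list[str] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)


def volume_variable(hemisphere: str, subfield: str) -> str:
    return f"{hemisphere}.{subfield}.volume"


def metabolite_variable(hemisphere: str, metabolite: str) -> str:
    return f"{hemisphere}.{metabolite}.conc"


def asymmetry_variable(measure: str) -> str:
    return f"{measure}.asymmetry"


def derive_cohort(cohort: Cohort, slopes: ReferenceSlopes | None,
                  scaling_mode: str = "adjusted_over_observed",
                  crlb_threshold: float = 50.0,
                  crlb_warn: float = 25.0) -> DerivedCohort:
    """Run every deterministic correction over a cohort.

    Volumes: head-size adjust totals (when reference slopes and TBV are
    available) and scale subfields. MRS: CRLB QC then CSF correction.
    Asymmetries are computed from the corrected per-hemisphere values for
    subjects with both hemispheres usable.
    """
    out = DerivedCohort()

    def put(variable: str, sid: str, value: float) -> None:
        out.values.setdefault(variable, {})[sid] = value

    # --- volumes ---
    for (sid, hemi), rec in sorted(cohort.volumes.items()):
        if rec.excluded:
            out.exclusions.append(f"{sid}/{hemi}: volumes excluded ({rec.reason or 'no reason'})")
            continue
        subj = cohort.subjects[sid]
        total = rec.total_hippocampal_volume
        if total is None:
            out.exclusions.append(f"{sid}/{hemi}: no total hippocampal volume")
            continue
        if slopes is not None and subj.tbv is not None and (subj.sex, hemi) in slopes.slopes:
            adjusted_total = adjust_total_volume(total, subj.tbv, slopes, subj.sex, hemi)
        else:
            adjusted_total = total  # no head-size information: identity
        adj = scale_subfields(rec, adjusted_total, mode=scaling_mode)
        out.adjusted[(sid, hemi)] = adj
        for s, v in adj.scaled_subfields.items():
            put(volume_variable(hemi, s), sid, v)
        put(f"{hemi}.total.volume", sid, adj.adjusted_total
            if scaling_mode == "adjusted_over_observed" else total * adj.scaling_factor)

    # --- metabolites ---
    panels = [crlb_filter(p, crlb_threshold) for p in cohort.mrs.values()]
    out.reportable_metabolites = cohort_reportable_metabolites(
        panels, threshold=crlb_threshold, warn_threshold=crlb_warn)
    for rec in sorted(panels, key=lambda p: (p.subject_id, p.hemisphere)):
        sid, hemi = rec.subject_id, rec.hemisphere
        if rec.excluded:
            out.exclusions.append(f"{sid}/{hemi}: MRS excluded ({rec.reason or 'no reason'})")
            continue
        f_csf = rec.f_csf if rec.f_csf is not None else 0.0
        for m in out.reportable_metabolites:
            conc = rec.concentrations.get(m)
            if conc is None or not rec.qc_pass.get(m, True):
                continue
            put(metabolite_variable(hemi, m), sid, csf_correct(conc, f_csf))

    # --- asymmetries from corrected values ---
    for measure in (*SUBFIELDS, *out.reportable_metabolites):
        kind = "volume" if measure in SUBFIELDS else "conc"
        left = out.values.get(f"left.{measure}.{kind}", {})
        right = out.values.get(f"right.{measure}.{kind}", {})
        for sid in sorted(set(left) & set(right)):
            if left[sid] + right[sid] == 0:
                out.exclusions.append(f"{sid}: asymmetry undefined for {measure} (L + R = 0)")
                continue
            put(asymmetry_variable(measure), sid, asymmetry_index(left[sid], right[sid]))

    return out
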