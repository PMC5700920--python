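"""Domain types, measurement-table I/O, configuration and validation.

Tables are UTF-8 delimited text (comma or tab, auto-detected from the
header line). Missing values are written as ``NA``; both ``NA`` and empty
fields are accepted on read. Hemisphere labels are normalized to
``left``/``right`` from the alias table :data:`HEMISPHERE_ALIASES`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "SUBFIELDS",
    "METABOLITES",
    "METABOLITES_REPORTED",
    "MEMORY_TESTS",
    "HEMISPHERE_ALIASES",
    "ValidationError",
    "SubjectRecord",
    "SubfieldVolumes",
    "MetabolitePanel",
    "ReferenceSlopes",
    "AnalysisConfig",
    "Cohort",
    "read_subjects",
    "read_volumes",
    "read_mrs",
    "read_measurement_tables",
    "write_subjects",
    "write_volumes",
    "write_mrs",
    "write_cohort",
    "write_results",
    "read_table",
]

SUBFIELDS = ("CA1", "CA2", "CA3", "DG", "subiculum")
#: metabolites carried through QC (GABA/Lac enter pre-QC and are rejected)
METABOLITES = ("tNAA", "Glu", "Gln", "tCho", "tCr", "Ins", "GABA", "Lac")
METABOLITES_REPORTED = ("tNAA", "Glu", "Gln", "tCho", "tCr", "Ins")
MEMORY_TESTS = ("list_learning", "story_recall_delayed", "design_learning", "figure_recall")

HEMISPHERE_ALIASES = {
    "left": "left",
    "right": "right",
    "L": "left",
    "R": "right",
    "lh": "left",
    "rh": "right",
}

_LATERALITIES = ("left", "right", "bilateral", "unknown")
_LANG_HEMIS = ("left", "right", "unknown")


class ValidationError(ValueError):
    """A record or file violates a type invariant or the table schema."""


def _normalize_hemisphere(raw: str, context: str = "") -> str:
    try:
        return HEMISPHERE_ALIASES[raw]
    except KeyError:
        raise ValidationError(
            f"unknown hemisphere {raw!r}{context}; accepted: {sorted(HEMISPHERE_ALIASES)}"
        ) from None


@dataclass
class SubjectRecord:
    """One participant: demographics, group label and clinical covariates."""

    subject_id: str
    group: str  # "control" | "patient"
    age: float
    sex: str  # "F" | "M"
    tbv: float | None = None  # total brain volume, mm^3
    age_at_onset: float | None = None
    duration: float | None = None
    eeg_laterality: str = "unknown"
    language_dominant_hemisphere: str = "unknown"
    memory_scores: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValidationError(f"{self.subject_id}: group must be control|patient, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.subject_id}: sex must be F|M, got {self.sex!r}")
        if not self.age > 0:
            raise ValidationError(f"{self.subject_id}: age must be > 0, got {self.age}")
        if self.duration is not None and self.duration < 0:
            raise ValidationError(f"{self.subject_id}: duration must be >= 0, got {self.duration}")
        if self.age_at_onset is not None and self.age_at_onset > self.age:
            raise ValidationError(
                f"{self.subject_id}: age_at_onset {self.age_at_onset} exceeds age {self.age}"
            )
        if self.eeg_laterality not in _LATERALITIES:
            raise ValidationError(
                f"{self.subject_id}: eeg_laterality must be one of {_LATERALITIES}"
            )
        if self.language_dominant_hemisphere not in _LANG_HEMIS:
            raise ValidationError(
                f"{self.subject_id}: language_dominant_hemisphere must be one of {_LANG_HEMIS}"
            )
        for test in self.memory_scores:
            if test not in MEMORY_TESTS:
                raise ValidationError(
                    f"{self.subject_id}: unknown memory test {test!r}; accepted: {MEMORY_TESTS}"
                )
        if self.group == "control":
            # epilepsy fields are ignored for controls
            self.age_at_onset = None
            self.duration = None


@dataclass
class SubfieldVolumes:
    """Per-hemisphere subfield volumes (mm^3) with exclusion flag."""

    subject_id: str
    hemisphere: str
    volumes: dict[str, float | None] = field(default_factory=dict)
    total_hippocampal_volume: float | None = None
    excluded: bool = False
    reason: str = ""

    def validate(self) -> None:
        self.hemisphere = _normalize_hemisphere(self.hemisphere, f" for {self.subject_id}")
        for name, value in self.volumes.items():
            if name not in SUBFIELDS:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: unknown subfield {name!r}; accepted: {SUBFIELDS}"
                )
            if value is not None and not value > 0:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: volume {name}={value} must be > 0"
                )
        t = self.total_hippocampal_volume
        if t is not None and not t > 0:
            raise ValidationError(
                f"{self.subject_id}/{self.hemisphere}: total volume {t} must be > 0"
            )


@dataclass
class MetabolitePanel:
    """Per-hemisphere metabolite concentrations (umol/g) with CRLB QC."""

    subject_id: str
    hemisphere: str
    concentrations: dict[str, float | None] = field(default_factory=dict)
    crlb: dict[str, float | None] = field(default_factory=dict)
    f_csf: float | None = None
    f_gm: float | None = None
    f_wm: float | None = None
    qc_pass: dict[str, bool] = field(default_factory=dict)
    excluded: bool = False
    reason: str = ""

    def validate(self) -> None:
        self.hemisphere = _normalize_hemisphere(self.hemisphere, f" for {self.subject_id}")
        for name, value in self.concentrations.items():
            if name not in METABOLITES:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: unknown metabolite {name!r}; "
                    f"accepted: {METABOLITES}"
                )
            if value is not None and value < 0:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: concentration {name}={value} must be >= 0"
                )
        for name, value in self.crlb.items():
            if name not in METABOLITES:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: unknown metabolite {name!r} in CRLB; "
                    f"accepted: {METABOLITES}"
                )
            if value is not None and value < 0:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: CRLB {name}={value} must be >= 0"
                )
        if self.f_csf is not None and not (0 <= self.f_csf < 1):
            raise ValidationError(
                f"{self.subject_id}/{self.hemisphere}: f_csf {self.f_csf} must lie in [0, 1)"
            )
        fractions = (self.f_csf, self.f_gm, self.f_wm)
        if all(f is not None for f in fractions):
            total = sum(fractions)  # type: ignore[arg-type]
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"{self.subject_id}/{self.hemisphere}: tissue fractions sum to {total}, expected 1"
                )


@dataclass
class ReferenceSlopes:
    """Sex- and hemisphere-specific hippocampus-on-TBV regression slopes.

    ``slopes``, ``tbv_mean`` and ``n_reference`` are keyed by
    ``(sex, hemisphere)`` cells, e.g. ``("F", "left")``.
    """

    slopes: dict[tuple[str, str], float]
    tbv_mean: dict[tuple[str, str], float]
    n_reference: dict[tuple[str, str], int]

    def validate(self) -> None:
        import math

        for cell, n in self.n_reference.items():
            if n < 3:
                raise ValidationError(f"reference cell {cell} has n={n} < 3")
        for cell, s in self.slopes.items():
            if not math.isfinite(s):
                raise ValidationError(f"reference cell {cell} slope not finite: {s}")


@dataclass
class AnalysisConfig:
    """Run configuration; thresholds quoted per-operation live here."""

    alpha: float = 0.05
    tails: str = "two"  # "two" | "one"
    n_max_exhaustive: int = 2 ** 18
    n_mc: int = 10000
    rng_seed: int = 0
    scaling_mode: str = "adjusted_over_observed"  # | "observed_over_adjusted"
    crlb_reject_threshold: float = 50.0  # percent; strict > rejects
    crlb_warn_threshold: float = 25.0  # reporting bound, warning only
    boxcox_apply_to_asymmetry: bool = False
    # lambda policy for the case battery's Box-Cox preconditioning:
    # "fixed_log" (lambda = 0, chosen a priori), "mle_pooled" (profile MLE on
    # case + controls), "mle_controls" (MLE on controls only), "none"
    boxcox_policy: str = "fixed_log"
    fwe_method: str = "bonferroni"  # | "maxstat"
    age_residualize: bool = False

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tails not in ("two", "one"):
            raise ValidationError(f"tails must be two|one, got {self.tails!r}")
        if self.n_mc < 100:
            raise ValidationError(f"n_mc must be >= 100, got {self.n_mc}")
        if self.scaling_mode not in ("adjusted_over_observed", "observed_over_adjusted"):
            raise ValidationError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.fwe_method not in ("bonferroni", "maxstat"):
            raise ValidationError(f"unknown fwe_method {self.fwe_method!r}")
        if self.boxcox_policy not in ("fixed_log", "mle_pooled", "mle_controls", "none"):
            raise ValidationError(f"unknown boxcox_policy {self.boxcox_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Cohort:
    """Typed container binding subjects to their hemisphere measurements."""

    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    volumes: dict[tuple[str, str], SubfieldVolumes] = field(default_factory=dict)
    mrs: dict[tuple[str, str], MetabolitePanel] = field(default_factory=dict)

    def validate(self) -> None:
        for rec in self.subjects.values():
            rec.validate()
        for store in (self.volumes, self.mrs):
            for key, rec in store.items():
                rec.validate()
                if rec.subject_id not in self.subjects:
                    raise ValidationError(f"measurement for unknown subject {rec.subject_id!r}")
                if key != (rec.subject_id, rec.hemisphere):
                    raise ValidationError(f"key {key} does not match record identity")

    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects.values() if s.group == "control"]

    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects.values() if s.group == "patient"]


# ---------------------------------------------------------------------------
# table primitives

def _fmt(value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if hasattr(value, "item") and not isinstance(value, str):  # numpy scalar
        value = value.item()
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _parse_float(raw: str, where: str) -> float | None:
    if raw in ("", "NA"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(f"{where}: not a number: {raw!r}") from None


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in ("true", "1", "yes")


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, dict[str, str]]]]:
    """Read a delimited table; returns header and (line_number, row) pairs."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header_line = lines[0]
    delim = "\t" if "\t" in header_line else ","
    header = [h.strip() for h in header_line.split(delim)]
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{i}: expected {len(header)} fields, got {len(fields)}"
            )
        rows.append((i, dict(zip(header, fields))))
    return header, rows


def _write_table(path: str | Path, header: list[str], rows: Iterable[Iterable[Any]],
                 column_dict: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = []
    if column_dict:
        for col, desc in column_dict.items():
            out.append(f"# {col}: {desc}")
    out.append("\t".join(header))
    for row in rows:
        out.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def read_table(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Generic reader for results tables: skips ``#`` comment headers."""
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        return [], []
    delim = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(delim)
    return header, [dict(zip(header, ln.split(delim))) for ln in lines[1:]]


# ---------------------------------------------------------------------------
# subjects

_SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "tbv", "age_at_onset", "duration",
    "eeg_laterality", "language_dominant_hemisphere", *MEMORY_TESTS,
]


def read_subjects(path: str | Path) -> dict[str, SubjectRecord]:
    header, rows = _read_rows(path)
    tbv_cm3 = "tbv(cm3)" in header
    accepted = set(_SUBJECT_COLUMNS) | {"tbv(cm3)"}
    unknown = [h for h in header if h not in accepted]
    if unknown:
        raise ValidationError(
            f"{path}: unknown columns {unknown}; accepted: {_SUBJECT_COLUMNS}"
        )
    subjects: dict[str, SubjectRecord] = {}
    for lineno, row in rows:
        where = f"{path}:{lineno}"
        sid = row.get("subject_id", "")
        if not sid:
            raise ValidationError(f"{where}: missing subject_id")
        if sid in subjects:
            raise ValidationError(f"{where}: duplicate subject_id {sid!r}")
        tbv = _parse_float(row.get("tbv(cm3)" if tbv_cm3 else "tbv", ""), where)
        if tbv is not None and tbv_cm3:
            tbv *= 1000.0
        age = _parse_float(row.get("age", ""), where)
        if age is None:
            raise ValidationError(f"{where}: age is required")
        scores = {}
        for test in MEMORY_TESTS:
            v = _parse_float(row.get(test, ""), where)
            if v is not None:
                scores[test] = v
        rec = SubjectRecord(
            subject_id=sid,
            group=row.get("group", ""),
            age=age,
            sex=row.get("sex", ""),
            tbv=tbv,
            age_at_onset=_parse_float(row.get("age_at_onset", ""), where),
            duration=_parse_float(row.get("duration", ""), where),
            eeg_laterality=row.get("eeg_laterality") or "unknown",
            language_dominant_hemisphere=row.get("language_dominant_hemisphere") or "unknown",
            memory_scores=scores,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        subjects[sid] = rec
    return subjects


def write_subjects(subjects: Mapping[str, SubjectRecord], path: str | Path) -> None:
    rows = []
    for rec in subjects.values():
        rows.append([
            rec.subject_id, rec.group, rec.age, rec.sex, rec.tbv,
            rec.age_at_onset, rec.duration, rec.eeg_laterality,
            rec.language_dominant_hemisphere,
            *[rec.memory_scores.get(t) for t in MEMORY_TESTS],
        ])
    _write_table(path, _SUBJECT_COLUMNS, rows)


# ---------------------------------------------------------------------------
# volumes

_VOLUME_COLUMNS = ["subject_id", "hemisphere", *SUBFIELDS, "total", "excluded", "reason"]


def read_volumes(path: str | Path) -> dict[tuple[str, str], SubfieldVolumes]:
    header, rows = _read_rows(path)
    unknown = [h for h in header if h not in _VOLUME_COLUMNS]
    if unknown:
        raise ValidationError(
            f"{path}: unknown columns {unknown}; accepted: {_VOLUME_COLUMNS}"
        )
    out: dict[tuple[str, str], SubfieldVolumes] = {}
    for lineno, row in rows:
        where = f"{path}:{lineno}"
        rec = SubfieldVolumes(
            subject_id=row.get("subject_id", ""),
            hemisphere=row.get("hemisphere", ""),
            volumes={s: _parse_float(row.get(s, ""), where) for s in SUBFIELDS if s in row},
            total_hippocampal_volume=_parse_float(row.get("total", ""), where),
            excluded=_parse_bool(row.get("excluded", "")),
            reason=row.get("reason", ""),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        key = (rec.subject_id, rec.hemisphere)
        if key in out:
            raise ValidationError(f"{where}: duplicate subject x hemisphere {key}")
        out[key] = rec
    return out


def write_volumes(volumes: Mapping[tuple[str, str], SubfieldVolumes], path: str | Path) -> None:
    rows = []
    for rec in volumes.values():
        rows.append([
            rec.subject_id, rec.hemisphere,
            *[rec.volumes.get(s) for s in SUBFIELDS],
            rec.total_hippocampal_volume, rec.excluded, rec.reason,
        ])
    _write_table(path, _VOLUME_COLUMNS, rows)


# ---------------------------------------------------------------------------
# MRS panels

_MRS_COLUMNS = [
    "subject_id", "hemisphere", *METABOLITES,
    *[f"crlb_{m}" for m in METABOLITES],
    "f_csf", "f_gm", "f_wm", "excluded", "reason",
]


def read_mrs(path: str | Path) -> dict[tuple[str, str], MetabolitePanel]:
    header, rows = _read_rows(path)
    unknown = [h for h in header if h not in _MRS_COLUMNS]
    if unknown:
        raise ValidationError(
            f"{path}: unknown columns {unknown}; accepted: {_MRS_COLUMNS}"
        )
    out: dict[tuple[str, str], MetabolitePanel] = {}
    for lineno, row in rows:
        where = f"{path}:{lineno}"
        rec = MetabolitePanel(
            subject_id=row.get("subject_id", ""),
            hemisphere=row.get("hemisphere", ""),
            concentrations={m: _parse_float(row.get(m, ""), where)
                            for m in METABOLITES if m in row},
            crlb={m: _parse_float(row.get(f"crlb_{m}", ""), where)
                  for m in METABOLITES if f"crlb_{m}" in row},
            f_csf=_parse_float(row.get("f_csf", ""), where),
            f_gm=_parse_float(row.get("f_gm", ""), where),
            f_wm=_parse_float(row.get("f_wm", ""), where),
            excluded=_parse_bool(row.get("excluded", "")),
            reason=row.get("reason", ""),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        key = (rec.subject_id, rec.hemisphere)
        if key in out:
            raise ValidationError(f"{where}: duplicate subject x hemisphere {key}")
        out[key] = rec
    return out


def write_mrs(mrs: Mapping[tuple[str, str], MetabolitePanel], path: str | Path) -> None:
    rows = []
    for rec in mrs.values():
        rows.append([
            rec.subject_id, rec.hemisphere,
            *[rec.concentrations.get(m) for m in METABOLITES],
            *[rec.crlb.get(m) for m in METABOLITES],
            rec.f_csf, rec.f_gm, rec.f_wm, rec.excluded, rec.reason,
        ])
    _write_table(path, _MRS_COLUMNS, rows)


# ---------------------------------------------------------------------------
# cohort-level entry points

def read_measurement_tables(subjects_path: str | Path,
                            volumes_path: str | Path | None = None,
                            mrs_path: str | Path | None = None) -> Cohort:
    """Load and validate a cohort from its measurement tables.

    Missing hemispheres stay represented as records flagged ``excluded``;
    they are never silently dropped. Any invariant violation raises
    :class:`ValidationError` naming file and line.
    """
    cohort = Cohort(subjects=read_subjects(subjects_path))
    if volumes_path is not None:
        cohort.volumes = read_volumes(volumes_path)
    if mrs_path is not None:
        cohort.mrs = read_mrs(mrs_path)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"subjects": out_dir / "subjects.tsv"}
    write_subjects(cohort.subjects, paths["subjects"])
    if cohort.volumes:
        paths["volumes"] = out_dir / "volumes.tsv"
        write_volumes(cohort.volumes, paths["volumes"])
    if cohort.mrs:
        paths["mrs"] = out_dir / "mrs.tsv"
        write_mrs(cohort.mrs, paths["mrs"])
    return paths


def write_results(rows: list[Mapping[str, Any]], path: str | Path,
                  columns: list[str] | None = None,
                  column_dict: Mapping[str, str] | None = None) -> None:
    """Write a flat results table with an optional column-dictionary header.

    An empty ``rows`` list with explicit ``columns`` yields a header-only
    file; without columns it is an error.
    """
    if columns is None:
        if not rows:
            raise ValidationError("cannot write an empty table without explicit columns")
        columns = list(rows[0].keys())
    _write_table(path, columns, ([r.get(c) for c in columns] for r in rows),
                 column_dict=column_dict)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
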