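"""Single-case inference by permutation with sign flipping.

Each patient's measures are tested one at a time against the control
group. The observed statistic is the standardized case deviation

    T = (x_case - mean_controls) / (sd_controls * sqrt(1 + 1/n_controls))

(the Crawford-Howell case-indicator contrast). Label permutations alone
allow only n+1 shufflings (a p-value floor of 1/(n+1)); assuming the
model residuals are symmetric about zero, sign flipping multiplies the
number of shufflings by 2^(n+1).

The null is built from the residuals of the fitted case-indicator model:
the case's residual is 0 (its indicator absorbs it) and the controls'
residuals are their deviations from the control mean. Each shuffling
rotates one residual into the case slot and applies one of the 2^(n+1)
sign patterns; pseudo-data are reconstructed and T recomputed. The orbit
therefore has (n+1) * 2^(n+1) elements, enumerated exhaustively when that
fits the configured bound and sampled uniformly otherwise. p-values use
the (b+1)/(m+1) convention in both modes, so p is never 0, and the null
distribution depends only on the controls — moving the case further from
the control mean can never increase the one-tailed p.

A naive scheme that keeps the case's own (null-model) residual in the
case slot and only flips signs is dramatically conservative: the observed
case deviation then reappears in essentially every pseudo-sample and the
null scales with the very effect under test (empirical type-I error ~0,
power at a 4-SD effect ~0.1). The shuffling orbit used here is calibrated
(type-I error ~alpha) and powerful; see the test suite's calibration
checks.

Volume and concentration measures (strictly positive, right-skewed) are
Box-Cox transformed before testing; asymmetry indices are not, since they
can be non-positive. The battery's default lambda is 0 (a log transform)
fixed a priori: estimating lambda by maximum likelihood per test either
lets the transform normalize away the case's own abnormality (lambda fit
on the pooled case+controls sample) or overfits the small control sample
(lambda fit on controls only, anticonservative). Both MLE policies remain
available through the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, stats

from .core_io import (
    METABOLITES_REPORTED,
    SUBFIELDS,
    AnalysisConfig,
    ValidationError,
)
from .derived_measures import DerivedCohort

__all__ = [
    "CaseTestResult",
    "ConcordanceLabel",
    "boxcox_transform",
    "sign_flip_test",
    "run_case_battery",
    "fwe_correct",
    "maxstat_family_fwe",
    "classify_concordance",
    "family_of",
    "default_battery_variables",
]

#: relative tolerance used when counting |T_flip| >= |T_obs| ties
_TIE_RTOL = 1e-9


@dataclass
class CaseTestResult:
    """One variable's single-case permutation outcome."""

    subject_id: str
    variable: str
    observed: float
    transformed: float
    statistic: float
    direction: str  # "decreased" | "increased"
    p_uncorrected: float
    family: str = ""
    family_size: int = 0
    fwe_significant: bool | None = None
    null_size: int = 0
    null_mode: str = ""  # "exhaustive" | "monte_carlo"
    seed: int | None = None
    n_controls: int = 0
    boxcox_lambda: float | None = None
    untestable: bool = False
    note: str = ""


@dataclass
class ConcordanceLabel:
    subject_id: str
    modality: str  # "volumetry" | "mrs"
    label: str  # concordant | discordant | bilateral | uninformative
    detail: str = ""


# ---------------------------------------------------------------------------
# Box-Cox preconditioning

def boxcox_transform(values: Sequence[float] | np.ndarray,
                     lmbda: float | str = "mle") -> tuple[np.ndarray, float]:
    """Power-transform positive data: (x^l - 1)/l, or log(x) at l = 0.

    ``lmbda="mle"`` fits lambda by profile maximum likelihood on the given
    sample. The transform is strictly increasing for any lambda, so ranks
    are preserved.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("boxcox_transform: empty sample")
    if np.any(x <= 0):
        raise ValidationError(
            "boxcox_transform requires strictly positive values; "
            "exclude this variable from transformation"
        )
    if isinstance(lmbda, str):
        if lmbda != "mle":
            raise ValidationError(f"unknown lambda spec {lmbda!r}")
        transformed, lam = stats.boxcox(x)
        return np.asarray(transformed, float), float(lam)
    lam = float(lmbda)
    return np.asarray(special.boxcox(x, lam), float), lam


# ---------------------------------------------------------------------------
# the sign-flip test

def _case_stat(case: float, controls: np.ndarray) -> float:
    n = controls.size
    sd = controls.std(ddof=1)
    if sd == 0:
        return 0.0 if case == controls.mean() else math.copysign(math.inf, case - controls.mean())
    return (case - controls.mean()) / (sd * math.sqrt(1.0 + 1.0 / n))


def _null_residuals(controls: np.ndarray) -> np.ndarray:
    """Residuals of the fitted case-indicator model: 0 for the case slot,
    centered deviations for the controls."""
    return np.concatenate(([0.0], controls - controls.mean()))


def _flip_stats(pseudo: np.ndarray) -> np.ndarray:
    """T for each pseudo-sample (rows); the case occupies column 0."""
    pcase = pseudo[:, 0]
    pc = pseudo[:, 1:]
    n = pc.shape[1]
    m = pc.mean(axis=1)
    sd = pc.std(axis=1, ddof=1)
    num = pcase - m
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / (sd * math.sqrt(1.0 + 1.0 / n))
    # degenerate pseudo-controls: sd 0 -> +-inf (counts as extreme), 0/0 -> 0
    t[np.isnan(t)] = 0.0
    return t


def _exhaustive_orbit(resid: np.ndarray) -> np.ndarray:
    """All (n+1) * 2^(n+1) pseudo-samples: rotation x sign pattern."""
    k = resid.size
    n_signs = 2 ** k
    bits = (np.arange(n_signs)[:, None] >> np.arange(k)) & 1
    signs = bits * 2 - 1
    blocks = []
    for j in range(k):
        rot = np.concatenate(([resid[j]], np.delete(resid, j)))
        blocks.append(signs * rot)
    return np.vstack(blocks)


def _mc_orbit(resid: np.ndarray, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    k = resid.size
    signs = rng.integers(0, 2, size=(n_mc, k)) * 2 - 1
    j = rng.integers(0, k, size=n_mc)
    rotations = np.stack([np.concatenate(([resid[i]], np.delete(resid, i)))
                          for i in range(k)])
    return signs * rotations[j]


def exhaustive_orbit_size(n_controls: int) -> int:
    return (n_controls + 1) * 2 ** (n_controls + 1)


def sign_flip_test(case_value: float,
                   control_values: Sequence[float] | np.ndarray,
                   tails: str = "two",
                   n_max_exhaustive: int = 2 ** 18,
                   n_mc: int = 10000,
                   seed: int = 0) -> CaseTestResult:
    """Test one case value against a control sample by sign-flipping
    permutation (see the module docstring for the shuffling scheme).

    Returns a :class:`CaseTestResult` with ``subject_id``/``variable``
    left blank (the battery fills them in).
    """
    controls = np.asarray(control_values, dtype=float)
    n = controls.size
    # the battery enforces >= 5 usable controls; the primitive itself only
    # needs a defined sample SD
    if n < 3:
        raise ValidationError(f"need >= 3 controls, got {n}")
    if controls.std(ddof=1) == 0:
        raise ValidationError("zero control variance")
    if tails not in ("two", "one"):
        raise ValidationError(f"tails must be two|one, got {tails!r}")

    t_obs = _case_stat(case_value, controls)
    resid = _null_residuals(controls)

    orbit_size = exhaustive_orbit_size(n)
    if orbit_size <= n_max_exhaustive:
        t_flip = _flip_stats(_exhaustive_orbit(resid))
        null_mode, null_size, used_seed = "exhaustive", orbit_size, None
    else:
        if n_mc < 100:
            raise ValidationError(f"n_mc must be >= 100, got {n_mc}")
        rng = np.random.default_rng(seed)
        t_flip = _flip_stats(_mc_orbit(resid, n_mc, rng))
        null_mode, null_size, used_seed = "monte_carlo", n_mc, seed
    b = _count_extreme(t_flip, t_obs, tails)
    p = (b + 1) / (null_size + 1)

    return CaseTestResult(
        subject_id="",
        variable="",
        observed=case_value,
        transformed=case_value,
        statistic=t_obs,
        direction="decreased" if case_value < controls.mean() else "increased",
        p_uncorrected=float(p),
        null_size=null_size,
        null_mode=null_mode,
        seed=used_seed,
        n_controls=n,
    )


def _count_extreme(t_flip: np.ndarray, t_obs: float, tails: str) -> int:
    tol = _TIE_RTOL * max(1.0, abs(t_obs))
    if tails == "two":
        return int(np.count_nonzero(np.abs(t_flip) >= abs(t_obs) - tol))
    # one-tailed in the observed direction, using signed T
    if t_obs >= 0:
        return int(np.count_nonzero(t_flip >= t_obs - tol))
    return int(np.count_nonzero(t_flip <= t_obs + tol))


# ---------------------------------------------------------------------------
# batteries and families

def family_of(variable: str) -> str:
    """Map a variable name to its FWE family."""
    parts = variable.split(".")
    if parts[-1] == "volume":
        return "subfield_volumes"
    if parts[-1] == "conc":
        return "metabolite_concentrations"
    if parts[-1] == "asymmetry":
        return "subfield_asymmetry" if parts[0] in SUBFIELDS else "metabolite_asymmetry"
    raise ValidationError(f"cannot assign variable {variable!r} to a family")


def default_battery_variables(derived: DerivedCohort) -> list[str]:
    """The standard battery: 5 subfields and 6 metabolites per hemisphere
    plus their asymmetry indices, restricted to variables actually present."""
    wanted = []
    for hemi in ("left", "right"):
        wanted += [f"{hemi}.{s}.volume" for s in SUBFIELDS]
    wanted += [f"{s}.asymmetry" for s in SUBFIELDS]
    for hemi in ("left", "right"):
        wanted += [f"{hemi}.{m}.conc" for m in METABOLITES_REPORTED]
    wanted += [f"{m}.asymmetry" for m in METABOLITES_REPORTED]
    return [v for v in wanted if v in derived.values]


def _residualize_on_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(ages), ages])
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def run_case_battery(patient_id: str,
                     derived: DerivedCohort,
                     control_ids: Iterable[str],
                     config: AnalysisConfig | None = None,
                     variables: Sequence[str] | None = None,
                     ages: Mapping[str, float] | None = None,
                     ) -> list[CaseTestResult]:
    """Test every battery variable for one patient against the controls.

    Controls missing a variable (excluded hemisphere, failed QC) are
    dropped per variable; a variable with fewer than 5 usable controls is
    returned flagged ``untestable`` rather than silently omitted.
    ``family_size`` counts the testable variables in each family, and
    Bonferroni FWE flags are filled in before returning.
    """
    config = config or AnalysisConfig()
    config.validate()
    control_ids = list(control_ids)
    if variables is None:
        variables = default_battery_variables(derived)

    results: list[CaseTestResult] = []
    for variable in variables:
        values = derived.values.get(variable, {})
        if patient_id not in values:
            continue  # patient has no measurement for this variable
        case_value = values[patient_id]
        ctrl_ids = [c for c in control_ids if c in values]
        controls = np.array([values[c] for c in ctrl_ids], dtype=float)
        family = family_of(variable)

        if controls.size < 5:
            results.append(CaseTestResult(
                subject_id=patient_id, variable=variable, observed=case_value,
                transformed=case_value, statistic=math.nan, direction="decreased",
                p_uncorrected=math.nan, family=family, untestable=True,
                n_controls=int(controls.size),
                note=f"only {controls.size} usable controls (need >= 5)",
            ))
            continue

        is_asymmetry = variable.endswith(".asymmetry")
        transform = (not is_asymmetry or config.boxcox_apply_to_asymmetry) \
            and config.boxcox_policy != "none"
        case_t, ctrl_t, lam = case_value, controls, None
        if transform:
            pooled = np.concatenate(([case_value], controls))
            if config.boxcox_policy == "fixed_log":
                # lambda fixed a priori: a data-dependent lambda either leaks
                # the case into the transform (MLE on the pooled sample can
                # normalize away the very abnormality under test) or overfits
                # the small control sample (anticonservative); see module tests
                transformed, lam = boxcox_transform(pooled, 0.0)
            elif config.boxcox_policy == "mle_pooled":
                transformed, lam = boxcox_transform(pooled, "mle")
            else:  # mle_controls
                _, lam = boxcox_transform(controls, "mle")
                transformed, lam = boxcox_transform(pooled, lam)
            case_t, ctrl_t = float(transformed[0]), transformed[1:]

        if config.age_residualize:
            if ages is None:
                raise ValidationError("age_residualize requires per-subject ages")
            pooled_vals = np.concatenate(([case_t], ctrl_t))
            pooled_ages = np.array([ages[patient_id]] + [ages[c] for c in ctrl_ids], float)
            res = _residualize_on_age(pooled_vals, pooled_ages)
            case_t, ctrl_t = float(res[0]), res[1:]

        r = sign_flip_test(case_t, ctrl_t, tails=config.tails,
                           n_max_exhaustive=config.n_max_exhaustive,
                           n_mc=config.n_mc, seed=config.rng_seed)
        r.subject_id = patient_id
        r.variable = variable
        r.observed = case_value
        r.transformed = case_t
        r.family = family
        r.boxcox_lambda = lam
        results.append(r)

    # family sizes over testable variables only
    sizes: dict[str, int] = {}
    for r in results:
        if not r.untestable:
            sizes[r.family] = sizes.get(r.family, 0) + 1
    for r in results:
        r.family_size = sizes.get(r.family, 0)

    return fwe_correct(results, method=config.fwe_method, alpha=config.alpha)


def fwe_correct(results: list[CaseTestResult], method: str = "bonferroni",
                alpha: float = 0.05) -> list[CaseTestResult]:
    """Set ``fwe_significant`` per family.

    Bonferroni: significant iff p <= alpha / family_size. The maxstat
    permutation alternative is exposed via :func:`maxstat_family_fwe`
    (it needs the raw data, not just p-values).
    """
    if method == "maxstat":
        raise ValidationError(
            "maxstat correction operates on shared sign-flip patterns; "
            "use maxstat_family_fwe with the family's data matrix"
        )
    if method != "bonferroni":
        raise ValidationError(f"unknown FWE method {method!r}")
    by_family: dict[str, list[CaseTestResult]] = {}
    for r in results:
        if not r.untestable:
            by_family.setdefault(r.family, []).append(r)
    for family, members in by_family.items():
        sizes = {m.family_size for m in members}
        if len(sizes) != 1:
            raise ValidationError(f"mixed family sizes in family {family!r}: {sorted(sizes)}")
        k = sizes.pop()
        for m in members:
            m.fwe_significant = bool(m.p_uncorrected <= alpha / k)
    return results


def maxstat_family_fwe(case_values: Mapping[str, float],
                       control_values: Mapping[str, Sequence[float]],
                       n_max_exhaustive: int = 2 ** 18,
                       n_mc: int = 10000,
                       seed: int = 0) -> dict[str, float]:
    """Permutation-native FWE: joint null of the family's max |T|.

    All variables must share the same number of controls (same subjects in
    the same order) so one shuffling (rotation + sign pattern) applies
    across the family. Returns family-wise-corrected p per variable.
    """
    variables = list(case_values)
    if set(variables) != set(control_values):
        raise ValidationError("case and control variable sets differ")
    mats = [np.asarray(control_values[v], float) for v in variables]
    ns = {m.size for m in mats}
    if len(ns) != 1:
        raise ValidationError(f"maxstat requires a shared control set; sizes {sorted(ns)}")
    n = ns.pop()
    if n < 5:
        raise ValidationError(f"need >= 5 controls, got {n}")

    orbit_size = exhaustive_orbit_size(n)
    exhaustive = orbit_size <= n_max_exhaustive
    if exhaustive:
        total = orbit_size
        shared = None
    else:
        rng = np.random.default_rng(seed)
        total = n_mc
        # one draw of (rotation, signs) shared across the family
        shared = (rng.integers(0, k_ := n + 1, size=n_mc),
                  rng.integers(0, 2, size=(n_mc, n + 1)) * 2 - 1)

    t_obs: dict[str, float] = {}
    max_abs = np.zeros(total)
    for v, ctrl in zip(variables, mats):
        if ctrl.std(ddof=1) == 0:
            raise ValidationError(f"zero control variance for {v}")
        t_obs[v] = _case_stat(float(case_values[v]), ctrl)
        resid = _null_residuals(ctrl)
        if exhaustive:
            # enumeration order (rotation-major, sign-minor) is identical
            # across variables, so row i is the same shuffling for all
            t_flip = _flip_stats(_exhaustive_orbit(resid))
        else:
            j, signs = shared
            rotations = np.stack([np.concatenate(([resid[i]], np.delete(resid, i)))
                                  for i in range(n + 1)])
            t_flip = _flip_stats(signs * rotations[j])
        np.maximum(max_abs, np.abs(t_flip), out=max_abs)

    out: dict[str, float] = {}
    for v in variables:
        tol = _TIE_RTOL * max(1.0, abs(t_obs[v]))
        b = int(np.count_nonzero(max_abs >= abs(t_obs[v]) - tol))
        out[v] = (b + 1) / (total + 1)
    return out


# ---------------------------------------------------------------------------
# concordance labelling

_VOLUMETRY_SUFFIXES = ("volume",)


def _modality(variable: str) -> str:
    parts = variable.split(".")
    if parts[-1] == "volume":
        return "volumetry"
    if parts[-1] == "conc":
        return "mrs"
    # asymmetry: modality follows the underlying measure
    return "volumetry" if parts[0] in SUBFIELDS else "mrs"


def _finding_hemisphere(result: CaseTestResult) -> str:
    """Hemisphere a significant finding points to.

    Lateralized variables point to their own hemisphere. A shifted
    asymmetry index points to the relatively reduced side: decreased index
    (L < R relative to controls) points left, increased points right.
    """
    parts = result.variable.split(".")
    if parts[0] in ("left", "right"):
        return parts[0]
    return "left" if result.direction == "decreased" else "right"


def classify_concordance(subject_id: str,
                         results: Iterable[CaseTestResult],
                         eeg_laterality: str,
                         modality: str,
                         alpha: float = 0.05) -> ConcordanceLabel:
    """Label one subject x modality against EEG lateralization.

    No significant lateralized finding -> uninformative; findings confined
    to the onset hemisphere -> concordant; confined to the opposite
    hemisphere -> discordant; both hemispheres -> bilateral (concordant
    when EEG onset is itself bilateral).
    """
    if eeg_laterality == "unknown":
        raise ValidationError(f"{subject_id}: label withheld, EEG laterality unknown")
    relevant = [r for r in results
                if not r.untestable and _modality(r.variable) == modality]
    sig = [r for r in relevant if r.p_uncorrected < alpha]
    hemis = {_finding_hemisphere(r) for r in sig}
    detail = "; ".join(f"{r.variable} {r.direction} p={r.p_uncorrected:.4g}" for r in sig)

    if not hemis:
        label = "uninformative"
    elif len(hemis) == 2:
        label = "concordant" if eeg_laterality == "bilateral" else "bilateral"
    else:
        (h,) = hemis
        if eeg_laterality == "bilateral" or h == eeg_laterality:
            label = "concordant"
        else:
            label = "discordant"
    return ConcordanceLabel(subject_id=subject_id, modality=modality,
                            label=label, detail=detail)
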