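import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippocase import (
    AnalysisConfig,
    ValidationError,
    boxcox_transform,
    classify_concordance,
    fwe_correct,
    maxstat_family_fwe,
    run_case_battery,
    sign_flip_test,
)
from hippocase.derived_measures import DerivedCohort
from hippocase.single_case_inference import CaseTestResult, family_of


# ---------------------------------------------------------------------------
# independent brute-force oracle (pure python, enumerates all 2^(n+1) patterns)

def _stat(case, controls):
    n = len(controls)
    m = sum(controls) / n
    var = sum((v - m) ** 2 for v in controls) / (n - 1)
    if var == 0:
        return 0.0 if case == m else math.copysign(math.inf, case - m)
    return (case - m) / (math.sqrt(var) * math.sqrt(1 + 1 / n))


def brute_force_p(case, controls, tails="two"):
    """Enumerate the full shuffling orbit: every rotation of the n+1
    null-model residuals (case residual 0, controls centered) into the
    case slot x every sign pattern; p = (b + 1) / (orbit + 1)."""
    n = len(controls)
    mean_c = sum(controls) / n
    resid = [0.0] + [v - mean_c for v in controls]
    t_obs = _stat(case, list(controls))
    tol = 1e-9 * max(1.0, abs(t_obs))
    count = total = 0
    for j in range(n + 1):
        rotated = [resid[j]] + resid[:j] + resid[j + 1:]
        for signs in itertools.product((1, -1), repeat=n + 1):
            pseudo = [s * r for s, r in zip(signs, rotated)]
            t = _stat(pseudo[0], pseudo[1:])
            total += 1
            if tails == "two":
                hit = abs(t) >= abs(t_obs) - tol
            elif t_obs >= 0:
                hit = t >= t_obs - tol
            else:
                hit = t <= t_obs + tol
            count += hit
    return (count + 1) / (total + 1)


# ---------------------------------------------------------------------------
# sign_flip_test

def test_case_at_mean_symmetric_controls_p_one():
    r = sign_flip_test(0.0, [-1.0, 0.0, 1.0])
    assert r.statistic == 0.0
    assert r.p_uncorrected == 1.0


def test_exhaustive_equals_brute_force_tiny():
    controls = [9.0, 10.0, 11.0]
    r = sign_flip_test(30.0, controls)
    # orbit: 4 rotations x 2^4 sign patterns
    assert r.null_mode == "exhaustive" and r.null_size == 64
    assert r.p_uncorrected == brute_force_p(30.0, controls)


@pytest.mark.parametrize("n_controls", [5, 8, 10])
@pytest.mark.parametrize("tails", ["two", "one"])
def test_exhaustive_equals_brute_force_random(n_controls, tails, rng):
    for _ in range(3):
        controls = rng.normal(10, 2, n_controls)
        case = rng.normal(10, 4)
        r = sign_flip_test(case, controls, tails=tails)
        assert r.null_mode == "exhaustive"
        assert r.p_uncorrected == brute_force_p(case, list(controls), tails=tails)


def test_monte_carlo_converges_to_exhaustive(rng):
    controls = list(rng.normal(10, 1, 8))
    ex = sign_flip_test(13.0, controls)
    assert ex.null_mode == "exhaustive"
    r = sign_flip_test(13.0, controls, n_max_exhaustive=8, n_mc=10000, seed=5)
    assert r.null_mode == "monte_carlo" and r.seed == 5
    # allow for the +1 conventions of both estimates on top of sampling error
    bound = (3 * math.sqrt(ex.p_uncorrected * (1 - ex.p_uncorrected) / 10000)
             + 2 / 10001 + 1 / (ex.null_size + 1))
    assert abs(r.p_uncorrected - ex.p_uncorrected) <= bound


def test_monte_carlo_bound_holds_across_seeds(rng):
    """|p_mc - p_exhaustive| <= 3*sqrt(p(1-p)/m) in ~all seeded trials."""
    controls = list(rng.normal(10, 2, 8))
    case = 14.0
    exact = sign_flip_test(case, controls).p_uncorrected
    n_mc = 2000
    bound = 3 * math.sqrt(exact * (1 - exact) / n_mc) + 2 / (n_mc + 1)
    ok = sum(
        abs(sign_flip_test(case, controls, n_max_exhaustive=8, n_mc=n_mc,
                           seed=s).p_uncorrected - exact) <= bound
        for s in range(50))
    assert ok >= 49


def test_p_floor_two_tailed():
    """Extreme case: p hits the floor set by the shuffling count."""
    controls = [9.0, 10.0, 11.0, 10.5, 9.5]
    r = sign_flip_test(1e6, controls)
    assert r.null_size == 6 * 2 ** 6
    assert r.p_uncorrected == 1 / (r.null_size + 1)


def test_direction():
    assert sign_flip_test(5.0, [9, 10, 11, 10, 9]).direction == "decreased"
    assert sign_flip_test(15.0, [9, 10, 11, 10, 9]).direction == "increased"


def test_one_tailed_monotone_in_case_value(rng):
    controls = list(rng.normal(0, 1, 8))
    cases = [0.5, 1.0, 2.0, 3.0, 5.0]
    ps = [sign_flip_test(c, controls, tails="one").p_uncorrected for c in cases]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_sign_flip_errors():
    with pytest.raises(ValidationError, match="controls"):
        sign_flip_test(1.0, [1.0, 2.0])
    with pytest.raises(ValidationError, match="variance"):
        sign_flip_test(1.0, [2.0, 2.0, 2.0])
    with pytest.raises(ValidationError, match="n_mc"):
        sign_flip_test(1.0, [1, 2, 3, 4, 5], n_max_exhaustive=8, n_mc=50)


def test_power_at_4sd(rng):
    """Case 4 control-SD below the mean, 10 controls: detected >= 80%."""
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        controls = rng.normal(0, 1, 10)
        case = rng.normal(-4, 1)
        r = sign_flip_test(case, controls)
        hits += (r.p_uncorrected < 0.05) and r.direction == "decreased"
    assert hits / n_rep >= 0.8


# ---------------------------------------------------------------------------
# Box-Cox

def test_boxcox_lambda_one():
    out, lam = boxcox_transform([5.0], lmbda=1.0)
    assert out[0] == pytest.approx(4.0)


def test_boxcox_lambda_zero_log():
    out, _ = boxcox_transform([math.e], lmbda=0.0)
    assert out[0] == pytest.approx(1.0)


def test_boxcox_mle_lognormal_near_zero(rng):
    """Grid-search profile-likelihood oracle agrees; lambda near 0."""
    x = rng.lognormal(1.0, 0.5, 200)

    def llf(lam):
        if lam == 0:
            y = np.log(x)
        else:
            y = (x ** lam - 1) / lam
        n = len(x)
        return -n / 2 * math.log(y.var()) + (lam - 1) * np.log(x).sum()

    grid = np.arange(-2, 2.001, 0.01)
    lam_grid = grid[int(np.argmax([llf(g) for g in grid]))]
    _, lam = boxcox_transform(x, "mle")
    assert abs(lam - lam_grid) < 0.02
    assert abs(lam) < 0.25


def test_boxcox_nonpositive_errors():
    with pytest.raises(ValidationError, match="positive"):
        boxcox_transform([1.0, -0.5, 2.0])


@given(st.lists(st.floats(0.01, 1e4), min_size=4, max_size=20, unique=True),
       st.floats(-2, 2))
@settings(max_examples=100)
def test_boxcox_rank_preserving(values, lam):
    ordered = np.sort(values)
    out, _ = boxcox_transform(ordered, lmbda=lam)
    assert np.all(np.diff(out) >= 0)


# ---------------------------------------------------------------------------
# battery + FWE

def _derived_for_battery(rng, n_controls=10, patient_shift=None):
    """Full 32-variable derived table: 10 volumes, 5 subfield asymmetries,
    12 concentrations, 6 metabolite asymmetries."""
    from hippocase.core_io import METABOLITES_REPORTED, SUBFIELDS

    derived = DerivedCohort()
    control_ids = [f"C{i:02d}" for i in range(n_controls)]
    variables = ([f"{h}.{s}.volume" for h in ("left", "right") for s in SUBFIELDS]
                 + [f"{s}.asymmetry" for s in SUBFIELDS]
                 + [f"{h}.{m}.conc" for h in ("left", "right") for m in METABOLITES_REPORTED]
                 + [f"{m}.asymmetry" for m in METABOLITES_REPORTED])
    for v in variables:
        asym = v.endswith(".asymmetry")
        mean = 0.0 if asym else 100.0
        sd = 0.05 if asym else 10.0
        vals = {c: float(rng.normal(mean, sd)) for c in control_ids}
        case = float(np.mean(list(vals.values())))
        if patient_shift and v in patient_shift:
            case += patient_shift[v] * sd
        vals["P01"] = case
        derived.values[v] = vals
    return derived, control_ids


def test_battery_null_patient_no_findings(rng):
    derived, control_ids = _derived_for_battery(rng)
    results = run_case_battery("P01", derived, control_ids)
    assert len(results) == 33
    assert all(r.p_uncorrected > 0.05 for r in results)


def test_battery_family_sizes(rng):
    derived, control_ids = _derived_for_battery(rng)
    results = run_case_battery("P01", derived, control_ids)
    sizes = {r.family: r.family_size for r in results}
    assert sizes == {"subfield_volumes": 10, "subfield_asymmetry": 5,
                     "metabolite_concentrations": 12, "metabolite_asymmetry": 6}


def test_battery_detects_shifted_ca3(rng):
    derived, control_ids = _derived_for_battery(
        rng, patient_shift={"left.CA3.volume": -4.0})
    results = {r.variable: r for r in run_case_battery("P01", derived, control_ids)}
    r = results["left.CA3.volume"]
    assert r.p_uncorrected < 0.05 and r.direction == "decreased"


def test_battery_untestable_flagged(rng):
    derived, control_ids = _derived_for_battery(rng)
    # leave only 4 controls for one variable
    keep = control_ids[:4] + ["P01"]
    derived.values["left.CA1.volume"] = {
        k: v for k, v in derived.values["left.CA1.volume"].items() if k in keep}
    results = {r.variable: r for r in run_case_battery("P01", derived, control_ids)}
    r = results["left.CA1.volume"]
    assert r.untestable and "4 usable controls" in r.note
    # untestable variables do not count toward the family size
    assert results["right.CA1.volume"].family_size == 9


def test_battery_asymmetry_not_boxcoxed(rng):
    derived, control_ids = _derived_for_battery(rng)
    results = run_case_battery("P01", derived, control_ids)
    for r in results:
        if r.variable.endswith(".asymmetry"):
            assert r.boxcox_lambda is None
        else:
            assert r.boxcox_lambda is not None


def test_boxcox_on_asymmetry_errors_on_nonpositive(rng):
    derived, control_ids = _derived_for_battery(rng)
    cfg = AnalysisConfig(boxcox_apply_to_asymmetry=True)
    with pytest.raises(ValidationError, match="positive"):
        run_case_battery("P01", derived, control_ids, config=cfg)


def _result(p, family="metabolite_concentrations", size=12, variable="left.Gln.conc"):
    return CaseTestResult(subject_id="P01", variable=variable, observed=1.0,
                          transformed=1.0, statistic=-2.0, direction="decreased",
                          p_uncorrected=p, family=family, family_size=size)


def test_bonferroni_examples():
    r1 = _result(0.004, family="subfield_volumes", size=10, variable="left.CA1.volume")
    r2 = _result(0.02, family="subfield_asymmetry", size=5, variable="CA1.asymmetry")
    r3 = _result(0.02, family="metabolite_concentrations", size=12)
    fwe_correct([r1, r2, r3])
    assert r1.fwe_significant is True      # 0.004 <= 0.05/10
    assert r2.fwe_significant is False     # 0.02 > 0.05/5
    assert r3.fwe_significant is False     # 0.02 > 0.05/12


def test_fwe_mixed_family_sizes_error():
    r1 = _result(0.01, size=12)
    r2 = _result(0.01, size=11)
    with pytest.raises(ValidationError, match="mixed family sizes"):
        fwe_correct([r1, r2])


def test_family_of():
    assert family_of("left.CA3.volume") == "subfield_volumes"
    assert family_of("CA3.asymmetry") == "subfield_asymmetry"
    assert family_of("right.Gln.conc") == "metabolite_concentrations"
    assert family_of("Gln.asymmetry") == "metabolite_asymmetry"
    with pytest.raises(ValidationError):
        family_of("banana")


def test_maxstat_calibration(rng):
    """Familywise type-I error of maxstat correction near alpha."""
    n_fam, n_ctl, n_rep = 5, 10, 2000
    rejections = 0
    for _ in range(n_rep):
        case = {f"v{i}": float(rng.normal()) for i in range(n_fam)}
        ctrl = {f"v{i}": rng.normal(size=n_ctl) for i in range(n_fam)}
        p_fwe = maxstat_family_fwe(case, ctrl, n_max_exhaustive=2 ** 11)
        rejections += min(p_fwe.values()) <= 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_maxstat_requires_shared_controls(rng):
    case = {"a": 0.0, "b": 0.0}
    ctrl = {"a": rng.normal(size=10), "b": rng.normal(size=8)}
    with pytest.raises(ValidationError, match="shared control"):
        maxstat_family_fwe(case, ctrl)


# ---------------------------------------------------------------------------
# concordance

def _sig(variable, direction="decreased", p=0.02):
    return CaseTestResult(
        subject_id="P01", variable=variable, observed=1.0, transformed=1.0,
        statistic=-2.0, direction=direction, p_uncorrected=p,
        family=family_of(variable), family_size=10)


def test_concordant_left_onset_left_finding():
    label = classify_concordance("P01", [_sig("left.CA2.volume")], "left", "volumetry")
    assert label.label == "concordant"


def test_discordant_right_onset_left_finding():
    label = classify_concordance("P01", [_sig("left.CA3.volume")], "right", "volumetry")
    assert label.label == "discordant"


def test_uninformative_no_findings():
    label = classify_concordance("P01", [_sig("left.CA3.volume", p=0.4)],
                                 "left", "volumetry")
    assert label.label == "uninformative"


def test_bilateral_findings():
    results = [_sig("left.CA3.volume"), _sig("right.CA1.volume")]
    assert classify_concordance("P01", results, "left", "volumetry").label == "bilateral"
    assert classify_concordance("P01", results, "bilateral", "volumetry").label == "concordant"


def test_asymmetry_points_to_reduced_side():
    dec = _sig("CA1.asymmetry", direction="decreased")
    inc = _sig("CA1.asymmetry", direction="increased")
    assert classify_concordance("P01", [dec], "left", "volumetry").label == "concordant"
    assert classify_concordance("P01", [inc], "left", "volumetry").label == "discordant"


def test_concordance_respects_modality():
    label = classify_concordance("P01", [_sig("left.Gln.conc")], "left", "volumetry")
    assert label.label == "uninformative"  # MRS finding invisible to volumetry


def test_unknown_laterality_withheld():
    with pytest.raises(ValidationError, match="withheld"):
        classify_concordance("P01", [_sig("left.CA3.volume")], "unknown", "volumetry")
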