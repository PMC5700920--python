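import numpy as np
import pytest

from hippocase import (
    Cohort,
    GeneratorSpec,
    MetabolitePanel,
    SubfieldVolumes,
    SubjectRecord,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_subject(sid="S01", group="control", age=30.0, sex="F", tbv=1.1e6, **kw):
    return SubjectRecord(subject_id=sid, group=group, age=age, sex=sex, tbv=tbv, **kw)


def make_volumes(sid="S01", hemisphere="left", scale=1.0, **kw):
    vols = {"CA1": 1300.0 * scale, "CA2": 150.0 * scale, "CA3": 250.0 * scale,
            "DG": 650.0 * scale, "subiculum": 450.0 * scale}
    return SubfieldVolumes(subject_id=sid, hemisphere=hemisphere, volumes=vols,
                           total_hippocampal_volume=sum(vols.values()), **kw)


def make_panel(sid="S01", hemisphere="left", f_csf=0.1, **kw):
    conc = {"tNAA": 11.0, "Glu": 8.5, "Gln": 3.0, "tCho": 2.2, "tCr": 8.0,
            "Ins": 6.5, "GABA": 1.2, "Lac": 0.8}
    crlb = {m: 10.0 for m in conc}
    crlb["GABA"], crlb["Lac"] = 70.0, 80.0
    return MetabolitePanel(subject_id=sid, hemisphere=hemisphere,
                           concentrations=conc, crlb=crlb,
                           f_csf=f_csf, f_gm=(1 - f_csf) * 0.6,
                           f_wm=(1 - f_csf) * 0.4, **kw)


@pytest.fixture
def tiny_cohort():
    """3 subjects (2 controls + 1 patient) with both hemispheres measured."""
    cohort = Cohort()
    for i, group in enumerate(["control", "control", "patient"], start=1):
        sid = f"S{i:02d}"
        subj = make_subject(sid=sid, group=group, age=25.0 + i)
        if group == "patient":
            subj.eeg_laterality = "left"
            subj.age_at_onset = 12.0
            subj.duration = subj.age - 12.0
        cohort.subjects[sid] = subj
        for hemi in ("left", "right"):
            cohort.volumes[(sid, hemi)] = make_volumes(sid, hemi, scale=1.0 + 0.01 * i)
            cohort.mrs[(sid, hemi)] = make_panel(sid, hemi)
    cohort.validate()
    return cohort


@pytest.fixture(scope="session")
def default_synth():
    """One mid-sized synthetic cohort shared across read-only tests."""
    spec = GeneratorSpec(seed=7, n_controls=12, n_patients=6)
    return generate_cohort(spec)
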