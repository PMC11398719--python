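import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import connlife as cl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the synthetic generator warns when it drops absent-edge columns; that is
# expected behaviour in nearly every PLS test
warnings.filterwarnings(
    "ignore", message="dropping .* zero-variance brain variables")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def planted_study():
    """n=300 cohort, 64 regions, one intra-hemispheric planted edge
    component; QC applied.  Shared by the recovery-style tests."""
    spec = cl.default_study_spec(seed=0, n_subjects=300, n_regions=64)
    cohort, cset, gt = cl.generate_study(spec)
    cset, cohort, qc = cl.apply_qc(cset, cohort)
    return {"spec": spec, "cohort": cohort, "cset": cset, "gt": gt, "qc": qc}


@pytest.fixture(scope="session")
def planted_pls(planted_study):
    st = planted_study
    inp = cl.edge_pls_input(st["cset"], st["cohort"], mask=st["qc"].mask)
    model = cl.pls_fit(inp)
    planted = np.array(
        [st["gt"].effect_masks[0][i, j] for i, j in inp.edge_index])
    return {"input": inp, "model": model, "planted": planted}


@pytest.fixture
def tiny_fixture_dir(tmp_path):
    """A 3-subject, 8-region synthetic fixture written to disk."""
    spec = cl.SyntheticSpec(n_subjects=12, n_regions=8, seed=5)
    cohort, cset, _ = cl.generate_study(spec)
    cohort = cl.Cohort(cohort.table.iloc[:3])
    cset = cset.subset(cohort.ids)
    cl.write_fixture(cset, cohort, tmp_path, spec=spec)
    return tmp_path


def make_cohort(ages, fis=None, sexes=None, ids=None):
    n = len(ages)
    return cl.Cohort(pd.DataFrame({
        "id": ids or [f"s{k}" for k in range(n)],
        "age": ages,
        "sex": sexes or ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "fluid_intelligence": fis if fis is not None else [30.0] * n,
    }))


def make_cset(mats, ids=None, dists=None):
    mats = np.asarray(mats, float)
    s, n, _ = mats.shape
    half = n // 2
    regions = pd.DataFrame({
        "id": range(n),
        "label": [f"{'L' if k < half else 'R'}{k % half:03d}" for k in range(n)],
        "hemisphere": ["L"] * half + ["R"] * (n - half),
        "subcortical": [0] * n,
    })
    if dists is None:
        dists = np.where(mats > 0, 10.0, 0.0)
    return cl.ConnectomeSet(ids or [f"s{k}" for k in range(s)], mats, dists,
                            regions)
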