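import numpy as np
import pytest

from hipload import (
    NoiseParams,
    StanceParams,
    GaitParams,
    generate_cohort,
    generate_invivo_series,
    generate_stance_trial,
    reference_cohort,
)

CLEAN_STANCE = StanceParams(marker_noise_mm=0.0, soft_tissue_scale=0.0)
CLEAN_GAIT = GaitParams(marker_noise_mm=0.0, soft_tissue_scale=0.0)
CLEAN_NOISE = NoiseParams(noise_bw=0.0, misalignment_deg=0.0)


@pytest.fixture(scope="session")
def cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def h1l(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def clean_stance_trial(h1l):
    """Zero-noise one-leg-stance trial for the first subject."""
    return generate_stance_trial(h1l, CLEAN_STANCE, seed=1)


@pytest.fixture(scope="session")
def clean_stance_vivo(clean_stance_trial):
    return generate_invivo_series(clean_stance_trial.truth, CLEAN_NOISE, seed=1)


@pytest.fixture(scope="session")
def noisy_cohort_pairs(cohort):
    """Default-condition synthetic cohort: 10 subjects, both activities."""
    return generate_cohort(cohort, seed=0)


@pytest.fixture(scope="session")
def clean_cohort_pairs(cohort):
    """Zero-noise cohort with noise-free pseudo-in-vivo measurements."""
    return generate_cohort(
        cohort,
        stance_params=CLEAN_STANCE,
        gait_params=CLEAN_GAIT,
        noise_params=CLEAN_NOISE,
        seed=0,
    )


def assert_models_equal(a, b):
    assert len(a.segments) == len(b.segments)
    assert a.hjw == b.hjw and a.hjw_mode == b.hjw_mode
    for sa, sb in zip(a.segments, b.segments):
        assert sa.name == sb.name
        np.testing.assert_allclose(sa.com_offset, sb.com_offset, atol=1e-12)
        assert sa.mass == pytest.approx(sb.mass)
        assert sa.length == pytest.approx(sb.length)
    for fa, fb in zip(a.fascicles, b.fascicles):
        assert fa.name == fb.name
        assert fa.pcsa == pytest.approx(fb.pcsa)
        for (na, pa), (nb, pb) in zip(fa.path, fb.path):
            assert na == nb
            np.testing.assert_allclose(pa, pb, atol=1e-12)
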