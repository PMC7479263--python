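import numpy as np
import pytest

from rpmap import AnnotatorProfile, PhantomConfig


def quiet_config(**kw) -> PhantomConfig:
    """Noise-free phantom: density exactly equals class means, features are
    exact affine functions of density."""
    kw.setdefault("density_sd", 0.0)
    kw.setdefault("lesion_density_jitter", 0.0)
    kw.setdefault("feature_noise_sd", np.zeros(6))
    kw.setdefault("feature_noise_corr_sd", np.zeros(6))
    return PhantomConfig(**kw)


def identity_profile(name="obs", seed_offset=0) -> AnnotatorProfile:
    return AnnotatorProfile(boundary_jitter_vox=0.0, detection_prob=1.0,
                            confusion=np.eye(6), annotates_atrophy=True,
                            seed_offset=seed_offset, name=name)


@pytest.fixture
def small_cfg():
    """Tiny deterministic cohort used across modules."""
    return PhantomConfig(n_patients=2, slides_per_patient=2, seed=7)


@pytest.fixture
def quiet_slide():
    """One noise-free slide with at least one lesion of each broad grade."""
    from rpmap import generate_cohort

    cfg = quiet_config(n_patients=1, slides_per_patient=1, seed=11,
                       lesion_count_mean=5.0)
    return generate_cohort(cfg)[0], cfg
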