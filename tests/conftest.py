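from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Generator config with every stochastic term switched off."""
    from olivegrade.synthetic_data import CompoundLevel, SyntheticConfig

    cfg = SyntheticConfig(
        rt_jitter_sd=0.0,
        stretch_sd=0.0,
        noise_sd=0.0,
        intra_day_cv=0.0,
        intra_day_jitter_sd=0.0,
        inter_day_cv=0.0,
        inter_day_gain_cv=0.0,
        inter_day_jitter_sd=0.0,
    )
    cfg.category_profiles = {
        cat: {name: CompoundLevel(level.mean, 0.0) for name, level in profile.items()}
        for cat, profile in cfg.category_profiles.items()
    }
    return cfg


@pytest.fixture(scope="session")
def qc_pipeline():
    """Aligned, region-selected QC replicate matrices (intra and inter day)
    with their noise floor; shared across validation tests."""
    from olivegrade.core import Category
    from olivegrade.preprocess import build_fingerprints, select_signal_region
    from olivegrade.synthetic_data import (
        SyntheticConfig,
        generate_qc_pool,
        generate_qc_replicates,
        generate_sample,
    )
    from olivegrade.validate import qc_noise_floor

    cfg = SyntheticConfig(seed=0)
    components = [
        generate_sample(cfg, cat, np.random.default_rng([0, i]), f"comp{i}")
        for i, cat in enumerate([Category.EVOO, Category.VOO, Category.VOO])
    ]
    pool = generate_qc_pool(cfg, components, seed=0)
    out = {"cfg": cfg, "pool": pool}
    for mode in ("intra_day", "inter_day"):
        reps = generate_qc_replicates(cfg, pool, 7, mode, seed=0)
        F = build_fingerprints(reps, pool)
        F = select_signal_region(F, pool)
        out[mode] = F
        out[f"floor_{mode}"] = qc_noise_floor(F, pool)
    return out


@pytest.fixture(scope="session")
def tiny_fitted_model():
    """A small fitted 2-LV PLS-DA on separable Gaussian clouds."""
    from olivegrade.plsda import fit_pls

    r = np.random.default_rng(7)
    X = np.vstack([r.normal(0, 1, (15, 12)), r.normal(2.5, 1, (15, 12))])
    y = np.array([0.0] * 15 + [1.0] * 15)
    return fit_pls(X, y, 2, class_labels=("lo", "hi")), X, y
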