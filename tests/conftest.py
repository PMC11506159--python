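"""Shared fixtures: seeded outlines and measured synthetic cohorts."""

import numpy as np
import pytest

from palaeoflight import pipeline, synthetic


def smooth_blob(seed: int, n: int = 211) -> np.ndarray:
    """A smooth wing-like closed outline (radial harmonic perturbation)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = (1.0 + 0.25 * np.cos(t) + 0.12 * np.sin(2 * t)
         + 0.05 * rng.uniform(-1, 1) * np.cos(3 * t + rng.uniform(0, np.pi)))
    return np.column_stack([2.5 * r * np.cos(t), r * np.sin(t)])


@pytest.fixture(scope="session")
def early_cohort():
    """200 early-group taxa with default published calibration."""
    spec = synthetic.default_cohort_spec("early", 200)
    return synthetic.generate_cohort([spec], seed=11)


@pytest.fixture(scope="session")
def late_cohort():
    """200 late-group taxa with default published calibration."""
    spec = synthetic.default_cohort_spec("late", 200)
    return synthetic.generate_cohort([spec], seed=11)


@pytest.fixture(scope="session")
def early_traits(early_cohort):
    return pipeline.measure_cohort(early_cohort, pipeline.PipelineConfig())


@pytest.fixture(scope="session")
def late_traits(late_cohort):
    return pipeline.measure_cohort(late_cohort, pipeline.PipelineConfig())
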