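"""Shared fixtures: small rendered screens and the heavier validation runs.

Session-scoped fixtures cache the expensive simulations (full-array EC50
recovery, the calcein stability run, the diffusivity sweep) so every test
that needs them shares one computation.
"""

import numpy as np
import pytest

from spherescreen.imaging import SegmentationParams, measure_timecourse
from spherescreen.layout import generate_layout
from spherescreen.synth import make_ground_truth, render_experiment


@pytest.fixture(scope="session")
def default_layout():
    return generate_layout()


@pytest.fixture(scope="session")
def small_layout():
    return generate_layout(n_rows=4, n_cols=8)


@pytest.fixture(scope="session")
def small_screen(small_layout):
    """A 4 x 8 disaggregation-mode screen: ground truth, images, table."""
    gt = make_ground_truth(small_layout, seed=7, ec50_uM=100.0, hill_slope=3.0)
    images = render_experiment(ground_truth=gt, days=(4, 5, 6, 7, 8), drug_day=5, seed=7)
    table = measure_timecourse(images, params=SegmentationParams(invert=True))
    return gt, images, table


@pytest.fixture(scope="session")
def vehicle_screen(small_layout):
    """Zero-dose control screen (all row doses 0)."""
    gt = make_ground_truth(
        small_layout, seed=11, ec50_uM=100.0, hill_slope=3.0,
        row_doses_uM=[0.0] * small_layout.n_rows,
    )
    images = render_experiment(ground_truth=gt, days=(4, 5, 8), drug_day=5, seed=11)
    table = measure_timecourse(images, params=SegmentationParams(invert=True))
    return gt, images, table


@pytest.fixture(scope="session")
def recovery_errors():
    """EC50 recovery errors over 20 independent full-array screens."""
    from spherescreen.validation import ec50_recovery_errors

    return ec50_recovery_errors(n_seeds=20, base_seed=1)


@pytest.fixture(scope="session")
def calcein_validation():
    from spherescreen.validation import calcein_stability

    return calcein_stability(hours=17.0)


@pytest.fixture(scope="session")
def drift_sweep_pct():
    from spherescreen.validation import gradient_drift_24h

    return gradient_drift_24h()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
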