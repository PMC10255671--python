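import numpy as np
import pytest

from strokemetrics.config import FilterConfig, PipelineConfig, SnpmConfig
from strokemetrics.recording import detect_impacts, extract_stroke_windows
from strokemetrics.synthgen import StrokeParams, generate_stroke


@pytest.fixture(scope="session")
def noiseless_stroke():
    """One noiseless synthetic stroke at the default working rate,
    with its detected window, shared across tests (read-only)."""
    params = StrokeParams().noiseless()
    rec, truth = generate_stroke(params, seed=11)
    window = extract_stroke_windows(rec, detect_impacts(rec))[0]
    return rec, truth, window


@pytest.fixture(scope="session")
def fast_stroke():
    """A noiseless stroke at a reduced 2 kHz rate for cheap tests."""
    params = StrokeParams(sample_rate=2000.0).noiseless()
    rec, truth = generate_stroke(params, seed=5)
    window = extract_stroke_windows(rec, detect_impacts(rec))[0]
    return rec, truth, window


@pytest.fixture()
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture()
def filter_cfg():
    return FilterConfig()


@pytest.fixture()
def snpm_cfg():
    return SnpmConfig()


def smooth_gaussian_curves(rng, n_curves, n_nodes, fwhm_nodes=12.0):
    """Smooth unit-variance Gaussian noise curves (shared test helper)."""
    from scipy.ndimage import gaussian_filter1d
    sigma = fwhm_nodes / (2 * np.sqrt(2 * np.log(2)))
    x = gaussian_filter1d(rng.standard_normal((n_curves, n_nodes)), sigma, axis=1,
                          mode="nearest")
    return x / x.std()
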