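import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spec():
    """A compact phantom: 32x32 grid, low noise, protonated-only adducts."""
    from lipidims import phantom

    return phantom.make_phantom_spec(
        genotype="WT", seed=7, grid_shape=(32, 32), sigma_log2=0.2,
        adduct_profile={"M+H": 1.0},
        panel_kwargs={"n_background": 10, "n_matrix": 4, "seed": 0},
    )


def make_pixelset(peak_rows, grid=(2, 2), metadata=None):
    """Build a PixelSpectrumSet from (pixel, mz, intensity) tuples."""
    from lipidims.spectra import PixelSpectrumSet

    coords = np.array([(r, c) for r in range(grid[0]) for c in range(grid[1])])
    df = pd.DataFrame(peak_rows, columns=["pixel", "mz", "intensity"])
    df["drift"] = np.nan
    return PixelSpectrumSet(coords, df, metadata or {})


def make_feature_matrix(values, kinds=None, tissues=None, zones=None,
                        genotypes=None, scale="linear"):
    """Build a FeatureMatrix from a 2-D array with minimal metadata."""
    from lipidims.roi import FeatureMatrix

    values = np.asarray(values, dtype=float)
    n = len(values)
    meta = pd.DataFrame({
        "roi_id": [f"roi{i}" for i in range(n)],
        "tissue": tissues or ["tissue"] * n,
        "zone": zones or [""] * n,
        "bone": [""] * n,
        "replicate": ["rep1"] * n,
        "kind": kinds or ["lROI"] * n,
        "sample": ["s"] * n,
        "genotype": genotypes or [""] * n,
    })
    cols = [f"ion{j}" for j in range(values.shape[1])]
    return FeatureMatrix(meta, pd.DataFrame(values, columns=cols), scale)
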