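"""Shared fixtures: small synthetic atlases and phantoms.

Everything is generated programmatically and seeded, so the suite needs
no data files.  The session-scoped atlas keeps the expensive pieces
(control phantoms, reference histogram) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from nawmetrics.alignment import OptimizerOptions
from nawmetrics.histogram import (
    BinningSpec,
    build_bivariate_histogram,
    build_reference_atlas,
)
from nawmetrics.io_prep import extract_paired_intensities
from nawmetrics.pipeline import PipelineConfig
from nawmetrics.synthetic import LesionSpec, PhantomSpec, generate_phantom

N_BINS = 96  # test-scale histogram resolution


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Pipeline settings at test scale: coarser bins, 3 multistarts."""
    return PipelineConfig(
        n_bins=N_BINS,
        optimizer=OptimizerOptions(
            multistart_scales=((1.0, 1.0), (1.1, 0.9), (0.9, 1.1))
        ),
    )


@pytest.fixture(scope="session")
def control_pools():
    pools = []
    for s in range(8):
        pair, _, _ = generate_phantom(PhantomSpec(seed=1000 + s, subject_id=f"ctl{s}"))
        pools.append(extract_paired_intensities(pair))
    return pools


@pytest.fixture(scope="session")
def binning(control_pools) -> BinningSpec:
    return BinningSpec.from_control_pool(control_pools, N_BINS, N_BINS)


@pytest.fixture(scope="session")
def control_histograms(control_pools, binning):
    return [build_bivariate_histogram(p, binning) for p in control_pools]


@pytest.fixture(scope="session")
def atlas(control_histograms, binning):
    return build_reference_atlas(control_histograms, binning=binning)


@pytest.fixture(scope="session")
def control_phantom():
    """A healthy-control phantom not used in the atlas."""
    return generate_phantom(PhantomSpec(seed=42, subject_id="ctl_test"))


@pytest.fixture(scope="session")
def ms_phantom():
    """An MS-like phantom: lesions plus diffuse NAWM FLAIR heterogeneity."""
    spec = PhantomSpec(
        seed=7,
        lesion_spec=LesionSpec(count=6),
        nawm_field_sd=25.0,
        subject_id="ms_test",
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
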