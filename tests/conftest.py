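import numpy as np
import pytest

from membrox.io import AxisKind, SpectralMatrix
from membrox.synth import EprModel, InhibitionTruth, TbarsModel, gen_tbars_titration


@pytest.fixture
def noiseless_model() -> TbarsModel:
    """TBARS shape model with every stochastic term switched off."""
    return TbarsModel(noise_sd=0.0, coupling_jitter=0.0, seed=1)


@pytest.fixture
def noiseless_titration(noiseless_model) -> SpectralMatrix:
    truth = InhibitionTruth(pI50_drug=3.7, cross_slope_drug_per_tro=-48e-3)
    return gen_tbars_titration(
        truth,
        [0.0, 0.08, 0.16, 0.24, 0.32, 0.40],
        [0.0, 5.0, 10.0, 15.0, 20.0, 25.0],
        noiseless_model,
    )


@pytest.fixture
def dpph_model() -> EprModel:
    return EprModel.dpph(center_offset=3.0)


@pytest.fixture
def glv_model() -> EprModel:
    return EprModel.glv(center_offset=3.0)


def random_spectral_matrix(rng: np.random.Generator, m: int, n: int) -> SpectralMatrix:
    """A random m x n matrix wrapped for decomposition (m >= n)."""
    assert m >= n
    return SpectralMatrix(
        np.arange(m, dtype=float),
        rng.normal(size=(m, n)),
        [{"col": float(j)} for j in range(n)],
        AxisKind.wavelength,
    )
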