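import numpy as np
import pytest

from ftirmw import LabelledDataset, SampleLabel, SimConfig, Spectrum, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The canonical 7-level x 10-replicate synthetic dataset."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(absorbances, wavenumbers=None, sample_id="S", replicate_id="r1"):
    a = np.asarray(absorbances, dtype=float)
    if wavenumbers is None:
        wavenumbers = np.arange(1800.0, 1800.0 - a.size, -1.0)
    return Spectrum(sample_id, replicate_id, np.asarray(wavenumbers, dtype=float), a)


@pytest.fixture
def toy_labelled_dataset(rng):
    """5-point grid, 4 samples x 3 replicates, with one planted monotone pair.

    Point 0 scales with M_w, the rest are constant; small noise keeps ranks
    well defined.
    """
    grid = np.array([1800.0, 1750.0, 1700.0, 1650.0, 1600.0])
    mws = [1e4, 5e4, 2e5, 6e5]
    spectra, labels = [], {}
    for si, mw in enumerate(mws, start=1):
        sid = f"T{si}"
        labels[sid] = SampleLabel(sid, mw)
        base = np.array([0.2 + 0.6 * mw / (mw + 1e5), 0.5, 0.35, 0.25, 0.6])
        for rep in range(3):
            noisy = base + rng.normal(0, 1e-3, base.size)
            spectra.append(Spectrum(sid, f"r{rep}", grid.copy(), noisy))
    return LabelledDataset(spectra, labels)
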