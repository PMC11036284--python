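import numpy as np
import pytest

from adcmapper.chem import PROTON, NEUTRON_SPACING
from adcmapper.deconv import averagine_envelope
from adcmapper.sequence import ChainSequence, load_trastuzumab
from adcmapper.spectra import Spectrum


@pytest.fixture(scope="session")
def trastuzumab():
    return load_trastuzumab()


@pytest.fixture(scope="session")
def heavy_chain(trastuzumab):
    return next(c for c in trastuzumab if c.role == "heavy")


@pytest.fixture(scope="session")
def light_chain(trastuzumab):
    return next(c for c in trastuzumab if c.role == "light")


def plant_envelope(mass, charge, scale=100.0, noise_sigma=0.0, rng=None,
                   truncate=1e-3):
    """Peaks of one averagine isotope envelope at exact grid m/z."""
    rng = rng or np.random.default_rng(0)
    env = averagine_envelope(mass, truncate)
    mono_mz = (mass + charge * PROTON) / charge
    mz = mono_mz + np.arange(env.size) * NEUTRON_SPACING / charge
    inten = env * scale
    if noise_sigma:
        inten = inten * (1 + noise_sigma * rng.standard_normal(env.size))
    return mz, np.clip(inten, 0, None)


def envelope_scan(mass, charge, scan_id="s", noise_sigma=0.0, n_noise=0,
                  rng=None, activation="UVPD"):
    rng = rng or np.random.default_rng(0)
    mz, inten = plant_envelope(mass, charge, 100.0, noise_sigma, rng)
    if n_noise:
        nm = rng.uniform(mz.min() - 50, mz.max() + 50, n_noise)
        ni = rng.uniform(0.001, 0.01, n_noise) * inten.max()
        mz = np.r_[mz, nm]
        inten = np.r_[inten, ni]
    return Spectrum(scan_id, 2, mz, inten, 1.0, activation,
                    precursor_mz=float(mz[0]), precursor_charge=charge)


@pytest.fixture(scope="session")
def toy_chain():
    return ChainSequence("toy", "light", "AKRKG", copies_per_antibody=1)
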