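import numpy as np
import pytest

import coce


@pytest.fixture(scope="session")
def system():
    return coce.SystemConfig()


@pytest.fixture(scope="session")
def two_block_chain(system):
    """Noiseless end-to-end run on a 600/1000 kPa two-block phantom.

    Shared by the stiffness-mapping unit tests and the image-chain
    acceptance test; everything downstream of the frames is deterministic.
    """
    phantom = coce.build_phantom(
        lateral_extent_mm=0.9,
        depth_extent_mm=1.2,
        silicone_thickness_um=300.0,
        silicone_modulus_kpa=100.0,
        tissue_modulus_kpa=coce.two_block_modulus(600.0, 1000.0, 450.0),
        system=system,
        seed=1,
    )
    series, truth = coce.simulate_compression_series(
        phantom, system, np.linspace(0.0, 8.0, 21), seed=2, snr_db=None
    )
    cumulative = coce.accumulate_strain(series)
    mapper = coce.StiffnessMapper(silicone_thickness_hint_um=300.0).fit(cumulative)
    stiff = mapper.transform(cumulative)
    return {
        "phantom": phantom,
        "series": series,
        "truth": truth,
        "cumulative": cumulative,
        "mapper": mapper,
        "stiff": stiff,
        "silicone_px": int(round(300.0 / system.axial_pixel_pitch_um)),
        "block_truth": (600.0, 1000.0),
    }


def block_median(stiff, silicone_px, cols):
    """Median recovered stiffness over one tissue block, away from edges."""
    v, ok = stiff.values_kpa, stiff.valid_mask
    rows = slice(silicone_px + 12, v.shape[0] - 12)
    sel = ok[rows, cols]
    return float(np.median(v[rows, cols][sel]))


@pytest.fixture(scope="session")
def uniform_pair(system):
    """Noisy (25 dB) single compression step with uniform strain 5e-3."""
    phantom = coce.build_phantom(
        lateral_extent_mm=0.6,
        depth_extent_mm=0.8,
        silicone_thickness_um=1.0,
        silicone_modulus_kpa=200.0,
        tissue_modulus_kpa=200.0,
        system=system,
        seed=3,
    )
    series, truth = coce.simulate_compression_series(
        phantom, system, [0.0, 1.0], seed=4, snr_db=25.0
    )
    return phantom, series, truth
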