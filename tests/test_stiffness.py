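"""Reference-layer segmentation, pressure standardization, modulus mapping."""

import numpy as np
import pytest

import coce
from coce.config import CalibrationConfig
from coce.exceptions import CalibrationError, InputError
from coce.stiffness import (
    StiffnessMap,
    quantify_roi,
    segment_reference_layer,
    select_pressure_standard_pair,
    stiffness_from_strain,
)
from coce.strain import StrainMap

from conftest import block_median


def make_strain(values, system, valid=None, window=(8, 8), pair=(0, 1)):
    values = np.asarray(values, float)
    if valid is None:
        valid = np.ones_like(values, bool)
    return StrainMap(
        values=values, window=window, valid_mask=valid, frame_pair=pair, system=system
    )


def layered_strain(system, nz=120, nx=60, sil_rows=30, eps_sil=0.01, eps_tis=0.002):
    vals = np.full((nz, nx), eps_tis)
    vals[:sil_rows] = eps_sil
    return make_strain(vals, system)


# ---------------------------------------------------------------- segmentation

def test_segment_exact_layered_map(system):
    sm = layered_strain(system)
    mask = segment_reference_layer(sm, silicone_thickness_hint_um=150.0)
    rows = mask.sum(axis=0)
    assert np.all(np.abs(rows - 30) <= 1)
    # simply connected from the top
    assert np.all(mask[:29, :])


def test_segment_fallback_low_contrast_warns(system):
    sm = make_strain(np.full((120, 60), 0.004), system)
    with pytest.warns(UserWarning, match="low-contrast"):
        mask = segment_reference_layer(sm, silicone_thickness_hint_um=150.0)
    assert mask[:30].all() and not mask[30:].any()


def test_segment_boundary_on_simulated_phantom(two_block_chain, system):
    """Noiseless end-to-end run: boundary within one axial resolution cell
    (2 px) of the true 300 um for most columns. The magnitude-weighted
    window pulls the interface estimate slightly toward the (more coherent)
    stiff side, so a small shallow bias is expected."""
    mask = two_block_chain["mapper"].reference_mask_
    rows = mask.sum(axis=0)
    true_px = two_block_chain["silicone_px"]
    assert np.mean(np.abs(rows - true_px) <= 2) >= 0.85
    assert abs(np.median(rows) - true_px) <= 2


def test_segment_boundary_monte_carlo(system):
    """SNR 25 dB: boundary localized within one resolution cell (10 um)
    for >= 90% of columns, over 20 phantom/noise seeds."""
    hits = []
    for s in range(20):
        phantom = coce.build_phantom(
            0.45, 0.6, 150.0, silicone_modulus_kpa=100.0, tissue_modulus_kpa=800.0,
            system=system, seed=300 + s,
        )
        series, _ = coce.simulate_compression_series(
            phantom, system, [0.0, 1.0], seed=400 + s, snr_db=25.0
        )
        sm = coce.VectorStrainEstimator().fit_transform(series)[0]
        mask = segment_reference_layer(sm, silicone_thickness_hint_um=150.0)
        rows = mask.sum(axis=0)
        hits.append(np.mean(np.abs(rows - 30) <= 2))
    assert np.mean(hits) >= 0.9


# ------------------------------------------------------ pressure standardization

def test_select_pressure_first_in_window(system):
    maps = [
        make_strain(np.full((40, 20), eps), system) for eps in (0.01, 0.03, 0.05)
    ]
    ref = np.zeros((40, 20), bool)
    ref[:10] = True
    idx, p = select_pressure_standard_pair(maps, ref, CalibrationConfig())
    assert idx == 1 and p == pytest.approx(3.0)


def test_select_pressure_out_of_range_errors(system):
    maps = [make_strain(np.full((40, 20), eps), system) for eps in (0.001, 0.002)]
    ref = np.zeros((40, 20), bool)
    ref[:10] = True
    with pytest.raises(CalibrationError, match="0.1-0.2"):
        select_pressure_standard_pair(maps, ref, CalibrationConfig())


def test_select_pressure_on_simulated_sweep(two_block_chain):
    """Simulated sweep to 8 kPa: the selected state sits in the 4 +/- 1 kPa
    window and within 10% of the true applied pressure."""
    mapper = two_block_chain["mapper"]
    truth = two_block_chain["truth"]
    assert 3.0 <= mapper.achieved_pressure_kpa_ <= 5.0
    true_p = truth.surface_pressures_kpa[mapper.pair_index_ + 1]
    assert mapper.achieved_pressure_kpa_ == pytest.approx(true_p, rel=0.10)


# ----------------------------------------------------------------- calibration

def test_stiffness_ratio_direct(system):
    vals = np.full((60, 30), 0.005)
    vals[:15] = 0.01
    sm = make_strain(vals, system)
    ref = np.zeros((60, 30), bool)
    ref[:15] = True
    stiff = stiffness_from_strain(sm, ref, CalibrationConfig())
    np.testing.assert_allclose(stiff.values_kpa[20:], 200.0, rtol=1e-12)
    # tissue identical to reference -> uniform 100 kPa
    stiff2 = stiffness_from_strain(
        make_strain(np.full((60, 30), 0.01), system), ref, CalibrationConfig()
    )
    np.testing.assert_allclose(stiff2.values_kpa, 100.0, rtol=1e-12)


def test_stiffness_scale_invariance(system):
    sm = layered_strain(system)
    ref = np.zeros_like(sm.values, bool)
    ref[:30] = True
    a = stiffness_from_strain(sm, ref, CalibrationConfig())
    scaled = make_strain(sm.values * 3.7, system)
    b = stiffness_from_strain(scaled, ref, CalibrationConfig())
    np.testing.assert_allclose(a.values_kpa, b.values_kpa, rtol=1e-12)


def test_degenerate_strain_pixels_capped(system):
    vals = np.full((60, 30), 0.005)
    vals[:15] = 0.01
    vals[40, 10] = 0.0
    vals[41, 11] = -1e-4
    ref = np.zeros((60, 30), bool)
    ref[:15] = True
    stiff = stiffness_from_strain(make_strain(vals, system), ref, CalibrationConfig())
    assert stiff.values_kpa[40, 10] == 2000.0
    assert stiff.values_kpa[41, 11] == 2000.0
    assert stiff.capped_mask[40, 10] and stiff.capped_mask[41, 11]


def test_two_block_recovery_and_monotonicity(two_block_chain):
    """Block medians within 10% of 600/1000 kPa ground truth; the stiffer
    block never recovers softer; both blocks inside the tumor-cell mask."""
    stiff = two_block_chain["stiff"]
    sil_px = two_block_chain["silicone_px"]
    nx = stiff.values_kpa.shape[1]
    left = block_median(stiff, sil_px, slice(4, nx // 2 - 4))
    right = block_median(stiff, sil_px, slice(nx // 2 + 4, nx - 4))
    assert left == pytest.approx(600.0, rel=0.10)
    assert right == pytest.approx(1000.0, rel=0.10)
    assert right > left
    rows = slice(sil_px + 12, stiff.values_kpa.shape[0] - 12)
    assert stiff.cancer_mask[rows, 4 : nx // 2 - 4].mean() > 0.5
    assert stiff.cancer_mask[rows, nx // 2 + 4 : nx - 4].mean() > 0.5


def test_silicone_self_test(two_block_chain):
    """Silicone pixels evaluated as tissue return 100 +/- 10 kPa."""
    stiff = two_block_chain["stiff"]
    sil_px = two_block_chain["silicone_px"]
    sel = stiff.valid_mask[5 : sil_px - 5, :]
    med = np.median(stiff.values_kpa[5 : sil_px - 5, :][sel])
    assert med == pytest.approx(100.0, abs=10.0)


def test_pressure_standardization_controls_nonlinearity(system):
    """With stress-stiffening tissue, stiffness read at the standardized
    pressure is stable across sweeps of different total depth, while the
    estimate at the deepest compression state varies more."""
    phantom = coce.build_phantom(
        0.6, 0.8, 200.0, silicone_modulus_kpa=100.0, tissue_modulus_kpa=700.0,
        system=system, seed=21,
    )
    standardized, final = [], []
    for pmax, n in ((6.0, 16), (12.0, 31)):
        series, _ = coce.simulate_compression_series(
            phantom, system, np.linspace(0.0, pmax, n), seed=22, snr_db=None,
            nonlinear_beta_per_kpa=0.08,
        )
        cum = coce.accumulate_strain(series)
        mapper = coce.StiffnessMapper(silicone_thickness_hint_um=200.0).fit(cum)
        rows = slice(40 + 12, 148)
        std_map = mapper.transform(cum)
        standardized.append(
            np.median(std_map.values_kpa[rows][std_map.valid_mask[rows]])
        )
        last_map = stiffness_from_strain(
            cum[-1], mapper.reference_mask_, CalibrationConfig()
        )
        final.append(np.median(last_map.values_kpa[rows][last_map.valid_mask[rows]]))
    spread_std = abs(standardized[1] - standardized[0]) / standardized[0]
    spread_final = abs(final[1] - final[0]) / final[0]
    assert spread_std < 0.10
    assert spread_final > spread_std


# -------------------------------------------------------------------- ROI math

def uniform_stiffness_map(values, cancer=None, reference=None):
    values = np.asarray(values, float)
    if cancer is None:
        cancer = values > 520.0
    if reference is None:
        reference = np.zeros_like(values, bool)
    return StiffnessMap(
        values_kpa=values,
        standardization_pressure_kpa=4.0,
        reference_mask=reference,
        cancer_mask=cancer,
        valid_mask=np.ones_like(values, bool),
        source_frame_pair=(0, 1),
    )


def test_quantify_roi_semantics():
    square = [(2.0, 2.0), (18.0, 2.0), (18.0, 18.0), (2.0, 18.0)]
    q = quantify_roi(uniform_stiffness_map(np.full((24, 24), 700.0)), square)
    assert q.mean_kpa == pytest.approx(700.0) and q.masked_fraction == 1.0

    half = np.full((24, 24), 400.0)
    half[:, 12:] = 800.0
    # half-open pixel convention: vertices at x.5 select columns 4..19
    q = quantify_roi(
        uniform_stiffness_map(half), [(3.5, 3.5), (19.5, 3.5), (19.5, 19.5), (3.5, 19.5)]
    )
    assert q.mean_kpa == pytest.approx(800.0)
    assert q.masked_fraction == pytest.approx(0.5)

    q = quantify_roi(uniform_stiffness_map(np.full((24, 24), 300.0)), square)
    assert np.isnan(q.mean_kpa) and q.masked_fraction == 0.0

    with pytest.raises(InputError):
        quantify_roi(
            uniform_stiffness_map(np.full((24, 24), 700.0)),
            [(30, 30), (40, 30), (40, 40)],
        )
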