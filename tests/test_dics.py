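import numpy as np
import pytest

from ocubss.dics_eval import (DEFAULT_BANDS, CrossSpectralDensity, common_filter,
                              compute_csd, make_parcellation, parcel_and_test,
                              reduction_maps, source_power)
from ocubss.forward import ForwardGrid, leadfield_sphere

from conftest import make_matrix_recording


# ---------------------------------------------------------------------------
# CSD estimation
# ---------------------------------------------------------------------------

def test_identical_sine_coherent_rank_one():
    t = np.arange(60000) / 600.0
    s = np.sin(2 * np.pi * 10 * t)
    rng = np.random.default_rng(0)
    X = np.vstack([s, s]) + 1e-6 * rng.standard_normal((2, t.size))
    rec = make_matrix_recording(X)
    csd = compute_csd(rec, (9, 11))
    csd.validate()
    coh = np.abs(csd.matrix[0, 1]) / np.sqrt(csd.matrix[0, 0].real
                                             * csd.matrix[1, 1].real)
    assert coh > 0.999
    assert csd.rank == 1


def test_independent_white_channels_diagonal():
    rng = np.random.default_rng(1)
    rec = make_matrix_recording(rng.standard_normal((4, 240000)))
    csd = compute_csd(rec, (10, 20))
    off = np.abs(csd.matrix - np.diag(np.diag(csd.matrix))).max()
    assert off < 0.1 * np.abs(np.diag(csd.matrix)).min()


def test_ar1_diagonal_matches_analytic_spectrum():
    # two-sided AR(1) PSD: sigma^2 / (1 - 2 phi cos w + phi^2) / fs
    rng = np.random.default_rng(2)
    phi, fs, n = 0.8, 600.0, 360000
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    rec = make_matrix_recording(np.vstack([x, x * 0 + rng.standard_normal(n)]))
    band = (10, 14)
    csd = compute_csd(rec, band)
    freqs = np.fft.rfftfreq(600, 1 / fs)
    bins = (freqs >= band[0]) & (freqs <= band[1])
    w = 2 * np.pi * freqs[bins] / fs
    analytic = np.mean(1.0 / (1 - 2 * phi * np.cos(w) + phi ** 2)) / fs
    assert csd.matrix[0, 0].real == pytest.approx(analytic, rel=0.05)


def test_band_above_nyquist_rejected():
    rec = make_matrix_recording(np.zeros((2, 2000)))
    with pytest.raises(ValueError):
        compute_csd(rec, (250, 400))


def test_csd_uses_reading_pages_only():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((2, 2400))
    X[:, 1200:] *= 100.0                      # huge power in the scanning page
    rec = make_matrix_recording(X, page_spans=[(0, 1200), (1200, 2400)])
    rec.page_labels = ["reading", "scanning"]
    csd = compute_csd(rec, (10, 20))
    rec_all = make_matrix_recording(X, page_spans=[(0, 1200), (1200, 2400)])
    csd_all = compute_csd(rec_all, (10, 20))
    assert csd.matrix[0, 0].real < 0.1 * csd_all.matrix[0, 0].real


# ---------------------------------------------------------------------------
# beamformer
# ---------------------------------------------------------------------------

def _unit_grid(n_ch=6, n_pts=5, seed=0):
    # synthetic grid with orthonormal leadfield columns per point, so every
    # scalar leadfield l = L @ ori has unit norm
    rng = np.random.default_rng(seed)
    G = np.empty((n_ch, n_pts, 2))
    for p in range(n_pts):
        Q, _ = np.linalg.qr(rng.standard_normal((n_ch, 2)))
        G[:, p, :] = Q
    pts = rng.uniform(-0.05, 0.05, size=(n_pts, 3))
    return ForwardGrid(points=pts, spacing=0.01, leadfield=G,
                       tangentials=np.zeros((n_pts, 2, 3)),
                       sensors=None)


def _csd(mat, rank=None):
    mat = np.asarray(mat, dtype=complex)
    r = rank if rank is not None else mat.shape[0]
    return CrossSpectralDensity(band=(8, 13), matrix=mat, rank=r, n_segments=10)


def test_identity_csd_closed_form():
    grid = _unit_grid()
    eye = _csd(np.eye(6))
    w = common_filter(eye, eye, eye, grid)
    # with C = I and a unit-norm scalar leadfield, w = l' and power = 1
    P = source_power(w, eye)
    assert np.allclose(P, 1.0, rtol=1e-8)
    assert np.allclose(np.imag(w), 0.0, atol=1e-12)


def test_identical_csds_match_single_condition():
    rng = np.random.default_rng(4)
    A = rng.standard_normal((6, 6))
    C = A @ A.T + 6 * np.eye(6)
    grid = _unit_grid(seed=5)
    w1 = common_filter(_csd(C), _csd(C), _csd(C), grid)
    w2 = common_filter(_csd(C), _csd(C), _csd(C), grid, rank=6)
    assert np.allclose(w1, w2)


def test_common_filter_weights_independent_of_condition():
    rng = np.random.default_rng(6)
    A = rng.standard_normal((6, 6))
    Cu = A @ A.T + 6 * np.eye(6)
    C1, C2 = 0.8 * Cu, 0.6 * Cu
    grid = _unit_grid(seed=7)
    w = common_filter(_csd(Cu), _csd(C1), _csd(C2), grid)
    P1 = source_power(w, _csd(C1))
    P2 = source_power(w, _csd(C2))
    assert np.allclose(P1 / P2, 0.8 / 0.6, rtol=1e-10)


def test_zero_rank_rejected():
    grid = _unit_grid()
    with pytest.raises(ValueError):
        common_filter(_csd(np.eye(6)), _csd(np.eye(6), rank=0),
                      _csd(np.eye(6), rank=0), grid)


def test_source_power_trivial_cases():
    grid = _unit_grid(seed=8)
    eye = _csd(np.eye(6))
    w = common_filter(eye, eye, eye, grid)
    assert np.allclose(source_power(w, _csd(np.zeros((6, 6)))), 0.0)
    P1 = source_power(w, _csd(np.eye(6)))
    P2 = source_power(w, _csd(2 * np.eye(6)))
    assert np.allclose(P2, 2 * P1)


def test_point_source_localized_within_one_spacing(sensors30, grid30):
    rng = np.random.default_rng(9)
    r = np.linalg.norm(grid30.points, axis=1)
    interior = np.flatnonzero(~grid30.eye_region_mask() & (r > 0.03) & (r < 0.07))
    p = int(interior[len(interior) // 2])
    ori = grid30.tangentials[p, 0]
    lf = leadfield_sphere(grid30.points[p], 1e-8 * ori, sensors30)
    t = np.arange(120000) / 600.0
    s = np.sin(2 * np.pi * 11 * t) * (1 + 0.2 * np.sin(2 * np.pi * 0.2 * t))
    X = np.outer(lf, s)
    X += 10 ** (-10 / 20) * X.std() * rng.standard_normal(X.shape)
    rec = make_matrix_recording(X)
    rec.ch_names = sensors30.channel_names()
    csd = compute_csd(rec, (8, 13))
    w = common_filter(csd, csd, csd, grid30)
    P = source_power(w, csd)
    peak = int(np.argmax(P))
    err = np.linalg.norm(grid30.points[peak] - grid30.points[p])
    assert err <= grid30.spacing + 1e-12


# ---------------------------------------------------------------------------
# reduction maps and group statistics
# ---------------------------------------------------------------------------

def test_reduction_map_trivial_cases():
    Pu = np.array([1.0, 2.0, 4.0])
    maps = reduction_maps(Pu, Pu, 0.5 * Pu)
    assert np.allclose(maps["reduction_p1"], 0.0)
    maps2 = reduction_maps(Pu, np.zeros(3), 0.5 * Pu)
    assert np.allclose(maps2["reduction_p1"], 1.0)
    maps3 = reduction_maps(Pu, 0.5 * Pu, 0.5 * Pu)
    assert np.allclose(maps3["difference"], 0.0)


def test_reduction_guards_zero_power():
    Pu = np.array([0.0, 1.0])
    maps = reduction_maps(Pu, Pu, Pu)
    assert maps["guarded"][0]


def test_negative_reduction_preserved():
    Pu = np.array([1.0])
    maps = reduction_maps(Pu, np.array([1.5]), np.array([0.5]))
    assert maps["reduction_p1"][0] == pytest.approx(-0.5)


def test_parcellation_covers_grid(grid30):
    ids, names = make_parcellation(grid30)
    assert ids.shape == (grid30.n_points,)
    assert ids.min() >= 0 and ids.max() < len(names)
    assert len(set(names)) == len(names)


def test_parcel_and_test_constant_shift(grid30):
    rng = np.random.default_rng(10)
    ids, names = make_parcellation(grid30)
    n_sub, n_pts = 8, grid30.n_points
    delta = 0.3
    maps = {(8, 13): delta + 0.01 * rng.standard_normal((n_sub, n_pts))}
    res = parcel_and_test(maps, ids, names, alpha=0.005, diff_threshold=0.05)
    tab = res["table"]
    assert np.all(res["pvalues"][(8, 13)] < 0.005)
    assert np.allclose(tab["mean_difference"], delta, atol=0.02)
    assert len(res["large_differences"]) == tab.shape[0]


def test_parcel_and_test_requires_three_subjects(grid30):
    ids, names = make_parcellation(grid30)
    with pytest.raises(ValueError):
        parcel_and_test({(8, 13): np.zeros((2, grid30.n_points))}, ids, names)


def test_default_bands():
    assert DEFAULT_BANDS == [(1, 4), (5, 8), (8, 13), (15, 25), (31, 47), (60, 90)]
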