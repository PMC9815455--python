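import numpy as np
import pytest

from ocubss.metrics import amari_index, best_match_correlations
from ocubss.sobi import (LagSet, joint_diagonalize, select_lags, sobi_decompose,
                         whiten)

from conftest import make_matrix_recording


# ---------------------------------------------------------------------------
# lag selection
# ---------------------------------------------------------------------------

def test_lagset_always_contains_base_range():
    ls = LagSet(lags=np.array([400, 200, 200]))
    assert set(range(151)) <= set(ls.lags.tolist())
    assert 200 in ls.lags and 400 in ls.lags
    assert len(ls.lags) == 153  # duplicates removed


def test_lagset_rejects_negative():
    with pytest.raises(ValueError):
        LagSet(lags=np.array([-3]))


def test_lagset_restrict_enforces_third_rule():
    ls = LagSet(lags=np.array([500]))
    kept = ls.restrict(1500)
    assert kept.lags.max() < 500
    with pytest.raises(ValueError):
        ls.restrict(300)  # base range itself too long


def test_white_noise_gives_base_lags_only():
    rng = np.random.default_rng(0)
    ls = select_lags(rng.standard_normal(20000), sfreq=600.0)
    assert ls.lags.tolist() == list(range(151))


def test_sawtooth_period_adds_lag_neighbourhood():
    # acf of a pure sawtooth of period 900 is itself periodic: the oracle
    # is the direct biased acf computed here
    period = 900
    n = 40 * period
    x = (np.arange(n) % period) / period - 0.5
    ls = select_lags(x, search_max=1200, sfreq=600.0)
    xc = x - x.mean()
    acf900 = np.dot(xc[:-900], xc[900:]) / np.dot(xc, xc)
    assert acf900 >= 0.3
    assert 900 in ls.lags
    # far from the period (and beyond base range) the acf is low
    assert 500 not in ls.lags


def test_threshold_rule_exact():
    # sinusoid of period 200 + noise, amplitude set so acf(200) ~ 0.35:
    # lags = {0..150} plus a neighbourhood of 200, nothing in between
    rng = np.random.default_rng(1)
    n = 120000
    t = np.arange(n)
    ratio = 0.35
    a = np.sqrt(2 * ratio / (1 - ratio))
    x = a * np.sin(2 * np.pi * t / 200) + rng.standard_normal(n)
    ls = select_lags(x, search_max=400, sfreq=600.0)
    assert 200 in ls.lags
    assert 175 not in ls.lags
    assert set(range(151)) <= set(ls.lags.tolist())


def test_constant_eog_raises():
    with pytest.raises(ValueError, match="degenerate|autocorrelation"):
        select_lags(np.ones(5000), sfreq=600.0)


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def test_whiten_postcondition_identity_covariance():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((6, 5000)) * np.array([[1, 3, 0.2, 5, 1, 2]]).T
    Z, W, Wd = whiten(X)
    C = Z @ Z.T / Z.shape[1]
    assert np.max(np.abs(C - np.eye(6))) < 1e-8


def test_whitener_of_white_data_is_orthogonal():
    rng = np.random.default_rng(3)
    Z, W, _ = whiten(rng.standard_normal((4, 200000)))
    assert np.max(np.abs(W @ W.T - np.eye(4))) < 0.05


def test_whitener_singular_values_match_eigendecomposition():
    rng = np.random.default_rng(4)
    X = np.diag([3.0, 5.0]) @ rng.standard_normal((2, 400000))
    _, W, _ = whiten(X)
    sv = np.sort(np.linalg.svd(W, compute_uv=False))
    assert np.allclose(sv, np.sort([1 / 3, 1 / 5]), rtol=0.02)


def test_whiten_projector_roundtrip():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((5, 3000))
    _, W, Wd = whiten(X, n_components=3)
    P = Wd @ W
    assert np.allclose(P @ P, P, atol=1e-8)


def test_whiten_rejects_single_channel():
    with pytest.raises(ValueError):
        whiten(np.ones((1, 100)))


def test_whiten_rank_deficient_errors():
    x = np.random.default_rng(6).standard_normal(1000)
    X = np.vstack([x, x, x])  # rank 1
    Z, W, _ = whiten(X)       # tolerance truncation keeps it usable
    assert Z.shape[0] == 1


# ---------------------------------------------------------------------------
# joint diagonalization
# ---------------------------------------------------------------------------

def test_already_diagonal_gives_signed_permutation():
    mats = [np.diag([3.0, 1.0, 0.5]), np.diag([0.2, 2.0, 1.5])]
    V, info = joint_diagonalize(mats)
    assert info["converged"]
    # V is a signed permutation: one +-1 per row and column
    absV = np.abs(V)
    assert np.allclose(absV.max(axis=0), 1.0, atol=1e-9)
    assert np.allclose(absV.sum(axis=0), 1.0, atol=1e-9)


def test_single_2x2_matches_closed_form_eigenvectors():
    rng = np.random.default_rng(7)
    M = rng.standard_normal((2, 2))
    M = M + M.T
    V, _ = joint_diagonalize([M], tol=1e-12)
    D = V.T @ M @ V
    assert abs(D[0, 1]) < 1e-8
    evals, evecs = np.linalg.eigh(M)
    # columns match eigenvectors up to permutation and sign
    overlap = np.abs(evecs.T @ V)
    assert np.allclose(np.sort(overlap.ravel())[-2:], 1.0, atol=1e-8)


def test_offdiagonal_nonincreasing():
    rng = np.random.default_rng(8)
    A = rng.standard_normal((4, 4))
    mats = [A @ np.diag(rng.uniform(0.5, 2, 4)) @ A.T for _ in range(6)]
    _, info = joint_diagonalize(mats)
    off = np.array(info["off_diagonal"])
    assert np.all(np.diff(off) <= 1e-9 * off[0])


def test_max_sweeps_warns_but_returns():
    rng = np.random.default_rng(9)
    mats = [m + m.T for m in rng.standard_normal((8, 5, 5))]
    with pytest.warns(RuntimeWarning):
        V, info = joint_diagonalize(mats, tol=1e-14, max_sweeps=1)
    assert not info["converged"]
    assert V.shape == (5, 5)


# ---------------------------------------------------------------------------
# sobi_decompose
# ---------------------------------------------------------------------------

def _ar1(phi, n, rng):
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def test_sobi_recovers_ar_sources():
    rng = np.random.default_rng(10)
    T = 36000
    S = np.vstack([_ar1(0.95, T, rng), _ar1(0.30, T, rng)])
    S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    A = rng.standard_normal((10, 2))
    rec = make_matrix_recording(A @ S)
    rec.data -= rec.data.mean(axis=1, keepdims=True)
    dec = sobi_decompose(rec, lagset=LagSet(np.arange(151)), n_components=2)
    corr = best_match_correlations(dec.sources, S)
    assert np.all(corr >= 0.95)


def test_sobi_amari_on_four_sources():
    rng = np.random.default_rng(11)
    T = 36000
    t = np.arange(T) / 600.0
    from scipy import signal as sig
    S = np.vstack([sig.sawtooth(2 * np.pi * 2.3 * t), np.sin(2 * np.pi * 11 * t),
                   _ar1(0.9, T, rng), _ar1(0.4, T, rng)])
    S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    A = rng.standard_normal((10, 4))
    X = A @ S
    X += 0.1 * X.std() * rng.standard_normal(X.shape)
    rec = make_matrix_recording(X - X.mean(1, keepdims=True))
    dec = sobi_decompose(rec, lagset=LagSet(np.arange(151)), n_components=4)
    assert amari_index(dec.demixing, A) < 0.1


def test_sobi_rank_one_case():
    rng = np.random.default_rng(12)
    s = _ar1(0.8, 20000, rng)
    X = np.tile(s, (4, 1)) + 1e-6 * rng.standard_normal((4, 20000))
    rec = make_matrix_recording(X - X.mean(1, keepdims=True))
    dec = sobi_decompose(rec, lagset=LagSet(np.arange(151)))
    var = dec.sources.var(axis=1) * (dec.mixing ** 2).sum(axis=0)
    assert var[0] / var.sum() > 0.99


def test_sobi_equivariance_under_global_scaling():
    rng = np.random.default_rng(13)
    S = np.vstack([_ar1(0.9, 12000, rng), _ar1(0.2, 12000, rng)])
    A = rng.standard_normal((4, 2))
    X = A @ S
    X -= X.mean(1, keepdims=True)
    rec1 = make_matrix_recording(X)
    rec2 = make_matrix_recording(X * 250.0)
    d1 = sobi_decompose(rec1, lagset=LagSet(np.arange(151)), n_components=2)
    d2 = sobi_decompose(rec2, lagset=LagSet(np.arange(151)), n_components=2)
    corr = best_match_correlations(d2.sources, d1.sources)
    assert np.all(corr > 0.9999)


def test_sobi_uses_recording_eog_for_lags(sim_small):
    _, rec, _ = sim_small
    from ocubss.preprocess import demean_pages
    dec = sobi_decompose(demean_pages(rec), n_components=8)
    lags = dec.info["lags"]
    assert set(range(151)) <= set(lags.tolist())
    dec.validate(data=None)
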