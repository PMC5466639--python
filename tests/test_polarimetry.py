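"""Stokes conversion and DOPU estimators against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polrpe import (FieldVolume, KernelSpec, NoiseEstimate, StokesVolume,
                    compute_dopu, dopu_bias_experiment, estimate_noise,
                    stokes_from_fields)


def _fields(e1, e2):
    e1 = np.asarray(e1, dtype=complex).reshape(1, 1, 1, 1)
    e2 = np.asarray(e2, dtype=complex).reshape(1, 1, 1, 1)
    return FieldVolume(e1, e2)


@pytest.mark.parametrize(
    "e1,e2,expected",
    [
        (1.0, 0.0, (1, 1, 0, 0)),                      # horizontal
        (1 / np.sqrt(2), 1 / np.sqrt(2), (1, 0, 1, 0)),  # diagonal
        (1 / np.sqrt(2), 1j / np.sqrt(2), (1, 0, 0, 1)),  # circular
    ],
)
def test_stokes_reference_states(e1, e2, expected):
    st_ = stokes_from_fields(_fields(e1, e2))
    got = (st_.s0[0, 0, 0, 0], st_.q[0, 0, 0, 0],
           st_.u[0, 0, 0, 0], st_.v[0, 0, 0, 0])
    assert np.allclose(got, expected, atol=1e-15)


def test_estimate_noise_is_region_mean():
    e1 = np.zeros((1, 2, 1, 1), dtype=complex)
    e1[0, 0, 0, 0], e1[0, 1, 0, 0] = 1.0, np.sqrt(3.0)  # energies 1 and 3
    e2 = np.zeros_like(e1)
    region = np.ones((2, 1, 1), dtype=bool)
    est = estimate_noise(FieldVolume(e1, e2), region)
    assert est.n1 == pytest.approx(2.0)
    assert est.n2 == 0.0


def test_estimate_noise_rejects_empty_region():
    f = _fields(1.0, 0.0)
    with pytest.raises(ValueError, match="empty"):
        estimate_noise(f, np.zeros((1, 1, 1), dtype=bool))


def test_estimate_noise_circular_gaussian_lln(rng):
    # circular Gaussian with per-component variance sigma^2 has mean energy
    # 2 sigma^2; check within 2% at >= 1e5 samples
    sigma = 0.3
    n = 150_000
    e = sigma * (rng.standard_normal((1, n, 1, 1))
                 + 1j * rng.standard_normal((1, n, 1, 1)))
    est = estimate_noise(FieldVolume(e, np.zeros_like(e)),
                         np.ones((n, 1, 1), dtype=bool))
    assert abs(est.n1 - 2 * sigma ** 2) / (2 * sigma ** 2) < 0.02


def _uniform_polarized_stokes(q=0.6, u=0.8, v=0.0, shape=(1, 3, 1, 3), s0=1.0):
    ones = np.full(shape, s0)
    return StokesVolume(s0=ones, q=q * ones, u=u * ones, v=v * ones)


@pytest.mark.parametrize("corrected", [True, False])
def test_dopu_uniform_fully_polarized_is_one(corrected):
    """Identical fully polarized noiseless samples attain the upper bound 1.0."""
    st_ = _uniform_polarized_stokes()
    d = compute_dopu(st_, KernelSpec(), NoiseEstimate(0, 0), corrected=corrected)
    assert d.values[1, 0, 1] == pytest.approx(1.0, abs=1e-12)
    assert d.valid[1, 0, 1]


def test_dopu_opposed_states_cancel_to_zero():
    # half the kernel samples at (Q,U,V)=(S0,0,0), half at (-S0,0,0)
    s0 = np.ones((2, 3, 1, 3))
    q = np.ones((2, 3, 1, 3))
    q[1] = -1.0
    st_ = StokesVolume(s0=s0, q=q, u=np.zeros_like(s0), v=np.zeros_like(s0))
    d = compute_dopu(st_, KernelSpec(), NoiseEstimate(0, 0), corrected=True)
    assert d.values[1, 0, 1] == pytest.approx(0.0, abs=1e-12)


def _naive_dopu(stokes, kt, kd, n1, n2, corrected, eps):
    """Per-voxel loop reimplementation of the kernel DOPU (test oracle)."""
    nrep, nx, nb, nz = stokes.s0.shape
    out = np.zeros((nx, nb, nz))
    for x in range(nx):
        for b in range(nb):
            for z in range(nz):
                xs = range(max(x - kt // 2, 0), min(x + kt // 2 + 1, nx))
                zs = range(max(z - kd // 2, 0), min(z + kd // 2 + 1, nz))
                sq = su = sv = ss = 0.0
                qs = us = vs = 0.0
                nw = 0
                for r in range(nrep):
                    for xi in xs:
                        for zi in zs:
                            s0 = stokes.s0[r, xi, b, zi]
                            sq += stokes.q[r, xi, b, zi] - (n1 - n2)
                            su += stokes.u[r, xi, b, zi]
                            sv += stokes.v[r, xi, b, zi]
                            ss += s0 - (n1 + n2)
                            if s0 > 0:
                                qs += stokes.q[r, xi, b, zi] / s0
                                us += stokes.u[r, xi, b, zi] / s0
                                vs += stokes.v[r, xi, b, zi] / s0
                                nw += 1
                if corrected:
                    val = np.sqrt(sq ** 2 + su ** 2 + sv ** 2) / max(ss, eps)
                else:
                    val = np.sqrt(qs ** 2 + us ** 2 + vs ** 2) / max(nw, 1)
                out[x, b, z] = min(max(val, 0.0), 1.0)
    return out


@pytest.mark.parametrize("corrected", [True, False])
@pytest.mark.parametrize("shape,kt,kd", [((2, 5, 4, 5), 3, 3), ((2, 5, 5, 2), 3, 1)])
def test_dopu_kernel_matches_naive_oracle(rng, corrected, shape, kt, kd):
    """Vectorized kernel DOPU equals a per-voxel loop on small volumes."""
    e1 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    e2 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    st_ = stokes_from_fields(FieldVolume(e1, e2))
    noise = NoiseEstimate(0.05, 0.03)
    d = compute_dopu(st_, KernelSpec(kt, kd), noise, corrected=corrected)
    eps = 1e-12 * st_.s0.max()
    expected = _naive_dopu(st_, kt, kd, noise.n1, noise.n2, corrected, eps)
    assert np.allclose(d.values, expected, atol=1e-12)


def test_dopu_random_speckle_mean_matches_mc_oracle():
    """Mean DOPU of 3x3x4-repeat kernels of independent random-polarization
    speckles matches a direct Monte-Carlo resampling oracle within 2 sigma."""
    trials = 20_000
    rng_impl = np.random.default_rng(1)
    shape = (4, 3, trials, 3)
    e1 = np.sqrt(0.25) * (rng_impl.standard_normal(shape)
                          + 1j * rng_impl.standard_normal(shape))
    e2 = np.sqrt(0.25) * (rng_impl.standard_normal(shape)
                          + 1j * rng_impl.standard_normal(shape))
    st_ = stokes_from_fields(FieldVolume(e1, e2))
    d = compute_dopu(st_, KernelSpec(), NoiseEstimate(0, 0), corrected=True)
    vals_impl = d.values[1, :, 1]

    # oracle: 36 uniform unit Stokes directions weighted by Gamma(2) energies
    rng_or = np.random.default_rng(11)
    g = rng_or.standard_normal((trials, 36, 3))
    s = g / np.linalg.norm(g, axis=2, keepdims=True)
    w = rng_or.gamma(shape=2.0, scale=0.5, size=(trials, 36))
    resultant = np.linalg.norm((w[..., None] * s).sum(axis=1), axis=1)
    vals_or = resultant / w.sum(axis=1)

    se = np.hypot(vals_impl.std(ddof=1) / np.sqrt(trials),
                  vals_or.std(ddof=1) / np.sqrt(trials))
    assert abs(vals_impl.mean() - vals_or.mean()) < 2 * se


def test_dopu_mean_nonincreasing_in_depolarizing_fraction(rng):
    """Mean DOPU over a region degrades monotonically with the fraction of
    depolarizing voxels (Monte-Carlo averages)."""
    shape = (4, 24, 10, 24)
    means = []
    for frac in (0.0, 0.3, 0.6, 1.0):
        depol = rng.random(shape[1:]) < frac
        a = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
        e1p, e2p = a / np.sqrt(2), a / np.sqrt(2)
        g1 = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / 2
        g2 = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / 2
        e1 = np.where(depol[None], g1, e1p)
        e2 = np.where(depol[None], g2, e2p)
        st_ = stokes_from_fields(FieldVolume(e1, e2))
        d = compute_dopu(st_, KernelSpec(), NoiseEstimate(0, 0))
        means.append(d.values[1:-1, :, 1:-1].mean())
    assert all(m2 <= m1 + 0.01 for m1, m2 in zip(means, means[1:]))
    assert means[-1] < means[0] - 0.3


def test_bias_experiment_corrected_beats_uncorrected_at_low_snr():
    tab = dopu_bias_experiment([1.0, 2.0, 1e6], n_trials=600, seed=3)
    hi = tab[tab.snr == 1e6].iloc[0]
    assert hi.dopu_corrected > 0.99 and hi.dopu_uncorrected > 0.95
    low = tab[tab.snr <= 2.0]
    assert (low.dopu_uncorrected < 0.95).all()
    for _, row in low.iterrows():
        assert abs(1 - row.dopu_corrected) < abs(1 - row.dopu_uncorrected)


def test_bias_experiment_deterministic():
    t1 = dopu_bias_experiment([2.0], n_trials=200, seed=9)
    t2 = dopu_bias_experiment([2.0], n_trials=200, seed=9)
    assert t1.equals(t2)


def test_bias_experiment_rejects_few_trials():
    with pytest.raises(ValueError):
        dopu_bias_experiment([1.0], n_trials=10)


def test_kernel_spec_rejects_even_extents():
    with pytest.raises(ValueError):
        KernelSpec(transverse=2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 31 - 1), corrected=st.booleans())
def test_dopu_range_property(seed, corrected):
    """Valid DOPU values always lie in [0, 1] on arbitrary noisy fields."""
    r = np.random.default_rng(seed)
    shape = (2, 6, 3, 6)
    e1 = r.standard_normal(shape) * r.uniform(0, 2) + 1j * r.standard_normal(shape)
    e2 = r.standard_normal(shape) + 1j * r.standard_normal(shape)
    d = compute_dopu(stokes_from_fields(FieldVolume(e1, e2)),
                     KernelSpec(), NoiseEstimate(0.1, 0.2), corrected=corrected)
    assert np.isfinite(d.values).all()
    assert (d.values >= 0).all() and (d.values <= 1).all()
    assert d.valid.dtype == bool
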