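"""Shared fixtures: small, fast scan grids and crafted high-SNR eyes."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from polrpe import (FocusSpec, GroupConfig, OpticParams, analyze_eye,
                    build_phantom, simulate_eye)

#: Small grid for fast tests; high SNR (retina reflectivity 1 vs total noise 2e-4).
SMALL_PARAMS = OpticParams(
    n_alines=48, n_bscans=24, n_depth=64, n_repeats=4,
    noise_energy_ch1=1e-4, noise_energy_ch2=1e-4,
)


def crafted_phantom(flags_list, params=SMALL_PARAMS, radius_um=35.0, gain=3.0):
    """Phantom with hand-placed foci (one per flags dict), no randomness in
    the focus layout."""
    ph = build_phantom(params, "early_intermediate", seed=5,
                      group_config=GroupConfig(foci_rate=0.0))
    centers = [(14, 8, 24), (34, 16, 24), (24, 12, 24), (14, 16, 24)]
    foci = [
        FocusSpec(center=centers[i], radius_um=radius_um,
                  reflectivity_gain=gain, **flags)
        for i, flags in enumerate(flags_list)
    ]
    ph = replace(ph, foci=foci)
    ph.validate()
    return ph


@pytest.fixture(scope="session")
def mixed_eye():
    """One high-SNR eye with a migrating (melanin+lipofuscin) and a
    non-migrating (lipofuscin-only) focus, plus its analysis results."""
    ph = crafted_phantom([
        dict(melanin=True, lipofuscin=True, melanolipofuscin=False),
        dict(melanin=False, lipofuscin=True, melanolipofuscin=False),
    ])
    ds = simulate_eye(ph, seed=7, eye_id="mixed")
    record, observations, artifacts = analyze_eye(ds)
    return ds, record, observations, artifacts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
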