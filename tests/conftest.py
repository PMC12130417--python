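"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (scalar loops, explicit 2^n
enumeration, O(n^2) DFT matrices) so that they stay independent of the
vectorized implementation paths they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata

from oxyvib.simulator import Calibration, SimCohortConfig


def brute_force_wilcoxon(
    baseline, condition, zero_policy: str = "drop", alternative: str = "two_sided"
) -> tuple[float, float]:
    """Exact signed-rank test by explicit enumeration of all 2^m sign
    assignments (doubled integer ranks for exact tie arithmetic)."""
    d = np.asarray(condition, dtype=float) - np.asarray(baseline, dtype=float)
    if zero_policy == "drop":
        d = d[d != 0]
        if d.size == 0:
            return 0.0, 1.0
        ranks = rankdata(np.abs(d))
    else:  # pratt
        nz = d != 0
        ranks = rankdata(np.abs(d))[nz]
        d = d[nz]
        if d.size == 0:
            return 0.0, 1.0
    doubled = np.rint(2 * ranks).astype(int)
    w_obs = int(doubled[d > 0].sum())
    m = doubled.size
    sums = [
        sum(r for r, pos in zip(doubled, signs) if pos)
        for signs in product((False, True), repeat=m)
    ]
    total = len(sums)
    p_le = sum(1 for s in sums if s <= w_obs) / total
    p_ge = sum(1 for s in sums if s >= w_obs) / total
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_obs / 2.0, p


@pytest.fixture
def wilcoxon_oracle():
    return brute_force_wilcoxon


def dft_matrix_bandpass(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """O(n^2) brick-wall bandpass via an explicit DFT matrix with symmetric
    (conjugate-pair) coefficient masking; independent of any FFT routine."""
    n = x.size
    k = np.arange(n)
    F = np.exp(-2j * np.pi * np.outer(k, k) / n)
    coeffs = F @ x
    freqs = np.minimum(k, n - k) * fs / n  # each bin and its mirror share |f|
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    coeffs[~keep] = 0.0
    out = np.conj(F) @ coeffs / n
    return out.real


def tone_config(rpm: float = 3000.0, **overrides) -> SimCohortConfig:
    """Tiny, fast protocol (30-s segments) at a single pump speed."""
    params = dict(
        seed=0,
        n_subjects=2,
        segment_s=30.0,
        pre_reversal_s=30.0,
        reversal_offsets_s=(30.0, 60.0, 90.0),
        post_reversal_s=120.0,
        rise_time_s=10.0,
        pump_rpm=(rpm, rpm, rpm),
        drift_amplitude_g=0.0,
        amp_sigma_ln=0.0,
        noise_sigma_ln=0.0,
        gain_sigma_ln=0.0,
        include_hemodynamics=False,
    )
    params.update(overrides)
    return SimCohortConfig(**params)


def pure_tone_calibration(amplitude: float = 0.1) -> Calibration:
    """A hand-built calibration: one noiseless harmonic, no thrombosis."""
    return Calibration(
        flow_exponent=1.0,
        harmonic_amplitudes=(amplitude,),
        harmonic_power=amplitude**2 / 2.0,
        noise_power_inband=0.0,
        noise_sd=0.0,
        max_gain=0.0,
        inband_fraction=0.73,
    )
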