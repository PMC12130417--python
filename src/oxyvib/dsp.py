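"""The vibration signal chain: triaxial norm, frequency-domain bandpass,
and non-overlapping windowed RMS.

The chain mirrors common practice in rotating-machinery condition
monitoring: the three axes are collapsed to an omnidirectional magnitude
``g_xyz = sqrt(gx^2 + gy^2 + gz^2)``, a brick-wall bandpass (10-375 Hz by
default) is applied by zeroing Fourier coefficients outside the band, and
the signal energy is summarized as the RMS of consecutive non-overlapping
30-s windows.  Zeroing coefficients gives ideally sharp cutoffs at the cost
of possible time-domain ringing near transients; no taper is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import AccelerometerRecording

__all__ = [
    "BandpassSpec",
    "RmsSeries",
    "vector_norm",
    "band_mask",
    "inband_power_fraction",
    "fft_bandpass",
    "windowed_rms",
    "windowed_mean",
    "process_recording",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Passband for the frequency-domain filter.

    Coefficients at exactly ``f_lo_hz`` or ``f_hi_hz`` are retained when
    ``edge_inclusive`` (the default).  Since ``f_lo_hz > 0`` the DC term is
    always removed, and the Nyquist bin is removed whenever
    ``f_hi_hz < fs/2``.
    """

    f_lo_hz: float = 10.0
    f_hi_hz: float = 375.0
    edge_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.f_lo_hz < self.f_hi_hz):
            raise ValueError("require 0 < f_lo_hz < f_hi_hz")

    def validate_rate(self, fs: float) -> None:
        if self.f_hi_hz >= fs / 2:
            raise ValueError(
                f"upper cutoff {self.f_hi_hz} Hz must lie below the Nyquist "
                f"frequency {fs / 2} Hz"
            )


@dataclass
class RmsSeries:
    """Per-window RMS values with window start times.

    ``values[i]`` is the RMS over ``[window_start_s[i],
    window_start_s[i] + window_s)``.  A trailing incomplete window is
    dropped, never padded.
    """

    window_s: float
    values: np.ndarray
    window_start_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        if self.values.size != self.window_start_s.size:
            raise ValueError("values and window_start_s must have equal length")

    @property
    def n_windows(self) -> int:
        return int(self.values.size)

    @property
    def window_end_s(self) -> np.ndarray:
        return self.window_start_s + self.window_s


def vector_norm(gx, gy, gz) -> np.ndarray:
    """Omnidirectional acceleration magnitude, elementwise
    ``sqrt(gx^2 + gy^2 + gz^2)``."""
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    gz = np.asarray(gz, dtype=float)
    if not (gx.shape == gy.shape == gz.shape):
        raise ValueError("axis arrays must have identical shape")
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def band_mask(n: int, fs: float, spec: BandpassSpec) -> np.ndarray:
    """Boolean mask over the ``n//2 + 1`` one-sided (rfft) frequency bins.

    Bin ``k`` is associated with frequency ``k * fs / n``; mirrored bins
    follow their conjugate partner, so the mask is defined one-sided only.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if spec.edge_inclusive:
        return (freqs >= spec.f_lo_hz) & (freqs <= spec.f_hi_hz)
    return (freqs > spec.f_lo_hz) & (freqs < spec.f_hi_hz)


def inband_power_fraction(n: int, fs: float, spec: BandpassSpec) -> float:
    """Expected fraction of white-noise power retained by the filter.

    Interior rfft bins each carry ``2/n`` of the expected power of a real
    white input; the DC and (for even ``n``) Nyquist bins carry ``1/n``.
    """
    mask = band_mask(n, fs, spec)
    weights = np.full(mask.size, 2.0 / n)
    weights[0] = 1.0 / n
    if n % 2 == 0:
        weights[-1] = 1.0 / n
    return float(weights[mask].sum())


def fft_bandpass(x, fs: float, spec: BandpassSpec | None = None) -> np.ndarray:
    """Brick-wall bandpass by zeroing out-of-band Fourier coefficients.

    The forward transform, coefficient zeroing and inverse transform use
    the real-input FFT, whose inverse is the conjugate-symmetric
    reconstruction: the output is purely real by construction and has the
    same length as the input.
    """
    if spec is None:
        spec = BandpassSpec()
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("input must contain at least two samples")
    spec.validate_rate(fs)
    coeffs = np.fft.rfft(x)
    coeffs[~band_mask(x.size, fs, spec)] = 0.0
    return np.fft.irfft(coeffs, n=x.size)


def _blocked(x: np.ndarray, fs: float, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Reshape into complete non-overlapping blocks; drop the trailing rest."""
    block = int(round(window_s * fs))
    if block < 1:
        raise ValueError("window must span at least one sample")
    n_windows = x.size // block
    blocks = x[: n_windows * block].reshape(n_windows, block)
    starts = np.arange(n_windows) * block / fs
    return blocks, starts


def windowed_rms(x, fs: float, window_s: float = 30.0) -> RmsSeries:
    """RMS over consecutive non-overlapping windows of ``window_s`` seconds.

    A window shorter than the recording yields ``floor(duration / window)``
    values; a window longer than the recording yields an empty series,
    flagged in the metadata rather than raised.
    """
    x = np.asarray(x, dtype=float)
    blocks, starts = _blocked(x, fs, window_s)
    values = np.sqrt(np.mean(blocks * blocks, axis=1)) if blocks.size else np.empty(0)
    meta = {"fs": fs}
    if blocks.shape[0] == 0:
        meta["empty_reason"] = "window longer than recording"
    return RmsSeries(window_s=window_s, values=values, window_start_s=starts, metadata=meta)


def windowed_mean(x, fs: float, window_s: float = 30.0) -> RmsSeries:
    """Mean over the same non-overlapping windows (for slow aux channels)."""
    x = np.asarray(x, dtype=float)
    blocks, starts = _blocked(x, fs, window_s)
    values = blocks.mean(axis=1) if blocks.size else np.empty(0)
    return RmsSeries(window_s=window_s, values=values, window_start_s=starts,
                     metadata={"fs": fs, "reduction": "mean"})


def process_recording(
    rec: AccelerometerRecording,
    spec: BandpassSpec | None = None,
    window_s: float = 30.0,
    order: str = "norm_first",
) -> RmsSeries:
    """Run the full vibration chain on a recording.

    ``order="norm_first"`` (default): magnitude norm, then bandpass, then
    windowed RMS — following the order in which the stages are applied to
    the omnidirectional signal.  ``order="filter_first"``: bandpass each
    axis, then norm, then RMS.  The norm is nonlinear so the two orders are
    not equivalent; the order used is recorded in the series metadata.
    """
    if spec is None:
        spec = BandpassSpec()
    fs = rec.sampling_rate_hz
    if order == "norm_first":
        g = vector_norm(rec.gx, rec.gy, rec.gz)
        filtered = fft_bandpass(g, fs, spec)
    elif order == "filter_first":
        filtered = vector_norm(
            fft_bandpass(rec.gx, fs, spec),
            fft_bandpass(rec.gy, fs, spec),
            fft_bandpass(rec.gz, fs, spec),
        )
    else:
        raise ValueError(f"unknown pipeline order {order!r}")
    series = windowed_rms(filtered, fs, window_s)
    series.metadata.update(
        {
            "order": order,
            "f_lo_hz": spec.f_lo_hz,
            "f_hi_hz": spec.f_hi_hz,
            "edge_inclusive": spec.edge_inclusive,
            "window_s": window_s,
            "subject_id": rec.subject_id,
        }
    )
    return series
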