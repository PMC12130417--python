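"""Synthetic ECMO vibration/pressure cohorts with ground-truth effects.

No public recordings of oxygenator-mounted accelerometry exist, so every
downstream stage is exercised on simulated cohorts that emulate the
two-phase experimental protocol: a pump-speed sweep (low / medium / high
rpm, flows 3.5 / 4.0 / 4.5 L/min) followed by anticoagulation reversal with
a 60-min watch and extraction timepoints at 15 / 30 / 60 min.

Generative model (per subject)
------------------------------
Vibration is modelled as a scalar process along the sensor's mount axis
``u`` (a unit vector parallel to the gravity offset), so each axis reads
``g_a(t) = u_a * (|G| + v(t))`` with

    v(t) = sum_k A_k sin(2 pi k theta(t) + phi_k)      pump harmonics,
                                                        f0 = rpm/60 Hz
         + D sin(2 pi f_drift t)                        sub-band drift
         + eps(t),   eps white Gaussian with
           sd(t) = sigma0 * (Q(t)/Q_ref)^e * (1 + gain(t))

The triaxial norm is then exactly ``| |G| + v(t) |``, which stays positive
for the default amplitudes, so the injected in-band power — and hence the
expected windowed RMS — is available in closed form instead of having to be
measured through the very pipeline under test.  Componentwise the model is
still "DC offset + harmonics + white Gaussian noise" per axis; the per-axis
noise is simply fully correlated across axes.

Flow-dependent broadband noise (``sigma proportional to Q^e``) carries the
pump-speed effect; a monotone logistic gain after the reversal event
carries the thrombosis effect.  Transmembrane pressure responds to the same
clot profile with a configurable lag, which is what makes vibration-first
detection a property of the model rather than an accident of noise.

Calibration
-----------
The free effect parameters (flow-noise exponent, baseline noise power,
thrombosis gain) are solved so that the *expected* cohort-median relative
RMS changes equal the configured targets: +23.1 % at medium rpm, +135.0 %
at high rpm, and +6.4 % at the first post-reversal timepoint.  These are
generator calibration defaults; tests verify their statistical recovery by
the pipeline, never the targets against themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .dsp import BandpassSpec, RmsSeries, inband_power_fraction
from .signal_core import (
    AccelerometerRecording,
    CohortManifest,
    ManifestEntry,
    ProtocolTimeline,
    write_manifest,
    write_recording,
    write_timeline,
)

__all__ = [
    "PumpModel",
    "ThrombosisModel",
    "PressureModel",
    "SimCohortConfig",
    "SubjectParams",
    "SimulatedSubject",
    "SimulatedCohort",
    "LeadTimeResult",
    "simulate_recording",
    "simulate_cohort",
    "detection_lead_time",
    "expected_response_fractions",
    "subject_seed",
]

#: Multiplier used to derive per-subject seeds from the master seed; chosen
#: prime and large enough that cohorts with nearby master seeds do not share
#: subject streams.  subject_seed = (seed + 1_000_003 * (index + 1)) mod 2^31.
_SEED_STRIDE = 1_000_003
_SEED_MOD = 2**31

#: Tolerance for comparing window boundaries against protocol instants;
#: boundaries derived from a CSV-inferred sampling rate are off by ulps.
_TIME_EPS = 1e-6


def subject_seed(master_seed: int, index: int) -> int:
    return (int(master_seed) + _SEED_STRIDE * (index + 1)) % _SEED_MOD


@dataclass(frozen=True)
class PumpModel:
    """Centrifugal-pump vibration source: harmonics of f0 = rpm/60 Hz."""

    rpm: float
    harmonic_amplitudes: tuple[float, ...]
    harmonic_phases: tuple[float, ...]

    @property
    def fundamental_hz(self) -> float:
        return self.rpm / 60.0

    def validate_rate(self, fs: float) -> None:
        k = len(self.harmonic_amplitudes)
        if k and self.fundamental_hz * k >= fs / 2:
            raise ValueError(
                f"harmonic {k} of {self.fundamental_hz} Hz violates the "
                f"Nyquist limit {fs / 2} Hz"
            )


@dataclass(frozen=True)
class ThrombosisModel:
    """Phenomenological broadband-gain rise after anticoagulation reversal.

    gain(t) = max_gain * profile(t - onset_s), with a logistic-shaped
    saturating profile that is 0 at onset and tends to 1; rise_time_s is
    the logistic time constant.  This is a stated effect model for the
    vibration change that follows reversal, not clot physiology.
    """

    onset_s: float
    rise_time_s: float
    max_gain: float

    def profile(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        post = t >= self.onset_s
        x = (t[post] - self.onset_s) / self.rise_time_s
        out[post] = 2.0 / (1.0 + np.exp(-x)) - 1.0
        return out

    def gain(self, t: np.ndarray | float) -> np.ndarray:
        return self.max_gain * self.profile(t)


@dataclass(frozen=True)
class PressureModel:
    """Transmembrane pressure: quadratic in flow plus a lagged clot term.

    dP(t) = a_lin * Q + a_quad * Q^2 + clot_coeff * profile(t - lag_s)
    + white noise.  The default flow coefficients interpolate the observed
    12 / 18 / 26 mmHg at 3.5 / 4.0 / 4.5 L/min; the clot term reuses the
    thrombosis profile delayed by ``lag_s`` so that the pressure response
    trails the vibration response by a configurable interval.
    """

    a_lin: float = -4.794
    a_quad: float = 2.349
    clot_coeff: float = 9.0
    lag_s: float = 900.0
    noise_sd: float = 0.5

    def baseline(self, flow_lpm: float) -> float:
        return self.a_lin * flow_lpm + self.a_quad * flow_lpm**2


@dataclass
class SimCohortConfig:
    """Generative parameters for one synthetic cohort.

    Durations default to the experimental protocol scale (10-min steady
    pump segments, 60-min post-reversal watch with extraction at 15/30/60
    min); :meth:`compact` and :meth:`lead_time_study` provide shorter
    protocols for fast statistical checks.  All segment boundaries should
    be multiples of ``window_s`` so that extraction windows sit wholly
    inside steady segments.
    """

    n_subjects: int = 7
    fs: float = 1000.0
    seed: int = 0
    window_s: float = 30.0

    # band used when calibrating in-band noise power (matches the analysis)
    f_lo_hz: float = 10.0
    f_hi_hz: float = 375.0

    # phase 1: pump-speed sweep (rpm even so every window holds an integer
    # number of pump cycles)
    include_phase1: bool = True
    pump_rpm: tuple[float, ...] = (2800.0, 3250.0, 3750.0)
    pump_flow_lpm: tuple[float, ...] = (3.5, 4.0, 4.5)
    segment_s: float = 600.0

    # phase 2: anticoagulation reversal
    pre_reversal_s: float = 600.0
    reversal_offsets_s: tuple[float, ...] = (900.0, 1800.0, 3600.0)
    reversal_labels: tuple[str, ...] = ("t15", "t30", "t60")
    post_reversal_s: float = 3600.0
    flow_dip: bool = True
    post_reversal_flows: tuple[float, ...] = (3.3, 3.2, 3.3)
    rise_time_s: float = 200.0

    # vibration model
    gravity_vector: tuple[float, float, float] = (2 / 7, 3 / 7, 6 / 7)
    harmonic_profile: tuple[float, ...] = (1.0, 0.5, 0.25)
    rms_baseline_g: float = 0.06
    drift_amplitude_g: float = 0.02
    drift_freq_hz: float = 0.3

    # calibration targets: expected cohort-median relative RMS change (%)
    drms_medium_pct: float = 23.1
    drms_high_pct: float = 135.0
    drms_reversal_pct: float = 6.4

    # between-subject multiplicative log-normal spreads
    amp_sigma_ln: float = 0.10
    noise_sigma_ln: float = 0.10
    gain_sigma_ln: float = 0.15

    pressure: PressureModel = field(default_factory=PressureModel)
    include_hemodynamics: bool = True

    @classmethod
    def compact(cls, seed: int = 0, **overrides) -> "SimCohortConfig":
        """Short protocol for statistical tests: 90-s pump segments and a
        6-min reversal watch with extraction at 90/180/270 s."""
        params = dict(
            seed=seed,
            segment_s=90.0,
            pre_reversal_s=90.0,
            reversal_offsets_s=(90.0, 180.0, 270.0),
            post_reversal_s=360.0,
            rise_time_s=20.0,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def lead_time_study(cls, seed: int = 0, lag_s: float = 900.0, **overrides) -> "SimCohortConfig":
        """Phase-2-only protocol for detection-latency experiments.

        The pump sweep is skipped and the post-reversal flow dip disabled so
        both channels are pure lagged logistic rises and matched fractional
        thresholds cross at the same point of the shared profile.
        """
        params = dict(
            seed=seed,
            include_phase1=False,
            pre_reversal_s=120.0,
            reversal_offsets_s=(300.0, 600.0, 900.0),
            post_reversal_s=1500.0,
            flow_dip=False,
            rise_time_s=120.0,
            pressure=PressureModel(lag_s=lag_s),
            include_hemodynamics=False,
        )
        params.update(overrides)
        return cls(**params)

    # -- protocol geometry -------------------------------------------------

    def segments(self) -> list[tuple[float, float, float, float, str]]:
        """(start_s, end_s, rpm, flow_lpm, label) for each steady segment."""
        segs = []
        t = 0.0
        base_rpm, base_flow = self.pump_rpm[0], self.pump_flow_lpm[0]
        if self.include_phase1:
            labels = ("baseline_start", "pump_medium", "pump_high")
            for label, rpm, flow in zip(labels, self.pump_rpm, self.pump_flow_lpm):
                segs.append((t, t + self.segment_s, rpm, flow, label))
                t += self.segment_s
        segs.append((t, t + self.pre_reversal_s, base_rpm, base_flow, "pre_reversal"))
        t += self.pre_reversal_s
        reversal = t
        flows = self.post_reversal_flows if self.flow_dip else (base_flow,) * 3
        bounds = [reversal] + [reversal + off for off in self.reversal_offsets_s]
        labels = ("reversal", *self.reversal_labels[:-1])
        for i, label in enumerate(labels):
            segs.append((bounds[i], bounds[i + 1], base_rpm, flows[min(i, len(flows) - 1)], label))
        end = reversal + self.post_reversal_s
        segs.append((bounds[-1], end, base_rpm, flows[-1], self.reversal_labels[-1]))
        return segs

    @property
    def reversal_time_s(self) -> float:
        t = self.segment_s * 3 if self.include_phase1 else 0.0
        return t + self.pre_reversal_s

    @property
    def duration_s(self) -> float:
        return self.reversal_time_s + self.post_reversal_s

    def timeline(self) -> ProtocolTimeline:
        events = [(s, label) for s, _, _, _, label in self.segments()]
        events.append((self.duration_s, "end"))
        return ProtocolTimeline(events=events)

    def extraction_times(self) -> dict[str, float]:
        """Timepoint label -> extraction instant (end of its steady window).

        Steady pump segments are extracted at their end; reversal
        timepoints at their event time, i.e. the end of the sub-segment
        that precedes them.
        """
        out: dict[str, float] = {}
        rename = {"baseline_start": "baseline", "pump_medium": "medium", "pump_high": "high"}
        for _, end, _, _, label in self.segments():
            if label == "pre_reversal":
                out["pre_reversal"] = end
            elif label in rename:
                out[rename[label]] = end
        reversal = self.reversal_time_s
        for off, label in zip(self.reversal_offsets_s, self.reversal_labels):
            out[label] = reversal + off
        return out


# ---------------------------------------------------------------------------
# Calibration: solve the effect parameters from the target medians


@dataclass(frozen=True)
class Calibration:
    flow_exponent: float
    harmonic_amplitudes: tuple[float, ...]
    harmonic_power: float          # in-band harmonic power, g^2
    noise_power_inband: float      # in-band white-noise power at Q_ref, g^2
    noise_sd: float                # per-sample sd at Q_ref, g
    max_gain: float
    inband_fraction: float


def _mean_sq_gain(thromb: ThrombosisModel, t0: float, t1: float, fs: float) -> tuple[float, float]:
    """mean(profile) and mean(profile^2) over [t0, t1) on the sample grid."""
    t = np.arange(int(round(t0 * fs)), int(round(t1 * fs))) / fs
    phi = thromb.profile(t)
    return float(phi.mean()), float((phi * phi).mean())


def calibrate(config: SimCohortConfig) -> Calibration:
    """Solve the generator's effect parameters from its calibration targets.

    The two pump-speed targets determine the flow-noise exponent ``e`` and
    the split of baseline in-band power between harmonics and noise; the
    reversal target then fixes the thrombosis gain given the post-reversal
    flow.  Expected window RMS^2 = harmonic power + in-band noise power,
    since all pump harmonics sit inside the passband and each extraction
    window holds an integer number of pump cycles.
    """
    q_base, q_med, q_high = (
        config.pump_flow_lpm[0],
        config.pump_flow_lpm[1],
        config.pump_flow_lpm[2],
    )
    r_med = 1.0 + config.drms_medium_pct / 100.0
    r_high = 1.0 + config.drms_high_pct / 100.0
    target_ratio = (r_high**2 - 1.0) / (r_med**2 - 1.0)

    def imbalance(e: float) -> float:
        u = (q_med / q_base) ** (2 * e)
        v = (q_high / q_base) ** (2 * e)
        return (v - 1.0) / (u - 1.0) - target_ratio

    e = brentq(imbalance, 0.05, 60.0, xtol=1e-12)
    p0 = config.rms_baseline_g**2
    u = (q_med / q_base) ** (2 * e)
    noise_power = (r_med**2 - 1.0) * p0 / (u - 1.0)
    harm_power = p0 - noise_power
    if harm_power <= 0:
        raise ValueError("calibration targets leave no room for harmonic power")
    rho = np.asarray(config.harmonic_profile, dtype=float)
    scale = np.sqrt(2.0 * harm_power / float((rho * rho).sum()))
    amplitudes = tuple(float(a) for a in rho * scale)

    n_total = int(round(config.duration_s * config.fs))
    spec = BandpassSpec(config.f_lo_hz, config.f_hi_hz)
    beta = inband_power_fraction(n_total, config.fs, spec)
    sigma0 = float(np.sqrt(noise_power / beta))

    # thrombosis gain from the first reversal timepoint's extraction window
    reversal = config.reversal_time_s
    t_x = reversal + config.reversal_offsets_s[0]
    thromb = ThrombosisModel(onset_s=reversal, rise_time_s=config.rise_time_s, max_gain=1.0)
    m1, m2 = _mean_sq_gain(thromb, t_x - config.window_s, t_x, config.fs)
    q_post = config.post_reversal_flows[0] if config.flow_dip else q_base
    q_factor = (q_post / q_base) ** (2 * e)
    r_t = 1.0 + config.drms_reversal_pct / 100.0
    target = (r_t**2 * p0 - harm_power) / (noise_power * q_factor)
    if target <= 1.0:
        raise ValueError(
            "reversal target unreachable: post-reversal flow drop removes "
            "more noise power than the thrombosis gain can restore"
        )
    # mean((1 + g*phi)^2) = m2*g^2 + 2*m1*g + 1 = target
    disc = 4 * m1 * m1 - 4 * m2 * (1.0 - target)
    max_gain = (-2 * m1 + np.sqrt(disc)) / (2 * m2)
    return Calibration(
        flow_exponent=float(e),
        harmonic_amplitudes=amplitudes,
        harmonic_power=float(harm_power),
        noise_power_inband=float(noise_power),
        noise_sd=sigma0,
        max_gain=float(max_gain),
        inband_fraction=float(beta),
    )


# ---------------------------------------------------------------------------
# Per-subject generation


@dataclass(frozen=True)
class SubjectParams:
    """Drawn per-subject parameters (multiplicative log-normal spreads)."""

    subject_id: str
    seed: int
    amp_mult: float
    noise_mult: float
    gain_mult: float
    hr_base: float = 85.0
    map_base: float = 75.0
    cvp_base: float = 6.0
    mpap_base: float = 20.0
    spo2_base: float = 100.0
    act_base_s: float = 230.0


def draw_subject_params(config: SimCohortConfig, index: int) -> SubjectParams:
    seed = subject_seed(config.seed, index)
    rng = np.random.default_rng(seed)
    amp = float(rng.lognormal(0.0, config.amp_sigma_ln))
    noise = float(rng.lognormal(0.0, config.noise_sigma_ln))
    gain = float(rng.lognormal(0.0, config.gain_sigma_ln))
    return SubjectParams(
        subject_id=f"pig{index + 1:02d}",
        seed=seed,
        amp_mult=amp,
        noise_mult=noise,
        gain_mult=gain,
        hr_base=float(rng.normal(85.0, 12.0)),
        map_base=float(rng.normal(75.0, 6.0)),
        cvp_base=float(rng.normal(6.0, 1.5)),
        mpap_base=float(rng.normal(20.0, 1.5)),
        spo2_base=float(np.clip(rng.normal(99.5, 0.5), 90.0, 100.0)),
        act_base_s=float(rng.normal(230.0, 20.0)),
    )


def _piecewise(config: SimCohortConfig, n: int, values_per_segment: list[float]) -> np.ndarray:
    out = np.empty(n)
    fs = config.fs
    for (start, end, *_), val in zip(config.segments(), values_per_segment):
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        out[i0:i1] = val
    return out


def _act_schedule(config: SimCohortConfig, params: SubjectParams, t: np.ndarray) -> np.ndarray:
    """Activated clotting time: flat pre-reversal, then a piecewise-linear
    fall through the timepoint nodes (relative profile from the protocol's
    220 -> 175 -> 125 -> 117 s course)."""
    reversal = config.reversal_time_s
    rel = np.array([1.0, 175 / 220, 125 / 220, 117 / 220]) * params.act_base_s
    nodes = np.array([reversal, *(reversal + np.asarray(config.reversal_offsets_s))])
    act = np.full(t.size, params.act_base_s)
    post = t >= reversal
    act[post] = np.interp(t[post], nodes, rel)
    return act


@dataclass
class SimulatedSubject:
    recording: AccelerometerRecording
    timeline: ProtocolTimeline
    params: SubjectParams
    expected_rms_g: dict[str, float]
    expected_drms_pct: dict[str, float]


def _expected_rms(
    config: SimCohortConfig,
    cal: Calibration,
    params: SubjectParams,
    thromb: ThrombosisModel,
) -> tuple[dict[str, float], dict[str, float]]:
    """Closed-form expected window RMS (and relative change) per timepoint."""
    q_base = config.pump_flow_lpm[0]
    harm = cal.harmonic_power * params.amp_mult**2
    noise0 = cal.noise_power_inband * params.noise_mult**2
    times = config.extraction_times()

    def flow_at(t_x: float) -> float:
        for start, end, _, flow, _ in config.segments():
            if start < t_x <= end:
                return flow
        raise ValueError(f"extraction time {t_x} outside protocol")

    rms: dict[str, float] = {}
    for label, t_x in times.items():
        flow = flow_at(t_x)
        q_factor = (flow / q_base) ** (2 * cal.flow_exponent)
        m1, m2 = _mean_sq_gain(thromb, t_x - config.window_s, t_x, config.fs)
        g = thromb.max_gain
        gain_factor = m2 * g * g + 2 * m1 * g + 1.0
        rms[label] = float(np.sqrt(harm + noise0 * q_factor * gain_factor))

    drms: dict[str, float] = {}
    if config.include_phase1:
        for label in ("medium", "high"):
            drms[label] = 100.0 * (rms[label] / rms["baseline"] - 1.0)
    for label in config.reversal_labels:
        drms[label] = 100.0 * (rms[label] / rms["pre_reversal"] - 1.0)
    return rms, drms


def simulate_recording(
    params: SubjectParams,
    config: SimCohortConfig,
    calibration: Calibration | None = None,
) -> SimulatedSubject:
    """Generate one subject's recording, timeline and ground truth.

    Deterministic given ``params.seed`` and the config.  Pump harmonics
    accumulate phase continuously across rpm steps; broadband noise tracks
    flow and the post-reversal thrombosis gain; the pressure channel tracks
    flow and the lagged clot profile.
    """
    cal = calibration if calibration is not None else calibrate(config)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    segs = config.segments()

    fund = PumpModel(
        rpm=max(rpm for _, _, rpm, _, _ in segs),
        harmonic_amplitudes=cal.harmonic_amplitudes,
        harmonic_phases=(0.0,) * len(cal.harmonic_amplitudes),
    )
    fund.validate_rate(fs)

    rpm_t = _piecewise(config, n, [rpm for _, _, rpm, _, _ in segs])
    flow_t = _piecewise(config, n, [flow for _, _, _, flow, _ in segs])
    theta = np.cumsum(rpm_t / 60.0) / fs  # cycles, phase-continuous

    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0.0, 2 * np.pi, size=len(cal.harmonic_amplitudes))
    v = np.zeros(n)
    for k, (amp, phi) in enumerate(zip(cal.harmonic_amplitudes, phases), start=1):
        v += params.amp_mult * amp * np.sin(2 * np.pi * k * theta + phi)
    if config.drift_amplitude_g:
        v += config.drift_amplitude_g * np.sin(2 * np.pi * config.drift_freq_hz * t)

    reversal = config.reversal_time_s
    thromb = ThrombosisModel(
        onset_s=reversal,
        rise_time_s=config.rise_time_s,
        max_gain=cal.max_gain * params.gain_mult,
    )
    q_base = config.pump_flow_lpm[0]
    sd_t = (
        cal.noise_sd
        * params.noise_mult
        * (flow_t / q_base) ** cal.flow_exponent
        * (1.0 + thromb.gain(t))
    )
    v += sd_t * rng.standard_normal(n)

    gvec = np.asarray(config.gravity_vector, dtype=float)
    g_mag = float(np.linalg.norm(gvec))
    # with no gravity offset the mount axis defaults to z
    u = gvec / g_mag if g_mag > 0 else np.array([0.0, 0.0, 1.0])
    scalar = g_mag + v
    gx, gy, gz = u[0] * scalar, u[1] * scalar, u[2] * scalar

    pm = config.pressure
    # the clot term shares the vibration profile, delayed by the lag
    clot = pm.clot_coeff * params.gain_mult * thromb.profile(t - pm.lag_s)
    dp = pm.baseline(flow_t) + clot + pm.noise_sd * rng.standard_normal(n)
    aux = {
        "delta_p_oxy": dp,
        "ecmo_flow": flow_t + 0.02 * rng.standard_normal(n),
    }
    if config.include_hemodynamics:
        aux["heart_rate"] = params.hr_base + 1.0 * rng.standard_normal(n)
        aux["map"] = params.map_base + 1.0 * rng.standard_normal(n)
        aux["cvp"] = params.cvp_base + 0.3 * rng.standard_normal(n)
        aux["mpap"] = params.mpap_base + 0.3 * rng.standard_normal(n)
        aux["spo2"] = np.minimum(100.0, params.spo2_base + 0.1 * rng.standard_normal(n))
        aux["act"] = _act_schedule(config, params, t)

    rec = AccelerometerRecording(
        sampling_rate_hz=fs,
        gx=gx,
        gy=gy,
        gz=gz,
        aux_channels=aux,
        subject_id=params.subject_id,
    )
    timeline = config.timeline()
    timeline.validate_against(rec)
    exp_rms, exp_drms = _expected_rms(config, cal, params, thromb)
    return SimulatedSubject(
        recording=rec,
        timeline=timeline,
        params=params,
        expected_rms_g=exp_rms,
        expected_drms_pct=exp_drms,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class SimulatedCohort:
    config: SimCohortConfig
    calibration: Calibration
    subjects: list[SimulatedSubject]
    manifest: CohortManifest | None = None

    @property
    def ground_truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_subjects": self.config.n_subjects,
            "calibration": asdict(self.calibration),
            "targets_drms_pct": {
                "medium": self.config.drms_medium_pct,
                "high": self.config.drms_high_pct,
                self.config.reversal_labels[0]: self.config.drms_reversal_pct,
            },
            "subjects": [
                {
                    "subject_id": s.params.subject_id,
                    "seed": s.params.seed,
                    "amp_mult": s.params.amp_mult,
                    "noise_mult": s.params.noise_mult,
                    "gain_mult": s.params.gain_mult,
                    "expected_rms_g": s.expected_rms_g,
                    "expected_drms_pct": s.expected_drms_pct,
                }
                for s in self.subjects
            ],
        }


def simulate_cohort(config: SimCohortConfig, out_dir: str | Path | None = None) -> SimulatedCohort:
    """Generate a cohort; optionally write recordings, timelines, manifest
    and the ground-truth record to ``out_dir``.

    Per-subject parameters come from deterministically derived sub-seeds,
    so cohorts are reproducible subject by subject and byte-identical
    across runs with the same seed.
    """
    cal = calibrate(config)
    subjects = [
        simulate_recording(draw_subject_params(config, i), config, cal)
        for i in range(config.n_subjects)
    ]
    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for s in subjects:
            rec_path = out_dir / f"{s.params.subject_id}_recording.csv"
            tl_path = out_dir / f"{s.params.subject_id}_timeline.csv"
            write_recording(s.recording, rec_path)
            write_timeline(s.timeline, tl_path)
            # store bare filenames so the manifest is relocatable
            entries.append(
                ManifestEntry(s.params.subject_id, rec_path.name, tl_path.name)
            )
        manifest = CohortManifest(entries=entries)
        write_manifest(manifest, out_dir / "manifest.yaml")
        cohort = SimulatedCohort(config, cal, subjects, manifest)
        with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(cohort.ground_truth, fh, indent=2)
        return cohort
    return SimulatedCohort(config, cal, subjects, manifest)


def expected_response_fractions(config: SimCohortConfig) -> tuple[float, float]:
    """Expected plateau fractional rises (vibration RMS, pressure) over
    their pre-reversal baselines, at cohort-median subject parameters.

    Used to set matched detection thresholds for lead-time studies.
    """
    cal = calibrate(config)
    q_base = config.pump_flow_lpm[0]
    q_post = config.post_reversal_flows[-1] if config.flow_dip else q_base
    q_factor = (q_post / q_base) ** (2 * cal.flow_exponent)
    p0 = cal.harmonic_power + cal.noise_power_inband
    plateau = cal.harmonic_power + cal.noise_power_inband * q_factor * (1.0 + cal.max_gain) ** 2
    rms_frac = float(np.sqrt(plateau / p0) - 1.0)
    pm = config.pressure
    dp_frac = float(
        (pm.baseline(q_post) + pm.clot_coeff) / pm.baseline(q_base) - 1.0
    )
    return rms_frac, dp_frac


# ---------------------------------------------------------------------------
# Detection lead time


@dataclass
class LeadTimeResult:
    """Threshold-crossing comparison of the two surveillance channels.

    ``lead_s > 0`` means the vibration channel crossed its threshold before
    the pressure channel.  A channel that never crosses is an open outcome:
    its crossing time is None and, if the other channel crossed, the lead is
    right-censored at the remaining observation span (``censored = True``).
    """

    t_rms_cross: float | None
    t_dp_cross: float | None
    lead_s: float | None
    rms_baseline: float
    dp_baseline: float
    censored: bool = False


def _first_crossing(
    series: RmsSeries, baseline: float, threshold_frac: float, after_s: float
) -> float | None:
    mask = (series.window_start_s >= after_s - _TIME_EPS) & (
        series.values >= baseline * (1.0 + threshold_frac)
    )
    idx = np.flatnonzero(mask)
    return float(series.window_start_s[idx[0]]) if idx.size else None


def detection_lead_time(
    rms_series: RmsSeries,
    dp_series: RmsSeries,
    reversal_time_s: float,
    rms_threshold_frac: float,
    dp_threshold_frac: float,
    baseline_start_s: float = 0.0,
) -> LeadTimeResult:
    """First post-reversal window at which each channel exceeds its
    pre-reversal baseline by its fractional threshold.

    Baselines are the medians of the complete windows lying wholly inside
    ``[baseline_start_s, reversal_time_s)``.
    """

    def baseline_of(series: RmsSeries) -> float:
        mask = (series.window_start_s >= baseline_start_s - _TIME_EPS) & (
            series.window_end_s <= reversal_time_s + _TIME_EPS
        )
        if not mask.any():
            raise ValueError("no complete pre-reversal baseline windows")
        return float(np.median(series.values[mask]))

    rms_base = baseline_of(rms_series)
    dp_base = baseline_of(dp_series)
    t_rms = _first_crossing(rms_series, rms_base, rms_threshold_frac, reversal_time_s)
    t_dp = _first_crossing(dp_series, dp_base, dp_threshold_frac, reversal_time_s)
    lead = None
    censored = False
    if t_rms is not None and t_dp is not None:
        lead = t_dp - t_rms
    elif t_rms is not None and t_dp is None:
        # pressure never crossed: vibration lead at least to end of record
        end = float(rms_series.window_start_s[-1] + rms_series.window_s)
        lead = end - t_rms
        censored = True
    elif t_rms is None and t_dp is not None:
        end = float(dp_series.window_start_s[-1] + dp_series.window_s)
        lead = -(end - t_dp)
        censored = True
    return LeadTimeResult(
        t_rms_cross=t_rms,
        t_dp_cross=t_dp,
        lead_s=lead,
        rms_baseline=rms_base,
        dp_baseline=dp_base,
        censored=censored,
    )
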