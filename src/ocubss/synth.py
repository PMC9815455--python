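"""Synthetic continuous-reading MEG with known ground truth.

Generates a gaze trace of a reader scanning pages of text (fixations,
forward saccades, regressions, line-return sweeps, sporadic blinks), turns
it into ocular artifact sources with eye-dipole sensor topographies, adds
oscillatory brain sources with 1/f background on a spherical source grid,
and assembles everything into a :class:`~ocubss.core.Recording` plus a
:class:`SimulationTruth` that stores the generative sides of
``x(t) = A s(t) + n(t)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .core import EOG_H, EOG_V, EYETRACK, GRAD, Recording, SensorArray
from .forward import (ForwardGrid, default_eye_positions, leadfield_sphere,
                      make_forward_grid, make_sensor_array)

__all__ = [
    "SimConfig",
    "GazeTrace",
    "SimulationTruth",
    "generate_gaze",
    "ocular_signals",
    "assemble_recording",
    "simulate",
    "band_power_fraction",
    "FIXATION",
    "SACCADE",
    "REGRESSION",
    "RETURN_SWEEP",
    "BLINK",
]

# per-sample event labels
FIXATION, SACCADE, REGRESSION, RETURN_SWEEP, BLINK = 0, 1, 2, 3, 4
LABEL_NAMES = {FIXATION: "fixation", SACCADE: "saccade", REGRESSION: "regression",
               RETURN_SWEEP: "return_sweep", BLINK: "blink"}


@dataclass
class SimConfig:
    """Parameters of the synthetic reading session.

    Defaults follow the target phenomenology: 102 two-gradiometer sites,
    600 Hz sampling, pages of eight lines spanning 15.4 x 7.7 degrees,
    fixations of ~220 +- 60 ms, ~2 degree forward saccades with 10-15 %
    regressions, and sporadic blinks of some hundreds of milliseconds.
    """

    n_sensor_sites: int = 102
    sfreq: float = 600.0
    n_pages: int = 3
    page_duration: float = 20.0          # s
    n_scanning_pages: int = 0
    fixation_mean: float = 220.0         # ms
    fixation_sd: float = 60.0            # ms
    saccade_amplitude_mean: float = 2.0  # degrees
    saccade_amplitude_sd: float = 0.5    # degrees
    regression_prob: float = 0.125
    lines_per_page: int = 8
    blink_rate: float = 0.2              # events / s
    blink_duration: float = 300.0        # ms
    page_width_deg: float = 15.4
    page_height_deg: float = 7.7
    n_brain_sources: int = 12
    snr_artifact: Optional[float] = 0.0  # dB, artifact vs brain at frontal sensors
    sensor_snr_db: float = 20.0          # brain signal vs white sensor noise
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.regression_prob <= 1.0):
            raise ValueError("regression_prob must lie in [0, 1]")
        if not (100.0 <= self.blink_duration <= 500.0):
            raise ValueError("blink_duration must be within 100-500 ms")
        for name in ("sfreq", "page_duration", "fixation_mean",
                     "saccade_amplitude_mean", "page_width_deg", "page_height_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.blink_rate < 0 or self.fixation_sd < 0 or self.saccade_amplitude_sd < 0:
            raise ValueError("rates and spreads must be non-negative")
        if self.n_pages < 1 or self.lines_per_page < 1 or self.n_sensor_sites < 2:
            raise ValueError("counts must be positive")

    @property
    def total_pages(self) -> int:
        return self.n_pages + self.n_scanning_pages


@dataclass
class GazeTrace:
    """Sampled gaze with per-sample event labels and a generator event log."""

    time: np.ndarray
    horizontal_angle: np.ndarray   # degrees, page centre = 0
    vertical_angle: np.ndarray
    labels: np.ndarray             # int8, FIXATION..BLINK
    blink: np.ndarray              # bool, gaze-undefined flag
    sfreq: float
    events: list = field(default_factory=list)  # (kind, onset_sample, page)

    @property
    def n_samples(self) -> int:
        return self.time.size

    def blink_onsets(self) -> np.ndarray:
        b = self.blink.astype(int)
        return np.flatnonzero(np.diff(np.concatenate([[0], b])) == 1)


@dataclass
class SimulationTruth:
    """Generative ground truth: sources s(t), mixing columns A, noise n(t).

    ``sensor_noise`` is not stored densely; it is regenerated on demand
    from ``noise_seed`` so large simulations stay memory-friendly while the
    construction identity remains exactly checkable.
    """

    artifact_sources: dict            # name -> (T,) time course
    artifact_mixing: dict             # name -> (m,) gradiometer pattern
    gaze: GazeTrace
    brain_sources: np.ndarray = None  # (n_b, T)
    brain_mixing: np.ndarray = None   # (m, n_b)
    brain_points: np.ndarray = None   # grid indices
    noise_seed: Optional[int] = None
    noise_sigma: float = 0.0
    n_meg: int = 0
    eye_positions: np.ndarray = field(default_factory=default_eye_positions)

    def artifact_signal(self) -> np.ndarray:
        names = sorted(self.artifact_sources)
        out = np.zeros((self.n_meg, self.gaze.n_samples))
        for name in names:
            out += np.outer(self.artifact_mixing[name], self.artifact_sources[name])
        return out

    def brain_signal(self) -> np.ndarray:
        if self.brain_sources is None or self.brain_sources.size == 0:
            return np.zeros((self.n_meg, self.gaze.n_samples))
        return self.brain_mixing @ self.brain_sources

    def noise(self) -> np.ndarray:
        if self.noise_seed is None or self.noise_sigma == 0.0:
            return np.zeros((self.n_meg, self.gaze.n_samples))
        rng = np.random.default_rng(self.noise_seed)
        return self.noise_sigma * rng.standard_normal((self.n_meg, self.gaze.n_samples))


# ---------------------------------------------------------------------------
# gaze generation
# ---------------------------------------------------------------------------

def _saccade_duration_s(amplitude_deg: float) -> float:
    # main-sequence approximation: ~21 ms intercept + 2.2 ms/degree
    return 0.021 + 0.0022 * abs(amplitude_deg)


def estimate_line_duration(config: SimConfig) -> float:
    """Deterministic single-line duration for an exact fixation grid."""
    amp = config.saccade_amplitude_mean
    n_fix = int(np.floor(config.page_width_deg / amp)) + 1
    fix = config.fixation_mean / 1000.0
    sacc = _saccade_duration_s(amp)
    sweep = _saccade_duration_s(config.page_width_deg)
    return n_fix * (fix + sacc) - sacc + sweep


def generate_gaze(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GazeTrace:
    """Simulate a reading gaze trace.

    Alternates lognormal-duration fixations with saccades; forward saccades
    advance rightward, regressions (probability ``regression_prob``) move
    backward, and the line end triggers a return sweep back to the line
    start one line down. After ``lines_per_page`` lines the gaze returns to
    the top of the page. Blinks are a Poisson process; blink samples carry
    the gaze-undefined flag.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    sf = config.sfreq
    page_n = int(round(config.page_duration * sf))
    if config.page_duration < estimate_line_duration(config):
        raise ValueError("page_duration too short to hold a single line of reading")
    total = config.total_pages * page_n

    h = np.empty(total)
    v = np.empty(total)
    labels = np.zeros(total, dtype=np.int8)
    events: list = []

    half_w = config.page_width_deg / 2.0
    line_h = config.page_height_deg / config.lines_per_page
    top_v = config.page_height_deg / 2.0 - line_h / 2.0

    fix_mean_s = config.fixation_mean / 1000.0
    fix_sd_s = config.fixation_sd / 1000.0
    if fix_sd_s > 0:
        # lognormal parametrized by its own mean/sd
        s2 = np.log(1.0 + (fix_sd_s / fix_mean_s) ** 2)
        ln_mu, ln_sig = np.log(fix_mean_s) - s2 / 2.0, np.sqrt(s2)

    for page in range(config.total_pages):
        t = page * page_n
        end = t + page_n
        x, y = -half_w, top_v
        line = 0
        while t < end:
            # fixation
            if fix_sd_s > 0:
                dur = rng.lognormal(ln_mu, ln_sig)
            else:
                dur = fix_mean_s
            n_fix = max(1, int(round(dur * sf)))
            stop = min(t + n_fix, end)
            h[t:stop] = x
            v[t:stop] = y
            labels[t:stop] = FIXATION
            t = stop
            if t >= end:
                break
            # saccade target; the regression draw happens only for
            # non-sweep events so the regression fraction is exactly
            # Bernoulli(regression_prob) among ordinary saccades
            if config.saccade_amplitude_sd > 0:
                amp = rng.normal(config.saccade_amplitude_mean, config.saccade_amplitude_sd)
                amp = float(np.clip(amp, 0.5, 2.5 * config.saccade_amplitude_mean))
            else:
                amp = config.saccade_amplitude_mean
            if x + amp > half_w:
                kind = RETURN_SWEEP
                tx = -half_w
                line += 1
                if line >= config.lines_per_page:
                    ty, line = top_v, 0
                else:
                    ty = y - line_h
            elif config.regression_prob > 0 and rng.random() < config.regression_prob:
                kind = REGRESSION
                tx, ty = max(x - 0.75 * amp, -half_w), y
            else:
                kind = SACCADE
                tx, ty = x + amp, y
            move = abs(tx - x) + abs(ty - y)
            n_sac = max(2, int(round(_saccade_duration_s(move) * sf)))
            stop = min(t + n_sac, end)
            ramp = np.linspace(0.0, 1.0, n_sac)[: stop - t]
            ramp = ramp * ramp * (3.0 - 2.0 * ramp)  # smoothstep
            h[t:stop] = x + (tx - x) * ramp
            v[t:stop] = y + (ty - y) * ramp
            labels[t:stop] = kind
            events.append((LABEL_NAMES[kind], t, page))
            x, y = tx, ty
            t = stop

    # blinks: Poisson onsets across the whole run
    blink = np.zeros(total, dtype=bool)
    bdur_n = int(round(config.blink_duration / 1000.0 * sf))
    if config.blink_rate > 0 and bdur_n > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / config.blink_rate)
            onset = int(round(t * sf))
            if onset + bdur_n >= total:
                break
            blink[onset:onset + bdur_n] = True
            labels[onset:onset + bdur_n] = BLINK
            events.append(("blink", onset, onset // page_n))

    return GazeTrace(time=np.arange(total) / sf, horizontal_angle=h,
                     vertical_angle=v, labels=labels, blink=blink,
                     sfreq=sf, events=events)


# ---------------------------------------------------------------------------
# artifact sources
# ---------------------------------------------------------------------------

def _blink_pulse_train(gaze: GazeTrace, config: SimConfig) -> np.ndarray:
    out = np.zeros(gaze.n_samples)
    n = int(round(config.blink_duration / 1000.0 * config.sfreq))
    if n == 0:
        return out
    pulse = np.sin(np.pi * np.arange(n) / n) ** 2  # squared half-sine
    for onset in gaze.blink_onsets():
        stop = min(onset + n, gaze.n_samples)
        out[onset:stop] += pulse[: stop - onset]
    return out


def ocular_signals(gaze: GazeTrace, config: SimConfig,
                   sensors: Optional[SensorArray] = None) -> SimulationTruth:
    """Build artifact sources and their eye-dipole mixing columns.

    The saccade artifact follows gaze *position* (baseline-offset model,
    linear in the gaze angle); its sensor patterns are the leadfields of
    the horizontal/vertical rotation derivatives of a corneo-retinal dipole
    at each eye, summed over eyes. The blink source is a train of squared
    half-sine pulses with an anterior bilateral topography from eyelid
    dipoles just anterior-superior to the eye centres.
    """
    if sensors is None:
        sensors = make_sensor_array(config.n_sensor_sites)
    eyes = default_eye_positions()
    q = 1e-8  # effective corneo-retinal dipole rotation strength, A m / rad

    col_h = np.zeros(sensors.n_channels)
    col_v = np.zeros(sensors.n_channels)
    for eye in eyes:
        col_h += leadfield_sphere(eye, q * np.array([1.0, 0.0, 0.0]), sensors)
        col_v += leadfield_sphere(eye, q * np.array([0.0, 0.0, 1.0]), sensors)
    # eyelid dipoles: slightly different position/orientation than the
    # vertical rotation pattern so blink and vertical-saccade topographies
    # are similar but not collinear
    col_b = np.zeros(sensors.n_channels)
    lid_offset = np.array([0.0, 0.004, 0.010])
    lid_moment = q * np.array([0.0, 0.35, 0.937])
    for eye in eyes:
        pos = eye * 0.97 + lid_offset
        col_b += leadfield_sphere(pos, lid_moment, sensors)

    sacc_h = np.deg2rad(gaze.horizontal_angle - gaze.horizontal_angle.mean())
    sacc_v = np.deg2rad(gaze.vertical_angle - gaze.vertical_angle.mean())
    blink = _blink_pulse_train(gaze, config)

    return SimulationTruth(
        artifact_sources={"saccade_h": sacc_h, "saccade_v": sacc_v, "blink": blink},
        artifact_mixing={"saccade_h": col_h, "saccade_v": col_v, "blink": col_b},
        gaze=gaze,
        n_meg=sensors.n_channels,
        eye_positions=eyes,
    )


# ---------------------------------------------------------------------------
# brain sources + assembly
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def _brain_source(freq: float, n: int, sfreq: float,
                  rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / sfreq
    # slowly drifting amplitude envelope
    env = _pink_noise(n, rng)
    env = signal.sosfiltfilt(signal.butter(2, 0.5, fs=sfreq, output="sos"), env)
    env = 1.0 + 0.5 * env / (np.abs(env).max() + 1e-30)
    osc = env * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    src = osc + 0.7 * _pink_noise(n, rng)
    return src / src.std()


def assemble_recording(truth: SimulationTruth, config: SimConfig,
                       sensors: Optional[SensorArray] = None,
                       grid: Optional[ForwardGrid] = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[Recording, SimulationTruth]:
    """Mix artifact and brain sources onto the sensor array, add noise.

    The returned recording satisfies the construction identity
    ``data_meg == truth.artifact_signal() + truth.brain_signal() + truth.noise()``
    exactly. EOG channels carry scaled eye signals plus frontal brain
    leakage and noise; eye-tracker channels carry the raw gaze and the
    blink flag.
    """
    if sensors is None:
        sensors = make_sensor_array(config.n_sensor_sites)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    gaze = truth.gaze
    n = gaze.n_samples
    m = sensors.n_channels
    if truth.n_meg != m:
        raise ValueError("truth mixing columns do not match the sensor array")

    # brain sources on the grid
    if config.n_brain_sources > 0:
        if grid is None:
            grid = make_forward_grid(sensors, spacing=0.012)
        deep = np.linalg.norm(grid.points, axis=1) < 0.8 * 0.09
        deep &= ~grid.eye_region_mask()
        cand = np.flatnonzero(deep)
        idx = [grid.occipital_point()]
        idx += list(rng.choice(cand, size=config.n_brain_sources - 1, replace=False)) \
            if config.n_brain_sources > 1 else []
        idx = np.array(idx)
        freqs = np.concatenate([[10.0], rng.uniform(2.0, 45.0, config.n_brain_sources - 1)])
        S_b = np.vstack([_brain_source(f, n, config.sfreq, rng) for f in freqs])
        A_b = np.empty((m, len(idx)))
        for k, (p, f) in enumerate(zip(idx, freqs)):
            ang = rng.uniform(0, 2 * np.pi)
            ori = np.cos(ang) * grid.tangentials[p, 0] + np.sin(ang) * grid.tangentials[p, 1]
            A_b[:, k] = leadfield_sphere(grid.points[p], 1e-8 * ori, sensors)
        # calibrate overall brain level to ~1e-12 T/m median channel RMS
        proj = A_b @ S_b
        scale_b = 1e-12 / (np.median(np.sqrt(np.mean(proj ** 2, axis=1))) + 1e-300)
        A_b *= scale_b
        brain = scale_b * proj
        truth.brain_sources, truth.brain_mixing, truth.brain_points = S_b, A_b, idx
    else:
        brain = np.zeros((m, n))
        truth.brain_sources = np.zeros((0, n))
        truth.brain_mixing = np.zeros((m, 0))
        truth.brain_points = np.array([], dtype=int)

    # calibrate artifact level against brain power at frontal sensors
    frontal = np.repeat(sensors.positions[:, 1] > 0.6 * sensors.positions[:, 1].max(), 2)
    art = truth.artifact_signal()
    if config.snr_artifact is None or not np.isfinite(config.snr_artifact):
        g = 0.0
    else:
        rms_art = np.sqrt(np.mean(art[frontal] ** 2))
        rms_brain = np.sqrt(np.mean(brain[frontal] ** 2)) if config.n_brain_sources else 1e-12
        g = 10.0 ** (config.snr_artifact / 20.0) * rms_brain / (rms_art + 1e-300)
    for name in truth.artifact_mixing:
        truth.artifact_mixing[name] = truth.artifact_mixing[name] * g
    art *= g

    # sensor noise, regenerable from its own seed
    sig_rms = np.median(np.sqrt(np.mean(brain ** 2, axis=1))) if config.n_brain_sources \
        else np.median(np.sqrt(np.mean(art ** 2, axis=1)))
    truth.noise_sigma = float(sig_rms * 10.0 ** (-config.sensor_snr_db / 20.0))
    truth.noise_seed = int(rng.integers(0, 2 ** 62))
    meg = art + brain + truth.noise()

    # auxiliary channels
    erng = np.random.default_rng(truth.noise_seed + 1)
    leak = brain[frontal].mean(axis=0) if config.n_brain_sources else np.zeros(n)
    leak = leak / (np.abs(leak).max() + 1e-300)
    heog = (16e-6 * (gaze.horizontal_angle - gaze.horizontal_angle.mean())
            + 5e-6 * leak + 2e-6 * erng.standard_normal(n))
    veog = (16e-6 * (gaze.vertical_angle - gaze.vertical_angle.mean())
            + 150e-6 * truth.artifact_sources["blink"]
            + 5e-6 * leak + 2e-6 * erng.standard_normal(n))

    data = np.vstack([meg, heog, veog, gaze.horizontal_angle,
                      gaze.vertical_angle, gaze.blink.astype(float)])
    ch_names = sensors.channel_names() + ["EOG_H", "EOG_V", "ET_H", "ET_V", "ET_BLINK"]
    ch_types = [GRAD] * m + [EOG_H, EOG_V, EYETRACK, EYETRACK, EYETRACK]
    site_ids = np.concatenate([np.repeat(np.arange(sensors.n_sites), 2),
                               -np.ones(5, dtype=int)])
    pair_ids = np.concatenate([np.tile([0, 1], sensors.n_sites),
                               -np.ones(5, dtype=int)])

    page_n = int(round(config.page_duration * config.sfreq))
    spans = [(i * page_n, (i + 1) * page_n) for i in range(config.total_pages)]
    labels = (["reading"] * config.n_pages + ["scanning"] * config.n_scanning_pages)

    rec = Recording(data=data, ch_names=ch_names, ch_types=ch_types,
                    sfreq=config.sfreq, page_spans=spans, site_ids=site_ids,
                    pair_ids=pair_ids, page_labels=labels, sensors=sensors)
    rec.validate()
    return rec, truth


def simulate(config: SimConfig, sensors: Optional[SensorArray] = None,
             grid: Optional[ForwardGrid] = None,
             ) -> tuple[Recording, SimulationTruth, Optional[ForwardGrid]]:
    """End-to-end synthetic dataset: gaze -> artifacts -> assembled recording."""
    if sensors is None:
        sensors = make_sensor_array(config.n_sensor_sites)
    rng = np.random.default_rng(config.rng_seed)
    gaze = generate_gaze(config, rng)
    truth = ocular_signals(gaze, config, sensors)
    if grid is None and config.n_brain_sources > 0:
        grid = make_forward_grid(sensors, spacing=0.012)
    rec, truth = assemble_recording(truth, config, sensors, grid, rng)
    return rec, truth, grid


# ---------------------------------------------------------------------------
# spectral surrogate
# ---------------------------------------------------------------------------

def band_power_fraction(x: np.ndarray, sfreq: float, band: tuple[float, float],
                        total_band: tuple[float, Optional[float]] = (0.0, None),
                        diff: bool = False, seg_seconds: float = 1.0) -> float:
    """Fraction of Welch power inside ``band`` relative to ``total_band``.

    ``diff=True`` measures the spectrum of the first difference, i.e. the
    artifact's rate-of-change content. Segments are linearly detrended so
    slow within-page ramps do not swamp the estimate.
    """
    x = np.asarray(x, dtype=float)
    if diff:
        x = np.diff(x)
    nper = int(seg_seconds * sfreq)
    f, p = signal.welch(x, fs=sfreq, nperseg=min(nper, x.size),
                        detrend="linear", window="hann")
    lo, hi = band
    t_lo, t_hi = total_band
    t_hi = f[-1] if t_hi is None else t_hi
    tot = p[(f >= t_lo) & (f <= t_hi)].sum()
    if tot <= 0:
        return 0.0
    return float(p[(f >= lo) & (f <= hi)].sum() / tot)
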