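"""Synthetic micromotion recordings with known ground truth.

No study recordings are distributed, so every pipeline stage is exercised
against simulated signals that emulate the phenomenology of a piezoelectric
sheet sensor during sleep:

* a respiration carrier (default 0.25 Hz, 15 breaths/min) whose amplitude
  jumps multiplicatively at posture shifts — the dominant nuisance of
  bed-sensor respiration — and drops by a configurable percentage during
  apnea/hypopnea events, with 3-s cosine-tapered transitions so the planted
  log-envelope dip depth equals ``-ln(1 - depth/100)`` at plateau;
* a ballistocardiogram pulse train (Gaussian-windowed 8-Hz wavelets) at
  beat times whose inter-beat interval carries a cyclic dip-recovery
  pattern anchored to the planted events (the CVHR signature), with
  optional shallow PLM-like dip trains;
* gross body-movement bursts (band-limited 2-3 Hz noise), PLM-like
  mini-bursts, and additive white sensor noise;
* integer quantisation into the signed 24-bit ADC range.

All randomness flows from a single integer seed; identical configurations
produce bit-identical recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .decompose import bandpass_filter
from .errors import ConfigurationError, SaturationError
from .io import ADC_MAX, MicromotionRecord, SubjectMeta


@dataclass(frozen=True)
class BcgConfig:
    """Ballistocardiogram model: beat timing and wavelet shape."""

    mean_rr_ms: float = 1000.0
    rr_sd_ms: float = 50.0
    pulse_freq_hz: float = 8.0
    pulse_amp: float = 10000.0
    pulse_sigma_s: float = 0.1
    cvhr_dip_ms: float = 200.0  # tachogram dip depth anchored to each event


@dataclass(frozen=True)
class PlmConfig:
    """Periodic-leg-movement artifacts: episodic trains of shallow
    heart-rate dips with accompanying movement mini-bursts."""

    enabled: bool = False
    spacing_s: float = 30.0
    dip_ms: float = 150.0
    dip_width_s: float = 18.0
    episode_len_s: float = 300.0
    episode_every_s: float = 1800.0
    movement_amp: float = 30000.0
    movement_burst_s: float = 0.8


@dataclass(frozen=True)
class SimulationConfig:
    """One subject's signal model; see the module docstring for the pieces."""

    duration_s: float = 10800.0
    sampling_rate: float = 100.0
    respiration_hz: float = 0.25
    respiration_amp: float = 30000.0
    event_rate_per_h: float = 15.0
    event_depth_percent: float = 60.0
    event_duration_s: Tuple[float, float] = (25.0, 65.0)
    event_taper_s: float = 3.0
    event_min_gap_s: float = 10.0
    #: Sub-scored breathing-instability spells (amplitude sags not scored as
    #: events): a severity-independent population present in every sleeper,
    #: plus a component proportional to the event rate.  Depth ranges are
    #: uniform in percent reduction.
    shallow_spell_base_per_h: float = 0.45
    shallow_spell_base_depth_percent: Tuple[float, float] = (30.0, 62.0)
    shallow_spell_per_event: float = 0.06
    shallow_spell_depth_percent: Tuple[float, float] = (40.0, 58.0)
    shallow_spell_duration_s: Tuple[float, float] = (12.0, 55.0)
    posture_shift_every_s: float = 1800.0  # 0 disables posture shifts
    shift_factor_range: Tuple[float, float] = (0.5, 2.0)
    bcg: BcgConfig = field(default_factory=BcgConfig)
    movement_burst_rate_per_h: float = 6.0
    burst_amp: float = 60000.0
    burst_duration_s: Tuple[float, float] = (2.0, 5.0)
    plm: PlmConfig = field(default_factory=PlmConfig)
    noise_sd: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.event_depth_percent < 100):
            raise ConfigurationError(
                f"event_depth_percent must be in [0, 100), got {self.event_depth_percent}"
            )
        for name in ("event_rate_per_h", "respiration_amp", "noise_sd",
                     "movement_burst_rate_per_h", "burst_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory for reproducibility")


@dataclass
class GroundTruth:
    """Everything the generator actually wrote into the signal."""

    events: List[Tuple[float, float]]
    true_ahi: float
    shallow_spells: List[Tuple[float, float, float]]  # (start, end, depth %)
    beat_times_s: np.ndarray
    posture_shifts: List[Tuple[float, float]]  # (time, factor applied)
    movement_bursts: List[Tuple[float, float]]  # (start, duration)
    plm_dips: List[float]
    cvhr_dips: List[float]
    duration_h: float


def _place_events(cfg: SimulationConfig, rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Poisson-process event starts thinned to forbid overlap.

    Gaps are exponential with intensity corrected for the dead time taken
    by event durations and the minimum recovery gap, so the realised rate
    tracks the configured rate.
    """
    if cfg.event_rate_per_h <= 0:
        return []
    dmin, dmax = cfg.event_duration_s
    mean_dur = 0.5 * (dmin + dmax)
    cycle = 3600.0 / cfg.event_rate_per_h
    gap_scale = max(5.0, cycle - mean_dur - cfg.event_min_gap_s)
    margin = 60.0
    events: List[Tuple[float, float]] = []
    t = margin + rng.exponential(gap_scale)
    while True:
        dur = rng.uniform(dmin, dmax)
        if t + dur > cfg.duration_s - margin:
            break
        events.append((t, t + dur))
        t = t + dur + cfg.event_min_gap_s + rng.exponential(gap_scale)
    return events


def _place_shallow_spells(
    cfg: SimulationConfig,
    events: Sequence[Tuple[float, float]],
    rng: np.random.Generator,
) -> List[Tuple[float, float, float]]:
    """Sub-scored amplitude sags: a baseline population common to all
    sleepers plus a severity-linked population tied to the event rate."""
    hours = cfg.duration_s / 3600.0
    populations = (
        (cfg.shallow_spell_base_per_h * hours, cfg.shallow_spell_base_depth_percent),
        (
            cfg.shallow_spell_per_event * cfg.event_rate_per_h * hours,
            cfg.shallow_spell_depth_percent,
        ),
    )
    dmin, dmax = cfg.shallow_spell_duration_s
    spells: List[Tuple[float, float, float]] = []
    occupied = list(events)
    for expected, (lo, hi) in populations:
        if expected <= 0:
            continue
        n = rng.poisson(expected)
        for start in np.sort(rng.uniform(60.0, cfg.duration_s - 120.0, size=n)):
            dur = float(rng.uniform(dmin, dmax))
            end = float(start) + dur
            if any(start < e + cfg.event_min_gap_s and end > s - cfg.event_min_gap_s
                   for s, e in occupied):
                continue
            depth = float(rng.uniform(lo, hi))
            spells.append((float(start), end, depth))
            occupied.append((float(start), end))
    spells.sort()
    return spells


def _posture_factor(
    cfg: SimulationConfig, rng: np.random.Generator, t: np.ndarray
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    factor = np.ones_like(t)
    shifts: List[Tuple[float, float]] = []
    if cfg.posture_shift_every_s <= 0:
        return factor, shifts
    lo, hi = cfg.shift_factor_range
    log_lo, log_hi = np.log(lo), np.log(hi)
    time = rng.exponential(cfg.posture_shift_every_s)
    current = 1.0
    while time < cfg.duration_s:
        step = float(np.exp(rng.uniform(log_lo, log_hi)))
        proposed = current * step
        # keep the cumulative amplitude within a physical range
        if not (0.2 <= proposed <= 5.0):
            step = 1.0 / step
            proposed = current * step
        current = proposed
        shifts.append((time, step))
        factor[t >= time] = current
        time += rng.exponential(cfg.posture_shift_every_s)
    return factor, shifts


def _dip_gate(t: np.ndarray, dips, taper: float) -> np.ndarray:
    """Multiplicative amplitude gate: 1 at baseline, 1 - depth inside each
    (start, end, depth_fraction) dip, raised-cosine transitions over the
    taper.  Dip depth in the log-envelope domain therefore equals
    ``-ln(1 - depth)`` at plateau."""
    gate = np.ones_like(t)
    for start, end, depth in dips:
        ramp_in = (t >= start) & (t < start + taper)
        plateau = (t >= start + taper) & (t < end - taper)
        ramp_out = (t >= end - taper) & (t < end)
        u = (t[ramp_in] - start) / taper
        gate[ramp_in] = 1.0 - depth * (1.0 - np.cos(np.pi * u)) / 2.0
        gate[plateau] = 1.0 - depth
        u = (t[ramp_out] - (end - taper)) / taper
        gate[ramp_out] = 1.0 - depth * (1.0 + np.cos(np.pi * u)) / 2.0
    return gate


def _dip_grid(
    cfg: SimulationConfig, events, rng: np.random.Generator
) -> Tuple[np.ndarray, List[float], List[float]]:
    """Tachogram dip field (ms, positive = RR shortening) on a 2-Hz grid."""
    grid_hz = 2.0
    n = int(cfg.duration_s * grid_hz) + 1
    grid = np.zeros(n)
    tg = np.arange(n) / grid_hz

    def add_dip(center: float, width: float, depth: float) -> None:
        sel = np.abs(tg - center) <= width / 2.0
        grid[sel] += depth * 0.5 * (1.0 + np.cos(2.0 * np.pi * (tg[sel] - center) / width))

    cvhr_dips: List[float] = []
    for start, end in events:
        width = float(np.clip(0.8 * (end - start), 15.0, 60.0))
        add_dip(end, width, cfg.bcg.cvhr_dip_ms)
        cvhr_dips.append(end)

    plm_dips: List[float] = []
    if cfg.plm.enabled:
        offset = rng.uniform(0.0, cfg.plm.episode_every_s / 2.0)
        ep_start = offset
        while ep_start < cfg.duration_s - cfg.plm.spacing_s:
            dip_t = ep_start
            while dip_t < min(ep_start + cfg.plm.episode_len_s, cfg.duration_s):
                add_dip(dip_t, cfg.plm.dip_width_s, cfg.plm.dip_ms)
                plm_dips.append(dip_t)
                dip_t += cfg.plm.spacing_s
            ep_start += cfg.plm.episode_every_s
    return grid, cvhr_dips, plm_dips


def _beat_times(
    cfg: SimulationConfig, dip_grid: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    beats: List[float] = []
    t = rng.uniform(0.0, cfg.bcg.mean_rr_ms / 1000.0)
    grid_hz = 2.0
    nmax = len(dip_grid) - 1
    while t < cfg.duration_s:
        beats.append(t)
        dip = dip_grid[min(nmax, int(t * grid_hz))]
        rr_ms = cfg.bcg.mean_rr_ms + rng.normal(0.0, cfg.bcg.rr_sd_ms) - dip
        rr_ms = float(np.clip(rr_ms, 350.0, 2000.0))
        t += rr_ms / 1000.0
    return np.asarray(beats)


def _bcg_signal(
    cfg: SimulationConfig, beats: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    fs = cfg.sampling_rate
    sigma = cfg.bcg.pulse_sigma_s
    tau = np.arange(-3 * sigma, 3 * sigma + 1.0 / fs, 1.0 / fs)
    template = np.exp(-0.5 * (tau / sigma) ** 2) * np.sin(
        2.0 * np.pi * cfg.bcg.pulse_freq_hz * tau
    )
    out = np.zeros(n)
    half = len(template) // 2
    amps = cfg.bcg.pulse_amp * rng.uniform(0.8, 1.2, size=len(beats))
    for beat, amp in zip(beats, amps):
        c = int(round(beat * fs))
        i0, i1 = c - half, c - half + len(template)
        j0, j1 = max(0, i0), min(n, i1)
        if j0 < j1:
            out[j0:j1] += amp * template[j0 - i0 : j1 - i0]
    return out


def _movement_signal(
    cfg: SimulationConfig, plm_dips: Sequence[float], n: int, rng: np.random.Generator
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    fs = cfg.sampling_rate
    out = np.zeros(n)
    bursts: List[Tuple[float, float]] = []

    def add_burst(start: float, dur: float, amp: float) -> None:
        length = int(round(dur * fs))
        if length < 8:
            return
        i0 = int(round(start * fs))
        if i0 < 0 or i0 + length > n:
            return
        noise = rng.standard_normal(length)
        shaped = bandpass_filter(noise, (2.0, 3.0), fs)
        rms = float(np.sqrt(np.mean(np.square(shaped))))
        if rms > 0:
            shaped *= amp / rms
        shaped *= sps.windows.tukey(length, alpha=0.4)
        out[i0 : i0 + length] += shaped

    n_bursts = rng.poisson(cfg.movement_burst_rate_per_h * cfg.duration_s / 3600.0)
    starts = np.sort(rng.uniform(0.0, cfg.duration_s - 10.0, size=n_bursts))
    for start in starts:
        dur = float(rng.uniform(*cfg.burst_duration_s))
        amp = cfg.burst_amp * float(rng.uniform(0.5, 1.0))
        add_burst(float(start), dur, amp)
        bursts.append((float(start), dur))

    if cfg.plm.enabled:
        for dip_t in plm_dips:
            add_burst(dip_t - cfg.plm.movement_burst_s / 2.0,
                      cfg.plm.movement_burst_s, cfg.plm.movement_amp)
    return out, bursts


def simulate_subject(config: SimulationConfig) -> Tuple[MicromotionRecord, GroundTruth]:
    """Generate one subject's recording and its ground truth.

    Deterministic for a fixed configuration (including the seed).

    Raises :class:`SaturationError` if the combined amplitudes exceed the
    24-bit ADC range.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    events = _place_events(cfg, rng)
    spells = _place_shallow_spells(cfg, events, rng)
    posture, shifts = _posture_factor(cfg, rng, t)
    depth = cfg.event_depth_percent / 100.0
    gate = _dip_gate(t, [(s, e, depth) for s, e in events], cfg.event_taper_s)
    gate *= _dip_gate(t, [(s, e, d / 100.0) for s, e, d in spells], cfg.event_taper_s)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    respiration = (
        cfg.respiration_amp * posture * gate * np.sin(2.0 * np.pi * cfg.respiration_hz * t + phase)
    )

    dip_grid, cvhr_dips, plm_dips = _dip_grid(cfg, events, rng)
    beats = _beat_times(cfg, dip_grid, rng)
    bcg = _bcg_signal(cfg, beats, n, rng)
    movement, bursts = _movement_signal(cfg, plm_dips, n, rng)
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0

    total = respiration + bcg + movement + noise
    peak = float(np.max(np.abs(total))) if n else 0.0
    if peak > ADC_MAX:
        raise SaturationError(
            f"combined signal peak {peak:.0f} exceeds the 24-bit range ({ADC_MAX})"
        )
    samples = np.rint(total).astype(np.int32)

    duration_h = cfg.duration_s / 3600.0
    truth = GroundTruth(
        events=events,
        true_ahi=len(events) / duration_h,
        shallow_spells=spells,
        beat_times_s=beats,
        posture_shifts=shifts,
        movement_bursts=bursts,
        plm_dips=plm_dips,
        cvhr_dips=cvhr_dips,
        duration_h=duration_h,
    )
    record = MicromotionRecord(samples=samples, sampling_rate=fs)
    return record, truth


# --- cohorts -----------------------------------------------------------------

#: Default cohort AHI distribution: lognormal matching the study population's
#: spread (median ~13 events/h, IQR roughly 4-24).
DEFAULT_AHI_DISTRIBUTION = {"kind": "lognormal", "median": 13.0, "sigma": 1.4, "max": 60.0}


def _draw_rates(n: int, spec: dict, rng: np.random.Generator) -> np.ndarray:
    kind = spec.get("kind")
    if kind == "lognormal":
        rates = rng.lognormal(mean=np.log(spec["median"]), sigma=spec["sigma"], size=n)
        return np.clip(rates, 0.0, spec.get("max", np.inf))
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=n)
    if kind == "linspace":
        return np.linspace(spec["low"], spec["high"], n)
    if kind == "values":
        values = np.asarray(spec["values"], dtype=np.float64)
        if values.size != n:
            raise ConfigurationError(f"need {n} values, got {values.size}")
        return values
    raise ConfigurationError(f"unknown AHI distribution kind {kind!r}")


def simulate_cohort(
    n: int,
    ahi_distribution: Optional[dict] = None,
    base_config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> List[Tuple[MicromotionRecord, GroundTruth, SubjectMeta]]:
    """Generate a cohort with per-subject event rates from a distribution.

    Per-subject seeds derive deterministically from the master seed
    (``seed + 1 + index``); the master seed itself drives the rate draws.
    The first half of the cohort is labelled ``training``, the second half
    ``test``.  In simulation the subject is treated as asleep for the whole
    recording, so ``ahi_tst == ahi_trt == true_ahi``.
    """
    if n < 2:
        raise ConfigurationError(f"cohort size must be >= 2, got {n}")
    spec = ahi_distribution or DEFAULT_AHI_DISTRIBUTION
    base = base_config or SimulationConfig()
    master = np.random.default_rng(seed)
    rates = _draw_rates(n, spec, master)

    cohort = []
    for i, rate in enumerate(rates):
        cfg = replace(base, event_rate_per_h=float(rate), seed=seed + 1 + i)
        record, truth = simulate_subject(cfg)
        meta = SubjectMeta(
            subject_id=f"S{i:03d}",
            ahi_trt=truth.true_ahi,
            ahi_tst=truth.true_ahi,
            plm_index=len(truth.plm_dips) / truth.duration_h,
            group="training" if i < n / 2 else "test",
        )
        cohort.append((record, truth, meta))
    return cohort


# --- ground-truth comparison -------------------------------------------------


@dataclass
class MatchResult:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")


def match_events(
    true_events: Sequence[Tuple[float, float]],
    detected_events: Sequence,
    min_overlap_fraction: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of detected to planted events.

    A pair matches when their overlap covers at least
    ``min_overlap_fraction`` of the shorter interval.
    """
    det = [
        (e.start_s, e.end_s) if hasattr(e, "start_s") else (float(e[0]), float(e[1]))
        for e in detected_events
    ]
    pairs = []
    for i, (ts, te) in enumerate(true_events):
        for j, (ds, de) in enumerate(det):
            overlap = min(te, de) - max(ts, ds)
            shorter = min(te - ts, de - ds)
            if shorter > 0 and overlap >= min_overlap_fraction * shorter:
                pairs.append((overlap, i, j))
    pairs.sort(reverse=True)
    used_true: set = set()
    used_det: set = set()
    matched = 0
    for _, i, j in pairs:
        if i not in used_true and j not in used_det:
            used_true.add(i)
            used_det.add(j)
            matched += 1
    return MatchResult(n_true=len(true_events), n_detected=len(det), n_matched=matched)
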