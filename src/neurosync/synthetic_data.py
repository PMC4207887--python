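"""Synthetic EAdi/Paw/flow recordings with exhaustive ground truth.

The generator emulates a COPD-like non-invasive ventilation recording:
quasi-periodic diaphragm activation bursts riding on a tonic baseline,
ventilator pressurization with mode-dependent trigger delay and cycling-off
error relative to the neural 70%-of-peak cycle-off, PEEP baseline, additive
noise, and injected asynchronies (wasted efforts, auto-triggering, double
triggering, multiple EAdi bursts per assist) — all with ground-truth event
times and per-breath true timing errors.

EAdi burst morphology
---------------------
Each burst rises linearly from the tonic level to its peak over 75% of the
neural inspiratory time ``ti_n_s``, then decays along a baseline-anchored
exponential that returns exactly to the tonic level 75% of the way through
neural expiration. The decay time constant is solved per breath so that the
descending 70%-of-prominence crossing falls exactly at ``onset + ti_n_s``:
this is the analytic neural cycle-off the detector must recover. When
expiration is too short for the anchored form, a plain truncated exponential
with the same 70% crossing is used instead.

Closed-loop mode
----------------
With ``closed_loop=True`` wasted efforts are not drawn from ``p_wasted``;
instead an effort is wasted whenever its trigger attempt falls while the
machine is still insufflating for the previous effort or within a short
expiratory refractory period. Sweeping the injected cycling-off degradation
upward then makes wasted efforts emerge mechanistically from dyssynchrony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .errors import ConfigError
from .waveform_io import AnnotationSet, Recording, SampledSignal

RISE_FRACTION = 0.75          # fraction of ti_n spent rising to peak
CYCLEOFF_FRACTION = 0.70      # neural cycle-off at 70% of peak prominence
DECAY_SPAN_FRACTION = 0.75    # decay reaches tonic this far through expiration
REFRACTORY_S = 0.25           # machine expiratory refractory (closed loop)

KLASS_MATCHED = "matched"
KLASS_WASTED = "wasted_effort"
KLASS_AUTO = "auto_trigger"
KLASS_DOUBLE = "double_trigger"
KLASS_MULTI = "multi_eadi"


@dataclass
class SimulationConfig:
    """Controls for one simulated recording. Units in field names."""

    fs: float = 62.5
    duration_s: float = 300.0
    rr_bpm: float = 22.0
    rr_cv: float = 0.08
    eadi_peak_uV: float = 25.0
    eadi_peak_cv: float = 0.15
    eadi_tonic_uV: float = 1.5
    ti_n_s: float = 0.9
    trigger_delay_ms: float = 50.0
    trigger_delay_sd_ms: float = 0.0
    cycleoff_error_ms: float = 0.0
    cycleoff_error_sd_ms: float = 0.0
    ps_cmH2O: float = 10.0
    peep_cmH2O: float = 5.0
    rise_time_s: float = 0.15
    p_wasted: float = 0.0
    p_autotrigger: float = 0.0   # events per minute
    p_double: float = 0.0
    p_multi_eadi: float = 0.0
    noise_uV: float = 0.0
    noise_cmH2O: float = 0.0
    closed_loop: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_wasted", "p_double", "p_multi_eadi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.p_wasted + self.p_double + self.p_multi_eadi > 1.0:
            raise ConfigError("per-breath asynchrony probabilities sum to more than 1")
        if self.p_autotrigger < 0:
            raise ConfigError("p_autotrigger (events/min) must be >= 0")
        for name in ("fs", "duration_s", "rr_bpm", "eadi_peak_uV", "ti_n_s"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if not self.eadi_tonic_uV < self.eadi_peak_uV:
            raise ConfigError("eadi_tonic_uV must be below eadi_peak_uV")
        if self.eadi_tonic_uV < 0 or self.rise_time_s < 0:
            raise ConfigError("eadi_tonic_uV and rise_time_s must be non-negative")
        if self.noise_uV < 0 or self.noise_cmH2O < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.ti_n_s >= 60.0 / self.rr_bpm:
            raise ConfigError(
                f"breaths overlap: ti_n_s={self.ti_n_s} s >= mean breath period "
                f"{60.0 / self.rr_bpm:.3g} s"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """AnnotationSet plus true per-breath timing errors for matched breaths."""

    annotations: AnnotationSet = field(default_factory=AnnotationSet)
    true_trigger_delay_ms: list = field(default_factory=list)
    true_cycleoff_error_ms: list = field(default_factory=list)

    @property
    def neural_events(self):
        return self.annotations.neural_events

    @property
    def vent_events(self):
        return self.annotations.vent_events

    @property
    def labels(self):
        return self.annotations.labels

    def count(self, klass: str) -> int:
        return sum(1 for _, k in self.labels if k == klass)

    def to_dict(self) -> dict:
        d = self.annotations.to_dict()
        d["true_trigger_delay_ms"] = list(map(float, self.true_trigger_delay_ms))
        d["true_cycleoff_error_ms"] = list(map(float, self.true_cycleoff_error_ms))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            annotations=AnnotationSet.from_dict(d),
            true_trigger_delay_ms=list(d.get("true_trigger_delay_ms", [])),
            true_cycleoff_error_ms=list(d.get("true_cycleoff_error_ms", [])),
        )


def preset_mode_config(mode: str, **overrides) -> SimulationConfig:
    """Preset configs echoing the study's qualitative mode contrast.

    ``"NAVA-like"``: neurally triggered/cycled assist — trigger delay
    ~50 ms, cycling-off error 12 ± 6 ms, essentially no asynchronies.
    ``"PSV-like"``: pneumatically triggered/cycled assist — larger and more
    variable trigger delay, early cycling off (−95 ± 22 ms), and a nonzero
    wasted-effort probability (4.3% of efforts).
    """
    presets = {
        "NAVA-like": dict(
            rr_bpm=24.0,
            trigger_delay_ms=50.0,
            trigger_delay_sd_ms=15.0,
            cycleoff_error_ms=12.0,
            cycleoff_error_sd_ms=6.0,
            p_wasted=0.0,
            p_autotrigger=0.3,
            noise_uV=0.5,
            noise_cmH2O=0.2,
        ),
        "PSV-like": dict(
            rr_bpm=22.0,
            trigger_delay_ms=150.0,
            trigger_delay_sd_ms=40.0,
            cycleoff_error_ms=-95.0,
            cycleoff_error_sd_ms=22.0,
            p_wasted=0.043,
            p_autotrigger=0.2,
            p_double=0.01,
            p_multi_eadi=0.01,
            noise_uV=0.5,
            noise_cmH2O=0.2,
        ),
    }
    if mode not in presets:
        raise ConfigError(f"unknown preset '{mode}'; choose one of {sorted(presets)}")
    cfg = SimulationConfig(**presets[mode])
    if overrides:
        bad = set(overrides) - set(cfg.to_dict())
        if bad:
            raise ConfigError(f"unknown SimulationConfig fields: {sorted(bad)}")
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def _anchored_decay_tau(a: float, b: float, frac: float = CYCLEOFF_FRACTION):
    """Time constant of (exp(-u/tau)-E)/(1-E), E=exp(-b/tau), hitting ``frac`` at u=a.

    The anchored shape decays from 1 at u=0 to exactly 0 at u=b. Returns None
    when no tau achieves the crossing (expiration too short), in which case
    the caller falls back to a plain exponential.
    """
    if b <= a or (b - a) / b <= frac + 1e-9:
        return None

    def g(tau):
        ea, eb = math.exp(-a / tau), math.exp(-b / tau)
        return (ea - eb) / (1.0 - eb) - frac

    return brentq(g, 1e-4, 1e4, xtol=1e-12, rtol=1e-14)


class _Burst:
    """One EAdi burst: linear rise then anchored-exponential decay."""

    def __init__(self, onset: float, ti: float, prominence: float, decay_until: float):
        self.onset = onset
        self.ti = ti
        self.prominence = prominence
        self.t_peak = onset + RISE_FRACTION * ti
        a = ti - RISE_FRACTION * ti                     # peak -> 70% crossing
        b = max(decay_until - self.t_peak, a + 1e-6)    # peak -> baseline return
        tau = _anchored_decay_tau(a, b)
        if tau is None:
            self.tau = a / math.log(1.0 / CYCLEOFF_FRACTION)
            self.E = 0.0
        else:
            self.tau = tau
            self.E = math.exp(-b / tau)
        self.t_end = self.t_peak + b
        self.cycleoff = onset + ti

    def render(self, t: np.ndarray) -> np.ndarray:
        """Burst shape (0..prominence) at times ``t``; zero outside support."""
        y = np.zeros_like(t)
        rise = (t >= self.onset) & (t <= self.t_peak)
        dur = self.t_peak - self.onset
        if dur > 0:
            y[rise] = self.prominence * (t[rise] - self.onset) / dur
        dec = (t > self.t_peak) & (t < self.t_end)
        u = t[dec] - self.t_peak
        shape = (np.exp(-u / self.tau) - self.E) / (1.0 - self.E)
        y[dec] = self.prominence * np.clip(shape, 0.0, 1.0)
        return y


def _plan_breaths(cfg: SimulationConfig, rng: np.random.Generator):
    """Neural onset times: first effort after a 1 s lead-in, last fully inside."""
    period_mean = 60.0 / cfg.rr_bpm
    onsets = []
    t = 1.0
    while t + cfg.ti_n_s + 0.5 <= cfg.duration_s:
        onsets.append(t)
        period = rng.normal(period_mean, cfg.rr_cv * period_mean)
        t += max(period, cfg.ti_n_s + 0.3)
    return onsets


def simulate_recording(cfg: SimulationConfig):
    """Generate one recording and its ground truth. Same config ⇒ identical output.

    Returns ``(Recording, GroundTruth)``.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    r_pattern, r_class, r_timing, r_auto, r_noise = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    onsets = _plan_breaths(cfg, r_pattern)
    n = len(onsets)
    if n == 0:
        raise ConfigError("duration too short for a single breath")
    bounds = onsets[1:] + [min(cfg.duration_s, onsets[-1] + 60.0 / cfg.rr_bpm)]

    proms = r_pattern.normal(cfg.eadi_peak_uV - cfg.eadi_tonic_uV,
                             cfg.eadi_peak_cv * cfg.eadi_peak_uV, size=n)
    proms = np.clip(proms, 1.0, None)
    # class draws and timing draws are consumed for every breath regardless of
    # probabilities so that recordings with the same seed share breath timing
    # across parameter settings
    u_class = r_class.random(n)
    delays = r_timing.normal(cfg.trigger_delay_ms, cfg.trigger_delay_sd_ms, size=n) / 1000.0
    cyc_errs = r_timing.normal(cfg.cycleoff_error_ms, cfg.cycleoff_error_sd_ms, size=n) / 1000.0

    classes = []
    for u in u_class:
        if not cfg.closed_loop and u < cfg.p_wasted:
            classes.append(KLASS_WASTED)
        elif u < cfg.p_wasted + cfg.p_double:
            classes.append(KLASS_DOUBLE)
        elif u < cfg.p_wasted + cfg.p_double + cfg.p_multi_eadi:
            classes.append(KLASS_MULTI)
        else:
            classes.append(KLASS_MATCHED)

    bursts: list[_Burst] = []
    neural_events = []
    vent_events = []          # (trigger_s, cycleoff_s)
    labels = []
    true_delay_ms = []
    true_cyc_ms = []
    machine_busy_until = -np.inf

    for i, onset in enumerate(onsets):
        nxt = bounds[i]
        te = nxt - (onset + cfg.ti_n_s)
        klass = classes[i]

        if klass == KLASS_MULTI:
            # two shorter bursts under one long assist
            ti_sub = 0.55 * cfg.ti_n_s
            onset2 = onset + ti_sub + 0.35 * cfg.ti_n_s
            b1 = _Burst(onset, ti_sub, proms[i], onset2)
            b2 = _Burst(onset2, ti_sub, proms[i],
                        onset2 + ti_sub + DECAY_SPAN_FRACTION * max(nxt - onset2 - ti_sub, 0.1))
            bursts += [b1, b2]
            neural_events += [(b1.onset, b1.t_peak, b1.cycleoff),
                              (b2.onset, b2.t_peak, b2.cycleoff)]
            trig = onset + max(delays[i], 0.0)
            cyc = max(b2.cycleoff + cyc_errs[i], trig + cfg.rise_time_s + 0.05)
            vent_events.append((trig, min(cyc, cfg.duration_s - 2.0 / cfg.fs)))
            labels.append((onset, KLASS_MULTI))
            continue

        burst = _Burst(onset, cfg.ti_n_s, proms[i],
                       onset + cfg.ti_n_s + DECAY_SPAN_FRACTION * max(te, 0.1))
        bursts.append(burst)
        neural_events.append((burst.onset, burst.t_peak, burst.cycleoff))

        if klass == KLASS_WASTED:
            labels.append((onset, KLASS_WASTED))
            continue

        trig = onset + delays[i]
        if cfg.closed_loop and trig < machine_busy_until:
            labels.append((onset, KLASS_WASTED))
            continue

        if klass == KLASS_DOUBLE:
            cyc1 = onset + 0.45 * cfg.ti_n_s
            trig2 = cyc1 + 0.12
            cyc2 = min(burst.cycleoff + cyc_errs[i], cfg.duration_s - 2.0 / cfg.fs)
            vent_events.append((trig, max(cyc1, trig + 0.1)))
            vent_events.append((trig2, max(cyc2, trig2 + 0.1)))
            labels.append((onset, KLASS_DOUBLE))
            continue

        cyc = burst.cycleoff + cyc_errs[i]
        cyc = max(cyc, trig + cfg.rise_time_s + 0.05)
        if cfg.closed_loop and i + 1 < n:
            # keep a runaway assist from swallowing the next burst's peak so
            # the unassisted effort reads as wasted, not multiple-EAdi
            cyc = min(cyc, onsets[i + 1] + 0.4 * cfg.ti_n_s)
        cyc = min(cyc, cfg.duration_s - 2.0 / cfg.fs)
        vent_events.append((trig, cyc))
        machine_busy_until = cyc + REFRACTORY_S
        labels.append((onset, KLASS_MATCHED))
        true_delay_ms.append(1000.0 * (trig - onset))
        true_cyc_ms.append(1000.0 * (cyc - burst.cycleoff))

    # auto-triggers: assists in quiet expiration with no EAdi burst
    n_auto = r_auto.poisson(cfg.p_autotrigger * cfg.duration_s / 60.0)
    hosts = [i for i in range(n - 1) if classes[i] == KLASS_MATCHED]
    for _ in range(int(n_auto)):
        if not hosts:
            break
        i = int(r_auto.choice(hosts))
        hosts.remove(i)
        cyc_n = onsets[i] + cfg.ti_n_s
        te = bounds[i] - cyc_n
        start = cyc_n + r_auto.uniform(0.55, 0.65) * te
        dur = 0.25 * te
        if dur < cfg.rise_time_s + 0.05:
            continue
        vent_events.append((start, start + dur))
        labels.append((start, KLASS_AUTO))

    vent_events.sort()
    labels.sort()

    # ---- render waveforms -------------------------------------------------
    n_samples = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n_samples) / cfg.fs
    eadi = np.full(n_samples, cfg.eadi_tonic_uV)
    for burst in bursts:
        lo = max(0, int(math.floor(burst.onset * cfg.fs)))
        hi = min(n_samples, int(math.ceil(burst.t_end * cfg.fs)) + 2)
        eadi[lo:hi] += burst.render(t[lo:hi])

    paw = np.full(n_samples, cfg.peep_cmH2O)
    for trig, cyc in vent_events:
        lo = int(math.ceil(trig * cfg.fs))
        hi = min(n_samples, int(math.floor(cyc * cfg.fs)) + 1)
        if hi <= lo:
            continue
        seg = t[lo:hi] - trig
        ramp = np.minimum(seg / cfg.rise_time_s, 1.0) if cfg.rise_time_s > 0 else 1.0
        paw[lo:hi] = cfg.peep_cmH2O + cfg.ps_cmH2O * ramp

    # flow: cosmetic first-order response to driving pressure (not analyzed)
    k_flow, tau_flow = 5.0, 0.15
    a = (1.0 / cfg.fs) / tau_flow
    flow = lfilter([a], [1.0, -(1.0 - a)], k_flow * (paw - cfg.peep_cmH2O))

    if cfg.noise_uV > 0:
        eadi = eadi + r_noise.normal(0.0, cfg.noise_uV, n_samples)
    if cfg.noise_cmH2O > 0:
        paw = paw + r_noise.normal(0.0, cfg.noise_cmH2O, n_samples)
    eadi = np.clip(eadi, 0.0, None)

    meta = {
        "fs_hz": cfg.fs,
        "peep_cmh2o": cfg.peep_cmH2O,
        "mode": "simulated",
        "subject": f"sim-{cfg.seed}",
        "simulation": cfg.to_dict(),
    }
    rec = Recording(
        eadi=SampledSignal("eadi", "uV", cfg.fs, eadi),
        paw=SampledSignal("paw", "cmH2O", cfg.fs, paw),
        flow=SampledSignal("flow", "L/min", cfg.fs, flow),
        meta=meta,
    )
    gt = GroundTruth(
        annotations=AnnotationSet(neural_events, vent_events, labels),
        true_trigger_delay_ms=true_delay_ms,
        true_cycleoff_error_ms=true_cyc_ms,
    )
    gt.annotations.validate(cfg.duration_s)
    return rec, gt
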