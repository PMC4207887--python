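"""Breath segmentation from EAdi and Paw waveforms.

Neural breaths are found on the (lightly smoothed) EAdi signal: peaks with
sufficient prominence above a sliding tonic baseline, onset by backtracking
from each peak, neural cycle-off at the first post-peak descent to 70% of
peak prominence (the cycle-off rule used clinically by neurally adjusted
assist). Ventilator assists are found on Paw: a sustained rise above
PEEP + threshold marks pressurization, the descent below 25% of the driving
pressure marks pneumatic cycle-off.

Threshold crossings are refined below sample resolution by linear
interpolation; reported onset and trigger times are additionally
extrapolated along the locally fitted rising slope back to the baseline, so
that the reported time is the start of the rise rather than the (biased)
threshold crossing. At 62.5 Hz one sample spans 16 ms, the same scale as
the timing errors of interest, so sub-sample refinement matters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks

from .errors import ConfigError, DetectionError
from .waveform_io import SampledSignal


@dataclass
class DetectorParams:
    """Tunable detection thresholds (all configurable; defaults logged)."""

    onset_fraction: float = 0.10        # of (peak - tonic), backtracking target
    cycleoff_fraction: float = 0.70     # of (peak - tonic), neural cycle-off
    min_peak_uV: float = 1.0            # minimum EAdi peak prominence
    min_breath_interval_s: float = 0.5
    paw_trigger_cmH2O: float = 1.0      # rise above PEEP marking the trigger
    paw_cycleoff_fraction: float = 0.25  # of (peak - PEEP), pneumatic cycle-off
    smoothing_ms: float = 48.0          # EAdi moving-average width (~3 samples)
    tonic_window_s: float = 10.0        # sliding window for tonic percentile
    tonic_percentile: float = 10.0

    def validate(self) -> None:
        for name in ("onset_fraction", "cycleoff_fraction", "paw_cycleoff_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.min_peak_uV <= 0 or self.min_breath_interval_s <= 0:
            raise ConfigError("min_peak_uV and min_breath_interval_s must be positive")
        if self.paw_trigger_cmH2O <= 0:
            raise ConfigError("paw_trigger_cmH2O must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NeuralBreath:
    """One neural inspiratory effort segmented from EAdi."""

    onset_s: float
    peak_s: float
    peak_uV: float              # prominence above the tonic baseline
    cycleoff_s: float           # descending 70%-of-prominence crossing
    ti_n_s: float               # onset -> cycle-off
    te_n_s: Optional[float] = None  # cycle-off -> next onset; None for last breath


@dataclass
class VentBreath:
    """One ventilator assist segmented from Paw."""

    trigger_s: float
    cycleoff_s: float
    peak_paw_cmH2O: float
    peak_flow_lmin: Optional[float] = None


@dataclass
class QualityVerdict:
    ok: bool
    median_peak_uV: float
    n_breaths: int
    reason: str


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    """Time where the segment (t0,v0)-(t1,v1) crosses ``level``."""
    if v1 == v0:
        return t0
    frac = (level - v0) / (v1 - v0)
    return t0 + np.clip(frac, 0.0, 1.0) * (t1 - t0)


def _rise_start(x: np.ndarray, fs: float, idx: int, level: float, baseline: float,
                ceiling: float) -> float:
    """Extrapolate the rise through ``level`` at sample ``idx`` back to ``baseline``.

    Fits a line to the rising samples between ``level`` and ``ceiling`` around
    the crossing and returns its baseline intercept (in sample-index time
    units, i.e. seconds with t0=0). Falls back to the interpolated level
    crossing when the slope is unusable.
    """
    t_c = _interp_crossing((idx - 1) / fs, idx / fs, x[idx - 1], x[idx], level)
    hi = idx
    while hi + 1 < x.size and x[hi + 1] > x[hi] and x[hi + 1] < ceiling and hi - idx < 12:
        hi += 1
    lo = max(idx - 1, 0)
    seg = np.arange(lo, hi + 1)
    # keep only samples clearly on the rise: a pre-onset baseline sample in
    # the fit would drag the slope and shift the extrapolated start
    seg = seg[x[seg] > baseline + 0.25 * (level - baseline)]
    if seg.size >= 2:
        slope, intercept = np.polyfit(seg / fs, x[seg], 1)
        if slope > 0:
            t_base = (baseline - intercept) / slope
            if t_c - 0.5 <= t_base <= t_c:
                return float(t_base)
    return float(t_c)


def _corner_peak(vals: np.ndarray, m: int) -> Optional[float]:
    """Refine a peak's amplitude by intersecting local rise/decay secants.

    A burst peak generally falls between samples, so the maximum sample
    underestimates the true amplitude by up to slope·dt/2 — enough to bias
    the 70%-of-peak cycle-off level. Returns None when the neighborhood does
    not look like a clean corner (then the raw maximum is used instead).
    """
    if m < 3 or m + 3 >= vals.size:
        return None
    li = np.arange(m - 3, m)
    ri = np.arange(m + 1, m + 4)
    s1, c1 = np.polyfit(li, vals[li], 1)
    s2, c2 = np.polyfit(ri, vals[ri], 1)
    if not (s1 > 0 > s2):
        return None
    t = (c2 - c1) / (s1 - s2)
    if not (m - 1.0 <= t <= m + 1.0):
        return None
    v = s1 * t + c1
    if v < vals[m] or v > vals[m] + 0.75 * (s1 - s2):
        return None
    return float(v)


def estimate_tonic(eadi: SampledSignal, params: DetectorParams | None = None) -> np.ndarray:
    """Sliding low-percentile estimate of the tonic (baseline) EAdi level."""
    params = params or DetectorParams()
    width = max(1, int(round(params.smoothing_ms / 1000.0 * eadi.fs)))
    x = _smooth(eadi.values, width)
    size = max(3, int(round(params.tonic_window_s * eadi.fs)))
    return percentile_filter(x, params.tonic_percentile, size=size, mode="nearest")


def detect_neural_breaths(
    eadi: SampledSignal, params: DetectorParams | None = None
) -> List[NeuralBreath]:
    """Segment EAdi into neural breaths.

    Detection is amplitude-invariant (thresholds are fractions of each
    peak's prominence above the tonic baseline) and robust to additive
    noise via smoothing and a noise-adaptive prominence floor.
    """
    params = params or DetectorParams()
    params.validate()
    if not np.all(np.isfinite(eadi.values)):
        raise ConfigError("EAdi contains non-finite samples")

    fs = eadi.fs
    width = max(1, int(round(params.smoothing_ms / 1000.0 * fs)))
    x = _smooth(eadi.values, width)
    tonic = percentile_filter(
        x, params.tonic_percentile, size=max(3, int(round(params.tonic_window_s * fs))),
        mode="nearest",
    )

    # noise-adaptive prominence floor: MAD of the first difference estimates
    # the residual noise SD after smoothing
    diffs = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0)
    prominence = max(params.min_peak_uV, 8.0 * sigma)
    raw_diffs = np.diff(eadi.values)
    sigma_raw = 1.4826 * np.median(np.abs(raw_diffs - np.median(raw_diffs))) / np.sqrt(2.0)

    peaks, _ = find_peaks(
        x, prominence=prominence, distance=max(1, int(round(params.min_breath_interval_s * fs)))
    )
    breaths: List[NeuralBreath] = []
    prev_peak = 0
    half = width // 2 + 1
    for p in peaks:
        base = tonic[p]
        # amplitude from the raw signal near the peak: smoothing clips the
        # peak corner, which would bias the 70% cycle-off level (and hence
        # its crossing time)
        lo_w = max(0, p - half)
        win_vals = eadi.values[lo_w: p + half + 1]
        m = lo_w + int(np.argmax(win_vals))
        raw_peak = float(win_vals.max())
        if sigma_raw < 0.02 * max(raw_peak - base, 1e-9):
            refined = _corner_peak(eadi.values, m)
            prom = (refined if refined is not None else raw_peak) - base
        else:
            # the expected-maximum term undoes the upward noise bias of a local max
            prom = max(raw_peak - 1.16 * sigma_raw, x[p]) - base
        if prom < prominence:
            prev_peak = p
            continue

        # onset: backtrack to the last crossing of base + onset_fraction*prom,
        # then extrapolate the rise to the baseline
        level_on = base + params.onset_fraction * prom
        j = p
        while j > prev_peak and x[j - 1] > level_on:
            j -= 1
        if j == 0 or x[j - 1] > level_on:
            onset = j / fs
        else:
            onset = _rise_start(x, fs, j, level_on, base, base + 0.5 * prom)

        # cycle-off: first post-peak descent to base + cycleoff_fraction*prom
        level_off = base + params.cycleoff_fraction * prom
        k = p
        last = x.size - 1
        while k < last and x[k + 1] > level_off:
            k += 1
        if k == last:
            continue  # decay truncated by the recording end: drop the breath
        cycleoff = _interp_crossing(k / fs, (k + 1) / fs, x[k], x[k + 1], level_off)

        peak_t = p / fs
        if not onset < peak_t < cycleoff:
            prev_peak = p
            continue
        breaths.append(
            NeuralBreath(
                onset_s=eadi.t0 + onset,
                peak_s=eadi.t0 + peak_t,
                peak_uV=float(prom),
                cycleoff_s=eadi.t0 + cycleoff,
                ti_n_s=float(cycleoff - onset),
            )
        )
        prev_peak = p

    for a, b in zip(breaths, breaths[1:]):
        a.te_n_s = b.onset_s - a.cycleoff_s
    return breaths


def estimate_peep(paw: SampledSignal) -> float:
    """PEEP as the mode of Paw rounded to 0.5 cmH2O."""
    rounded = np.round(paw.values * 2.0) / 2.0
    vals, counts = np.unique(rounded, return_counts=True)
    return float(vals[np.argmax(counts)])


def detect_vent_breaths(
    paw: SampledSignal,
    peep: float | str = "auto",
    params: DetectorParams | None = None,
    flow: SampledSignal | None = None,
) -> List[VentBreath]:
    """Segment Paw into ventilator assists.

    A trigger is a sustained (≥3-sample) rise above PEEP + trigger
    threshold; the reported trigger time is the pressurization onset
    (baseline intercept of the rising slope). Pneumatic cycle-off is the
    interpolated descent below PEEP + 25% of the driving pressure.
    """
    params = params or DetectorParams()
    params.validate()
    if not np.all(np.isfinite(paw.values)):
        raise ConfigError("Paw contains non-finite samples")
    x = paw.values
    if peep == "auto":
        peep_val = estimate_peep(paw)
        if peep_val >= np.max(x):
            raise DetectionError(
                f"PEEP estimate {peep_val:.2f} cmH2O is not below peak Paw: "
                "no pressurization present"
            )
    else:
        peep_val = float(peep)
    fs = paw.fs
    level_trig = peep_val + params.paw_trigger_cmH2O
    above = x >= level_trig

    events: List[VentBreath] = []
    i = 1
    n = x.size
    while i < n:
        if above[i] and not above[i - 1]:
            run = i
            while run < n and above[run]:
                run += 1
            if run - i >= 3:
                seg_peak = int(i + np.argmax(x[i:run]))
                peak = x[seg_peak]
                level_off = peep_val + params.paw_cycleoff_fraction * (peak - peep_val)
                k = seg_peak
                while k + 1 < n and x[k + 1] > level_off:
                    k += 1
                if k + 1 < n:
                    cyc = _interp_crossing(k / fs, (k + 1) / fs, x[k], x[k + 1], level_off)
                    trig = _rise_start(x, fs, i, level_trig, peep_val,
                                       peep_val + 0.8 * (peak - peep_val))
                    pf = None
                    if flow is not None:
                        lo, hi = int(trig * fs), int(cyc * fs) + 1
                        pf = float(np.max(flow.values[max(lo, 0):hi]))
                    if trig < cyc:
                        events.append(
                            VentBreath(
                                trigger_s=paw.t0 + trig,
                                cycleoff_s=paw.t0 + cyc,
                                peak_paw_cmH2O=float(peak),
                                peak_flow_lmin=pf,
                            )
                        )
                    i = max(k, run)
            i = max(i, run)
        i += 1
    return events


def neural_respiratory_rate(breaths: List[NeuralBreath], duration_s: float) -> float:
    """Neural respiratory rate: EAdi peaks per minute."""
    if not duration_s > 0:
        raise ConfigError("duration_s must be positive")
    return len(breaths) * 60.0 / duration_s


def check_signal_quality(
    breaths: List[NeuralBreath],
    min_median_peak_uV: float = 1.0,
    min_breaths: int = 10,
) -> QualityVerdict:
    """Gate recordings whose EAdi is too weak or too sparse to analyze."""
    n = len(breaths)
    median_peak = float(np.median([b.peak_uV for b in breaths])) if n else 0.0
    if n < min_breaths:
        return QualityVerdict(False, median_peak, n,
                              f"only {n} breaths detected (need >= {min_breaths})")
    if median_peak < min_median_peak_uV:
        return QualityVerdict(
            False, median_peak, n,
            f"median peak EAdi {median_peak:.2f} uV below {min_median_peak_uV:.2f} uV",
        )
    return QualityVerdict(True, median_peak, n, "ok")
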