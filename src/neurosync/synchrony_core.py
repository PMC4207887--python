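"""Neural-ventilator event matching, timing errors and the NeuroSync index.

Each ventilator trigger is assigned to the neural breath whose onset
interval contains it; per-breath trigger and cycle-off errors are signed
percentages of neural inspiratory and expiratory time, and complete
EAdi/Paw dissociations (wasted efforts, auto-triggering, double
triggering, multiple EAdi bursts per assist) are assigned 100% error. The
NeuroSync index is the mean per-breath percentage error, so it grades a
recording from 0 (every assist perfectly timed) to 100 (every breath a
full asynchrony). Sign convention for cycling off: positive = late,
negative = early.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Union

import numpy as np

from .errors import ConfigError
from .event_detection import NeuralBreath, VentBreath

KLASS_MATCHED = "matched"
KLASS_WASTED = "wasted_effort"
KLASS_AUTO = "auto_trigger"
KLASS_DOUBLE = "double_trigger"
KLASS_MULTI = "multi_eadi"
ASYNC_KLASSES = (KLASS_WASTED, KLASS_AUTO, KLASS_DOUBLE, KLASS_MULTI)
ALL_KLASSES = (KLASS_MATCHED,) + ASYNC_KLASSES

BOX_SYNCHRONOUS = "synchronous"
BOX_DYSSYNCHRONOUS = "dyssynchronous"
BOX_ASYNCHRONOUS = "asynchronous"


@dataclass
class SynchronyParams:
    """Tunables of the matching/scoring layer (defaults logged in reports)."""

    box_threshold_pct: float = 20.0
    error_combination: str = "mean"      # "mean" or "max" of |trigger|,|cycle-off|
    cap_pct: float = 100.0               # per-component magnitude cap
    trigger_match_lead_s: float = 0.10   # slack before an onset still matching it
    auto_trigger_expiry_fraction: float = 0.5  # of te_n, late-trigger -> auto rule
    grid_bin_pct: float = 5.0

    def validate(self) -> None:
        if self.error_combination not in ("mean", "max"):
            raise ConfigError("error_combination must be 'mean' or 'max'")
        if self.box_threshold_pct <= 0 or self.grid_bin_pct <= 0:
            raise ConfigError("box_threshold_pct and grid_bin_pct must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BreathRecord:
    """One matched or unmatched neural-ventilator pairing."""

    klass: str
    neural: Optional[Union[NeuralBreath, List[NeuralBreath]]] = None
    vent: Optional[Union[VentBreath, List[VentBreath]]] = None
    trigger_error_pct: Optional[float] = None
    trigger_delay_ms: Optional[float] = None
    cycleoff_error_pct: Optional[float] = None
    cycleoff_error_ms: Optional[float] = None
    breath_error_pct: Optional[float] = None

    @property
    def time_s(self) -> float:
        """Representative time for ordering records."""
        n = self.neural[0] if isinstance(self.neural, list) else self.neural
        if n is not None:
            return n.onset_s
        v = self.vent[0] if isinstance(self.vent, list) else self.vent
        return v.trigger_s


def match_events(
    neural: List[NeuralBreath],
    vent: List[VentBreath],
    params: SynchronyParams | None = None,
) -> List[BreathRecord]:
    """Classify neural efforts and ventilator assists into breath records.

    Assignment rule: a trigger belongs to the neural breath whose interval
    [onset - lead, next onset - lead) contains it. A trigger landing in no
    interval, or far into expiration (beyond cycle-off + fraction*te) with no
    EAdi burst under the assist, is an auto-trigger. An assist spanning >= 2
    EAdi peaks is a multiple-EAdi-per-assist event; a neural breath with
    >= 2 assigned triggers is a double-trigger; one-to-one pairs are matched
    and unassisted efforts are wasted. Every neural breath and every
    ventilator assist appears in exactly one record. Timing-error fields are
    left unfilled (see :func:`score_records`).
    """
    params = params or SynchronyParams()
    params.validate()
    neural = sorted(neural, key=lambda b: b.onset_s)
    vent = sorted(vent, key=lambda v: v.trigger_s)
    n, m = len(neural), len(vent)
    records: List[BreathRecord] = []

    # interval assignment with lead slack
    shifted = [b.onset_s - params.trigger_match_lead_s for b in neural]
    assign: List[Optional[int]] = []
    for v in vent:
        i = bisect.bisect_right(shifted, v.trigger_s) - 1
        assign.append(i if i >= 0 else None)

    vent_used = [False] * m
    neural_used = [False] * n
    is_auto = [False] * m

    def peaks_under(v: VentBreath) -> List[int]:
        return [i for i, b in enumerate(neural)
                if v.trigger_s <= b.peak_s <= v.cycleoff_s and not neural_used[i]]

    for j, v in enumerate(vent):
        i = assign[j]
        if i is None:
            is_auto[j] = True
            continue
        b = neural[i]
        if b.te_n_s is not None:
            expiry = b.cycleoff_s + params.auto_trigger_expiry_fraction * b.te_n_s
            if v.trigger_s > expiry and not peaks_under(v):
                is_auto[j] = True

    # multiple EAdi peaks under one assist
    for j, v in enumerate(vent):
        if is_auto[j] or vent_used[j]:
            continue
        under = peaks_under(v)
        if len(under) >= 2:
            vent_used[j] = True
            for i in under:
                neural_used[i] = True
            records.append(BreathRecord(KLASS_MULTI,
                                        neural=[neural[i] for i in under], vent=v))

    # group remaining triggers by assigned neural breath
    by_neural: dict[int, List[int]] = {}
    for j in range(m):
        if is_auto[j] or vent_used[j] or assign[j] is None:
            continue
        by_neural.setdefault(assign[j], []).append(j)

    for i, b in enumerate(neural):
        if neural_used[i]:
            continue
        js = [j for j in by_neural.get(i, []) if not vent_used[j]]
        if not js:
            records.append(BreathRecord(KLASS_WASTED, neural=b))
        elif len(js) == 1:
            vent_used[js[0]] = True
            records.append(BreathRecord(KLASS_MATCHED, neural=b, vent=vent[js[0]]))
        else:
            for j in js:
                vent_used[j] = True
            records.append(BreathRecord(KLASS_DOUBLE, neural=b,
                                        vent=[vent[j] for j in js]))
        neural_used[i] = True

    for j, v in enumerate(vent):
        if is_auto[j] or not vent_used[j]:
            records.append(BreathRecord(KLASS_AUTO, vent=v))

    records.sort(key=lambda r: r.time_s)
    return records


def _cap(value: float, cap: float) -> float:
    return float(np.clip(value, -cap, cap))


def trigger_error(rec: BreathRecord, params: SynchronyParams | None = None) -> float:
    """Signed trigger error as % of neural inspiratory time (fills the record).

    Positive: the assist started after the neural onset (delayed trigger).
    """
    params = params or SynchronyParams()
    if rec.klass != KLASS_MATCHED:
        raise ConfigError("trigger_error is defined for matched records only")
    delta = rec.vent.trigger_s - rec.neural.onset_s
    rec.trigger_delay_ms = 1000.0 * delta
    rec.trigger_error_pct = _cap(100.0 * delta / rec.neural.ti_n_s, params.cap_pct)
    return rec.trigger_error_pct


def cycleoff_error(rec: BreathRecord, params: SynchronyParams | None = None) -> float:
    """Signed cycling-off error as % of neural expiratory time (fills the record).

    Positive = late cycling off, negative = early. Requires te_n, so the
    last breath of a recording is excluded from cycle-off statistics.
    """
    params = params or SynchronyParams()
    if rec.klass != KLASS_MATCHED:
        raise ConfigError("cycleoff_error is defined for matched records only")
    if rec.neural.te_n_s is None:
        raise ConfigError("cycleoff_error undefined: te_n unknown for the last breath")
    delta = rec.vent.cycleoff_s - rec.neural.cycleoff_s
    rec.cycleoff_error_ms = 1000.0 * delta
    rec.cycleoff_error_pct = _cap(100.0 * delta / rec.neural.te_n_s, params.cap_pct)
    return rec.cycleoff_error_pct


def breath_error(rec: BreathRecord, params: SynchronyParams | None = None) -> float:
    """Per-breath percentage error in [0, 100] entering the NeuroSync average.

    Asynchronies score 100 exactly; matched breaths combine the trigger and
    cycle-off error magnitudes (mean by default, max by configuration); a
    matched last breath contributes its trigger error only.
    """
    params = params or SynchronyParams()
    params.validate()
    if rec.klass != KLASS_MATCHED:
        rec.breath_error_pct = 100.0
        return 100.0
    if rec.trigger_error_pct is None:
        raise ConfigError("breath_error requires trigger_error to be filled")
    comps = [min(abs(rec.trigger_error_pct), params.cap_pct)]
    if rec.cycleoff_error_pct is not None:
        comps.append(min(abs(rec.cycleoff_error_pct), params.cap_pct))
    combined = max(comps) if params.error_combination == "max" else float(np.mean(comps))
    rec.breath_error_pct = min(combined, 100.0)
    return rec.breath_error_pct


def score_records(records: List[BreathRecord],
                  params: SynchronyParams | None = None) -> List[BreathRecord]:
    """Fill timing errors and per-breath errors for every record in place."""
    params = params or SynchronyParams()
    for rec in records:
        if rec.klass == KLASS_MATCHED:
            trigger_error(rec, params)
            if rec.neural.te_n_s is not None:
                cycleoff_error(rec, params)
        breath_error(rec, params)
    return records


def neurosync_index(records: List[BreathRecord], include_wasted: bool = True) -> float:
    """NeuroSync index: mean per-breath percentage error.

    With ``include_wasted=False`` wasted efforts are dropped before
    averaging (the decoupled index used when regressing wasted efforts on
    dyssynchrony, to avoid mathematically coupled variables).
    """
    retained = [r for r in records
                if include_wasted or r.klass != KLASS_WASTED]
    if not retained:
        raise ConfigError("NeuroSync index undefined: no breaths after exclusion")
    errs = [r.breath_error_pct for r in retained]
    if any(e is None for e in errs):
        raise ConfigError("records must be scored before computing the index")
    return float(np.mean(errs))


def classify_box(rec: BreathRecord, threshold_pct: float = 20.0) -> str:
    """Synchrony box: matched breaths with both |errors| <= threshold are
    synchronous, other matched breaths dyssynchronous, everything else
    asynchronous."""
    if rec.klass != KLASS_MATCHED:
        return BOX_ASYNCHRONOUS
    trig = abs(rec.trigger_error_pct) if rec.trigger_error_pct is not None else 0.0
    cyc = abs(rec.cycleoff_error_pct) if rec.cycleoff_error_pct is not None else 0.0
    if trig <= threshold_pct and cyc <= threshold_pct:
        return BOX_SYNCHRONOUS
    return BOX_DYSSYNCHRONOUS


@dataclass
class SynchronyReport:
    """Summary of one analyzed recording (see per-field docs in the module)."""

    n_breaths: int
    neurosync_pct: Optional[float]
    neurosync_no_wasted_pct: Optional[float]
    counts: dict
    wasted_per_min: float
    pct_synchronous: float
    pct_dyssynchronous: float
    pct_asynchronous: float
    density_grid: dict
    per_breath: List[BreathRecord]
    duration_s: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        rows = []
        for i, r in enumerate(self.per_breath):
            rows.append({
                "breath_id": i,
                "klass": r.klass,
                "trigger_error_pct": r.trigger_error_pct,
                "trigger_delay_ms": r.trigger_delay_ms,
                "cycleoff_error_pct": r.cycleoff_error_pct,
                "cycleoff_error_ms": r.cycleoff_error_ms,
                "breath_error_pct": r.breath_error_pct,
            })
        return {
            "n_breaths": self.n_breaths,
            "neurosync_pct": self.neurosync_pct,
            "neurosync_no_wasted_pct": self.neurosync_no_wasted_pct,
            "counts": self.counts,
            "wasted_per_min": self.wasted_per_min,
            "pct_synchronous": self.pct_synchronous,
            "pct_dyssynchronous": self.pct_dyssynchronous,
            "pct_asynchronous": self.pct_asynchronous,
            "density_grid": self.density_grid,
            "per_breath": rows,
            "duration_s": self.duration_s,
            "params": self.params,
        }


def build_report(
    records: List[BreathRecord],
    duration_s: float,
    params: SynchronyParams | None = None,
    extra_params: dict | None = None,
) -> SynchronyReport:
    """Aggregate scored breath records into a SynchronyReport.

    The density grid is a 2-D histogram of matched breaths over cycling-off
    error (x) versus trigger error (y) on a fixed [-100, 100]% grid.
    """
    params = params or SynchronyParams()
    params.validate()
    counts = {k: 0 for k in ALL_KLASSES}
    for r in records:
        counts[r.klass] += 1
    n = len(records)

    boxes = [classify_box(r, params.box_threshold_pct) for r in records]
    pct = lambda k: 100.0 * boxes.count(k) / n if n else 0.0

    edges = np.arange(-100.0, 100.0 + params.grid_bin_pct, params.grid_bin_pct)
    matched = [r for r in records if r.klass == KLASS_MATCHED
               and r.trigger_error_pct is not None and r.cycleoff_error_pct is not None]
    hist, _, _ = np.histogram2d(
        [r.cycleoff_error_pct for r in matched],
        [r.trigger_error_pct for r in matched],
        bins=[edges, edges],
    ) if matched else (np.zeros((edges.size - 1, edges.size - 1)), None, None)

    provenance = {"synchrony": params.to_dict()}
    if extra_params:
        provenance.update(extra_params)

    return SynchronyReport(
        n_breaths=n,
        neurosync_pct=neurosync_index(records, True) if n else None,
        neurosync_no_wasted_pct=(
            neurosync_index(records, False)
            if any(r.klass != KLASS_WASTED for r in records) else None
        ),
        counts=counts,
        wasted_per_min=counts[KLASS_WASTED] * 60.0 / duration_s if duration_s > 0 else 0.0,
        pct_synchronous=pct(BOX_SYNCHRONOUS),
        pct_dyssynchronous=pct(BOX_DYSSYNCHRONOUS),
        pct_asynchronous=pct(BOX_ASYNCHRONOUS),
        density_grid={
            "cycleoff_edges_pct": edges.tolist(),
            "trigger_edges_pct": edges.tolist(),
            "counts": hist.astype(int).tolist(),
        },
        per_breath=records,
        duration_s=duration_s,
        params=provenance,
    )
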