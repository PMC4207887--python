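"""End-to-end analysis of one recording: window, detect, match, score, report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .event_detection import (
    DetectorParams,
    NeuralBreath,
    QualityVerdict,
    VentBreath,
    check_signal_quality,
    detect_neural_breaths,
    detect_vent_breaths,
    neural_respiratory_rate,
)
from .synchrony_core import SynchronyParams, SynchronyReport, build_report, match_events, score_records
from .waveform_io import Recording, extract_analysis_window


@dataclass
class AnalysisResult:
    recording: Recording            # the analysis window actually analyzed
    neural_breaths: List[NeuralBreath]
    vent_breaths: List[VentBreath]
    report: SynchronyReport
    quality: QualityVerdict
    neural_rr_bpm: float


def analyze_recording(
    rec: Recording,
    window_s: Optional[float] = 300.0,
    det_params: DetectorParams | None = None,
    syn_params: SynchronyParams | None = None,
    peep: float | str | None = None,
    min_median_peak_uV: float = 1.0,
) -> AnalysisResult:
    """Run the full interaction analysis on the final ``window_s`` seconds.

    ``peep`` defaults to the recording's metadata value when present,
    otherwise it is estimated from the Paw histogram.
    """
    det_params = det_params or DetectorParams()
    syn_params = syn_params or SynchronyParams()
    win = extract_analysis_window(rec, window_s) if window_s else rec

    if peep is None:
        peep = rec.meta.get("peep_cmh2o")
        if peep is None:
            peep = "auto"

    neural = detect_neural_breaths(win.eadi, det_params)
    vents = detect_vent_breaths(win.paw, peep=peep, params=det_params, flow=win.flow)
    quality = check_signal_quality(neural, min_median_peak_uV=min_median_peak_uV)

    records = score_records(match_events(neural, vents, syn_params), syn_params)
    report = build_report(
        records,
        win.duration_s,
        syn_params,
        extra_params={"detection": det_params.to_dict(), "window_s": win.duration_s},
    )
    return AnalysisResult(
        recording=win,
        neural_breaths=neural,
        vent_breaths=vents,
        report=report,
        quality=quality,
        neural_rr_bpm=neural_respiratory_rate(neural, win.duration_s),
    )
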