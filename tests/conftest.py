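import numpy as np
import pytest

from neurosync.event_detection import NeuralBreath, VentBreath
from neurosync.synthetic_data import SimulationConfig, simulate_recording


def make_neural(onset, ti=1.0, te=2.0, peak_uV=20.0):
    """NeuralBreath with peak midway through inspiration."""
    return NeuralBreath(
        onset_s=onset,
        peak_s=onset + 0.75 * ti,
        peak_uV=peak_uV,
        cycleoff_s=onset + ti,
        ti_n_s=ti,
        te_n_s=te,
    )


def make_vent(trigger, cycleoff=None, peak_paw=15.0):
    if cycleoff is None:
        cycleoff = trigger + 0.8
    return VentBreath(trigger_s=trigger, cycleoff_s=cycleoff, peak_paw_cmH2O=peak_paw)


def chain_neural(onsets, ti=1.0):
    """Consecutive neural breaths; te derived from the next onset (last: None)."""
    breaths = []
    for i, onset in enumerate(onsets):
        te = (onsets[i + 1] - (onset + ti)) if i + 1 < len(onsets) else None
        b = make_neural(onset, ti=ti, te=te)
        breaths.append(b)
    return breaths


def detection_timing_errors(cfg, rec=None, gt=None):
    """Max |detected - ground truth| per event field, in seconds.

    Asserts detected event counts equal ground truth before pairing by order.
    """
    from neurosync.event_detection import detect_neural_breaths, detect_vent_breaths

    if rec is None:
        rec, gt = simulate_recording(cfg)
    nb = detect_neural_breaths(rec.eadi)
    vb = detect_vent_breaths(rec.paw, peep=cfg.peep_cmH2O)
    assert len(nb) == len(gt.neural_events)
    assert len(vb) == len(gt.vent_events)
    errs = {
        "onset": [b.onset_s - e[0] for b, e in zip(nb, gt.neural_events)],
        "peak": [b.peak_s - e[1] for b, e in zip(nb, gt.neural_events)],
        "neural_cycleoff": [b.cycleoff_s - e[2] for b, e in zip(nb, gt.neural_events)],
        "trigger": [v.trigger_s - e[0] for v, e in zip(vb, gt.vent_events)],
        "vent_cycleoff": [v.cycleoff_s - e[1] for v, e in zip(vb, gt.vent_events)],
    }
    return {k: max(abs(x) for x in v) for k, v in errs.items()}


@pytest.fixture(scope="session")
def noiseless_perfect():
    """60 s, rr 20, zero delay/error/noise: 20 perfectly assisted breaths."""
    cfg = SimulationConfig(
        duration_s=60.0, rr_bpm=20.0, rr_cv=0.0, eadi_peak_cv=0.0,
        trigger_delay_ms=0.0, trigger_delay_sd_ms=0.0,
        cycleoff_error_ms=0.0, cycleoff_error_sd_ms=0.0,
        noise_uV=0.0, noise_cmH2O=0.0, seed=1,
    )
    return cfg, simulate_recording(cfg)
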