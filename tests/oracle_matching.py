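"""Independent brute-force oracle for neural-ventilator event matching.

Enumerates every legal assignment of ventilator triggers to neural-breath
intervals (each trigger may go to the interval containing it, or be left
unassigned when the auto-trigger rule permits), picks the assignment
maximizing the number of assisted neural breaths, then derives class labels
from assignment counts plus the multiple-EAdi-per-assist override. This is
an exhaustive-search restatement of the matching contract, used to check
the direct-rule implementation on small instances.
"""

import itertools

import numpy as np

LEAD_S = 0.10
EXPIRY_FRACTION = 0.5


def _interval_of(trigger_s, neural):
    idx = None
    for i, b in enumerate(neural):
        lo = b.onset_s - LEAD_S
        hi = neural[i + 1].onset_s - LEAD_S if i + 1 < len(neural) else float("inf")
        if lo <= trigger_s < hi:
            idx = i
    return idx


def _peaks_under(v, neural):
    return [i for i, b in enumerate(neural) if v.trigger_s <= b.peak_s <= v.cycleoff_s]


def _auto_legal(v, i, neural):
    if i is None:
        return True
    b = neural[i]
    if b.te_n_s is None:
        return False
    expiry = b.cycleoff_s + EXPIRY_FRACTION * b.te_n_s
    return v.trigger_s > expiry and not _peaks_under(v, neural)


def brute_force_match(neural, vent):
    """Return {'neural': [klass per breath], 'vent': [klass per assist]}."""
    neural = sorted(neural, key=lambda b: b.onset_s)
    vent = sorted(vent, key=lambda v: v.trigger_s)
    n, m = len(neural), len(vent)

    candidates = []
    for v in vent:
        i = _interval_of(v.trigger_s, neural)
        opts = []
        if i is not None and not _auto_legal(v, i, neural):
            opts.append(i)
        if _auto_legal(v, i, neural) or i is None:
            opts.append(None)
        candidates.append(opts)

    best = None
    best_score = -1
    for combo in itertools.product(*candidates):
        assisted = len({i for i in combo if i is not None})
        if assisted > best_score:
            best_score = assisted
            best = combo

    vent_klass = [None] * m
    neural_klass = [None] * n

    # multiple-EAdi override: an assigned assist spanning >= 2 unconsumed peaks
    consumed = [False] * n
    for j, v in enumerate(vent):
        if best[j] is None:
            vent_klass[j] = "auto_trigger"
            continue
        under = [i for i in _peaks_under(v, neural) if not consumed[i]]
        if len(under) >= 2:
            vent_klass[j] = "multi_eadi"
            for i in under:
                consumed[i] = True
                neural_klass[i] = "multi_eadi"

    for i in range(n):
        if consumed[i]:
            continue
        js = [j for j in range(m) if best[j] == i and vent_klass[j] is None]
        if not js:
            neural_klass[i] = "wasted_effort"
        elif len(js) == 1:
            neural_klass[i] = "matched"
            vent_klass[js[0]] = "matched"
        else:
            neural_klass[i] = "double_trigger"
            for j in js:
                vent_klass[j] = "double_trigger"

    for j in range(m):
        if vent_klass[j] is None:
            vent_klass[j] = "auto_trigger"
    return {"neural": neural_klass, "vent": vent_klass}


def record_classes(records):
    """Flatten BreathRecords into per-neural and per-vent class lists."""
    neural, vent = [], []
    for r in records:
        ns = r.neural if isinstance(r.neural, list) else ([r.neural] if r.neural else [])
        vs = r.vent if isinstance(r.vent, list) else ([r.vent] if r.vent else [])
        for b in ns:
            neural.append((b.onset_s, r.klass))
        for v in vs:
            vent.append((v.trigger_s, r.klass))
    neural.sort()
    vent.sort()
    return [k for _, k in neural], [k for _, k in vent]


def random_instance(rng, max_events=6):
    """A small random matching instance (neural breaths + triggers)."""
    from conftest import chain_neural, make_vent

    n = int(rng.integers(1, max_events + 1))
    gaps = rng.uniform(1.5, 3.0, size=n)
    onsets = list(np.cumsum(gaps))
    neural = chain_neural(onsets, ti=1.0)
    m = int(rng.integers(0, max_events + 1))
    t_max = onsets[-1] + 2.0
    vent = []
    for _ in range(m):
        trig = float(rng.uniform(0.0, t_max))
        vent.append(make_vent(trig, trig + float(rng.uniform(0.3, 2.5))))
    vent.sort(key=lambda v: v.trigger_s)
    return neural, vent
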