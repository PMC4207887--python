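import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import chain_neural, make_neural, make_vent
from neurosync.errors import ConfigError
from neurosync.pipeline import analyze_recording
from neurosync.synchrony_core import (
    BreathRecord,
    SynchronyParams,
    breath_error,
    build_report,
    classify_box,
    cycleoff_error,
    match_events,
    neurosync_index,
    score_records,
    trigger_error,
)
from neurosync.synthetic_data import preset_mode_config, simulate_recording
from oracle_matching import brute_force_match, random_instance, record_classes


def _matched(trig_pct=None, cyc_pct=None):
    rec = BreathRecord("matched", neural=make_neural(0.0), vent=make_vent(0.2))
    rec.trigger_error_pct = trig_pct
    rec.cycleoff_error_pct = cyc_pct
    return rec


class TestMatching:
    def test_one_to_one_is_matched(self):
        neural = chain_neural([0.0])
        records = match_events(neural, [make_vent(0.3)])
        assert [r.klass for r in records] == ["matched"]

    def test_unassisted_effort_is_wasted_with_full_error(self):
        records = score_records(match_events(chain_neural([0.0]), []))
        assert records[0].klass == "wasted_effort"
        assert records[0].breath_error_pct == 100.0

    def test_two_triggers_in_one_interval_is_double_trigger(self):
        neural = chain_neural([0.0, 3.0, 6.0])
        vents = [make_vent(t, t + 0.6) for t in (0.2, 3.2, 3.9, 6.2)]
        records = match_events(neural, vents)
        assert [r.klass for r in records] == ["matched", "double_trigger", "matched"]

    def test_assist_spanning_two_peaks_is_multi_eadi(self):
        neural = chain_neural([0.0, 2.0], ti=1.0)
        records = match_events(neural, [make_vent(0.1, 3.2)])
        assert [r.klass for r in records] == ["multi_eadi"]
        assert len(records[0].neural) == 2

    def test_assist_deep_in_expiration_is_auto_trigger(self):
        neural = chain_neural([0.0, 4.0])  # cycleoff 1.0, te 3.0, expiry 2.5
        records = match_events(neural, [make_vent(0.2, 0.9), make_vent(2.8, 3.4)])
        klasses = sorted(r.klass for r in records)
        assert klasses == ["auto_trigger", "matched", "wasted_effort"]

    def test_every_event_appears_exactly_once(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            neural, vent = random_instance(rng)
            records = match_events(neural, vent)
            nk, vk = record_classes(records)
            assert len(nk) == len(neural)
            assert len(vk) == len(vent)

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            neural, vent = random_instance(rng)
            records = match_events(neural, vent)
            got_n, got_v = record_classes(records)
            oracle = brute_force_match(neural, vent)
            assert got_n == oracle["neural"]
            assert got_v == oracle["vent"]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(st.floats(1.5, 3.0), min_size=1, max_size=6),
        trig_fracs=st.lists(st.tuples(st.floats(0.0, 1.0), st.floats(0.3, 2.5)),
                            max_size=6),
    )
    def test_matching_property_against_enumeration(self, gaps, trig_fracs):
        """Any small instance: direct-rule matching equals exhaustive search."""
        onsets = list(np.cumsum(gaps))
        neural = chain_neural(onsets, ti=1.0)
        t_max = onsets[-1] + 2.0
        vent = sorted(
            (make_vent(f * t_max, f * t_max + dur) for f, dur in trig_fracs),
            key=lambda v: v.trigger_s,
        )
        got_n, got_v = record_classes(match_events(neural, vent))
        oracle = brute_force_match(neural, vent)
        assert got_n == oracle["neural"]
        assert got_v == oracle["vent"]

    def test_class_counts_invariant_to_input_order(self):
        rng = np.random.default_rng(21)
        neural, vent = random_instance(rng)
        a = sorted(r.klass for r in match_events(neural, vent))
        shuffled_n, shuffled_v = list(neural), list(vent)
        random.Random(0).shuffle(shuffled_n)
        random.Random(1).shuffle(shuffled_v)
        b = sorted(r.klass for r in match_events(shuffled_n, shuffled_v))
        assert a == b


class TestErrorArithmetic:
    def test_trigger_error_percent_and_ms(self):
        rec = BreathRecord("matched", neural=make_neural(0.0, ti=1.0),
                           vent=make_vent(0.2))
        assert trigger_error(rec) == pytest.approx(20.0)
        assert rec.trigger_delay_ms == pytest.approx(200.0)

    def test_trigger_at_onset_is_zero(self):
        rec = BreathRecord("matched", neural=make_neural(0.0), vent=make_vent(0.0))
        assert trigger_error(rec) == pytest.approx(0.0)

    def test_trigger_error_rejects_non_matched(self):
        with pytest.raises(ConfigError):
            trigger_error(BreathRecord("wasted_effort", neural=make_neural(0.0)))

    def test_early_cycling_is_negative(self):
        # neural cycle-off 1.0 s, pneumatic 0.9 s, te 2.0 s -> -5% (early)
        rec = BreathRecord("matched", neural=make_neural(0.0, ti=1.0, te=2.0),
                           vent=make_vent(0.1, 0.9))
        assert cycleoff_error(rec) == pytest.approx(-5.0)
        assert rec.cycleoff_error_ms == pytest.approx(-100.0)

    def test_coincident_cycleoff_is_zero(self):
        rec = BreathRecord("matched", neural=make_neural(0.0, ti=1.0, te=2.0),
                           vent=make_vent(0.1, 1.0))
        assert cycleoff_error(rec) == pytest.approx(0.0)

    def test_cycleoff_error_requires_te(self):
        rec = BreathRecord("matched", neural=make_neural(0.0, te=None),
                           vent=make_vent(0.1, 0.9))
        rec.neural.te_n_s = None
        with pytest.raises(ConfigError):
            cycleoff_error(rec)

    def test_error_magnitudes_capped_at_100(self):
        rec = BreathRecord("matched", neural=make_neural(0.0, ti=0.5, te=1.0),
                           vent=make_vent(1.2, 3.5))
        assert trigger_error(rec) == pytest.approx(100.0)
        assert cycleoff_error(rec) == pytest.approx(100.0)


class TestBreathError:
    def test_asynchrony_scores_100(self):
        for klass in ("wasted_effort", "auto_trigger", "double_trigger", "multi_eadi"):
            assert breath_error(BreathRecord(klass)) == 100.0

    def test_mean_of_magnitudes(self):
        assert breath_error(_matched(20.0, -10.0)) == pytest.approx(15.0)
        assert breath_error(_matched(0.0, 0.0)) == 0.0

    def test_max_combination_switch(self):
        params = SynchronyParams(error_combination="max")
        assert breath_error(_matched(20.0, -10.0), params) == pytest.approx(20.0)

    def test_last_breath_uses_trigger_only(self):
        assert breath_error(_matched(30.0, None)) == pytest.approx(30.0)


class TestNeuroSyncIndex:
    def _records(self, errors, klasses=None):
        out = []
        for i, e in enumerate(errors):
            klass = klasses[i] if klasses else "matched"
            rec = _matched(0.0, 0.0) if klass == "matched" else BreathRecord(klass)
            rec.breath_error_pct = e
            out.append(rec)
        return out

    def test_simple_mean(self):
        assert neurosync_index(self._records([0.0, 0.0, 100.0])) == pytest.approx(100 / 3)

    def test_perfect_synchrony_is_zero(self):
        assert neurosync_index(self._records([0.0] * 10)) == 0.0

    def test_ninety_ten_construction_exact(self):
        records = self._records([0.0] * 90 + [100.0] * 10,
                                ["matched"] * 90 + ["wasted_effort"] * 10)
        assert neurosync_index(records, include_wasted=True) == 10.0
        assert neurosync_index(records, include_wasted=False) == 0.0

    def test_empty_retained_set_rejected(self):
        records = self._records([100.0], ["wasted_effort"])
        with pytest.raises(ConfigError):
            neurosync_index(records, include_wasted=False)

    def test_index_equals_mean_of_per_breath_errors_on_simulation(self):
        cfg = preset_mode_config("PSV-like", duration_s=120.0, seed=14)
        rec, _ = simulate_recording(cfg)
        rep = analyze_recording(rec, window_s=None).report
        recomputed = np.mean([r.breath_error_pct for r in rep.per_breath])
        assert rep.neurosync_pct == pytest.approx(recomputed, abs=1e-9)


class TestBoxClassification:
    def test_inside_box_is_synchronous(self):
        assert classify_box(_matched(5.0, -3.0)) == "synchronous"

    def test_one_axis_outside_is_dyssynchronous(self):
        assert classify_box(_matched(25.0, 0.0)) == "dyssynchronous"

    def test_non_matched_is_asynchronous(self):
        assert classify_box(BreathRecord("auto_trigger")) == "asynchronous"


class TestReport:
    def test_all_synchronous(self):
        records = score_records(match_events(
            chain_neural([3.0 * i for i in range(10)]),
            [make_vent(3.0 * i + 0.05, 3.0 * i + 1.0) for i in range(10)],
        ))
        rep = build_report(records, 30.0)
        assert rep.pct_synchronous == 100.0
        assert rep.neurosync_pct < 10.0

    def test_ninety_ten_proportions(self):
        records = []
        for i in range(90):
            r = _matched(0.0, 0.0)
            r.breath_error_pct = 0.0
            records.append(r)
        for i in range(10):
            r = BreathRecord("wasted_effort", neural=make_neural(300.0 + 3.0 * i))
            r.breath_error_pct = 100.0
            records.append(r)
        rep = build_report(records, 300.0)
        assert rep.neurosync_pct == pytest.approx(10.0)
        assert (rep.pct_synchronous, rep.pct_dyssynchronous, rep.pct_asynchronous) == \
            (90.0, 0.0, 10.0)
        assert rep.wasted_per_min == pytest.approx(2.0)

    def test_empty_input_degenerate(self):
        rep = build_report([], 300.0)
        assert rep.n_breaths == 0
        assert rep.neurosync_pct is None

    def test_density_grid_counts_matched_breaths(self):
        records = [_matched(7.0, -12.0)]
        records[0].breath_error_pct = 9.5
        rep = build_report(records, 60.0)
        grid = np.asarray(rep.density_grid["counts"])
        assert grid.sum() == 1
        # cycle-off -12% -> bin index (100-12)/5 = 17; trigger +7% -> (100+7)/5 = 21
        assert grid[17, 21] == 1
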