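"""Breath segmentation, per-breath features, QC filters and Bi aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayphys import plethysmography as pl
from airwayphys import synthetic as syn


def make_record(**kw) -> pl.BreathRecord:
    base = dict(start=0.0, end=1.0, ti=0.3, te=0.6, rt=0.25,
                pip=9.0, pep=8.0, tvi=2.0, tve=2.0)
    base.update(kw)
    return pl.BreathRecord(**base)


class TestSegmentation:
    def test_sinusoid_yields_one_segment_per_cycle(self):
        t = np.arange(0, 10, 0.01)
        segs = pl.segment_breaths(t, np.sin(2 * np.pi * t))
        assert len(segs) == 10

    def test_flat_signal_yields_empty_list(self):
        t = np.arange(0, 5, 0.01)
        assert pl.segment_breaths(t, np.zeros_like(t)) == []

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.15, 0.9, 1.4])
        with pytest.raises(ValueError, match="non-uniform"):
            pl.segment_breaths(t, np.ones_like(t))

    def test_jittered_train_boundaries_within_two_samples(self, rng):
        fs = 200.0
        params = []
        for _ in range(25):
            period_jitter = rng.uniform(0.9, 1.1)
            p = syn.GUINEA_PIG_BREATH
            rt = p.rt * period_jitter
            params.append(syn.BreathParams(
                ti=p.ti * period_jitter, te=p.te * period_jitter, rt=rt,
                pip=p.pip, pep=1.35 * p.tve / rt, tvi=p.tvi, tve=p.tve))
        wf = syn.gen_breath_train(params, sample_rate=fs, seed=1)
        segs = pl.segment_breaths(wf.time, wf.signal)
        assert len(segs) == 25
        onsets = np.array([wf.time[s.start] for s in segs])
        truth = np.array([b["onset_s"] for b in wf.truth])
        assert np.all(np.abs(onsets - truth) <= 2.0 / fs + 1e-12)


class TestBreathFeatures:
    def test_symmetric_triangular_breath(self):
        # triangle up then mirrored triangle down: TVi = TVe, PIP = PEP
        fs = 500.0
        half = np.linspace(0, 1, 250, endpoint=False)
        lobe = np.concatenate([half, 1 - half])
        sig = np.concatenate([lobe, -lobe])
        t = np.arange(sig.size) / fs
        rec = pl.breath_features(t, sig, slice(0, sig.size))
        assert rec.qc_pass
        assert rec.pip == pytest.approx(rec.pep, rel=1e-6)
        assert rec.tvi == pytest.approx(rec.tve, rel=5e-3)

    def test_round_trip_recovers_requested_relaxation_time(self):
        fs = 400.0
        p = syn.BreathParams(ti=0.3, te=0.6, rt=0.30, pip=9.0, pep=7.5, tvi=2.0, tve=2.0)
        wf = syn.gen_breath_train([p] * 5, sample_rate=fs, seed=0)
        segs = pl.segment_breaths(wf.time, wf.signal)
        recs = [pl.breath_features(wf.time, wf.signal, s) for s in segs]
        for rec in recs:
            assert rec.rt == pytest.approx(0.30, abs=2.0 / fs)

    def test_no_expiratory_lobe_gives_qc_failure_not_exception(self):
        t = np.arange(0, 2, 0.01)
        sig = np.clip(np.sin(2 * np.pi * t), 0, None)  # inspiration only
        rec = pl.breath_features(t, sig, slice(0, t.size))
        assert not rec.qc_pass
        assert rec.qc_reason == "no expiration"


class TestBiFormula:
    @pytest.mark.parametrize(
        "te,rt,pep,pip,expected",
        [
            (0.6, 0.3, 5.0, 5.0, 1.0),
            (0.5, 0.5, 3.0, 2.0, 0.0),
            (0.75, 0.25, 3.0, 2.0, 3.0),
        ],
    )
    def test_printed_formula(self, te, rt, pep, pip, expected):
        assert pl.compute_bi(te, rt, pep, pip) == pytest.approx(expected)

    @pytest.mark.parametrize("te,rt,pep,pip", [(0.6, 0.0, 1.0, 1.0), (0.6, 0.3, 1.0, 0.0)])
    def test_degenerate_denominators_rejected(self, te, rt, pep, pip):
        with pytest.raises(ValueError):
            pl.compute_bi(te, rt, pep, pip)

    @given(
        te=st.floats(0.2, 3.0), rt_frac=st.floats(0.05, 1.0),
        pep=st.floats(0.5, 20.0), pip=st.floats(0.5, 20.0),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bi_invariant_under_pressure_rescaling(self, te, rt_frac, pep, pip, c):
        rt = rt_frac * te
        assert pl.compute_bi(te, rt, c * pep, c * pip) == pytest.approx(
            pl.compute_bi(te, rt, pep, pip), rel=1e-9)


class TestFilters:
    def test_first_violated_rule_is_reported(self):
        cases = {
            "tidal_volume": make_record(tvi=0.9, tve=0.9),
            "min_Ti": make_record(ti=0.10),
            "max_Ti": make_record(ti=3.5),
            "volume_diff": make_record(tvi=2.0, tve=1.7),
        }
        for expected, rec in cases.items():
            _, rej = pl.apply_breath_filters([rec])
            assert rej and rej[0].qc_reason == expected

    def test_interior_point_accepted_and_boundaries_inclusive(self):
        recs = [
            make_record(tvi=1.2, tve=1.2),          # 0% volume difference
            make_record(tvi=1.0, tve=1.0),          # TV boundary
            make_record(ti=0.15),                   # min Ti boundary
            make_record(ti=3.0),                    # max Ti boundary
            make_record(tvi=2.0, tve=1.8),          # exactly 10% difference
        ]
        acc, rej = pl.apply_breath_filters(recs)
        assert len(acc) == 5 and not rej

    def test_filter_is_idempotent(self):
        recs = [make_record(tvi=0.9, tve=0.9), make_record(), make_record(ti=0.1)]
        acc1, rej1 = pl.apply_breath_filters(recs)
        acc2, rej2 = pl.apply_breath_filters(acc1 + rej1)
        assert {id(r) for r in acc1} == {id(r) for r in acc2}
        assert [r.qc_reason for r in rej1] == [r.qc_reason for r in rej2]

    def test_tightening_rules_never_grows_accepted_set(self):
        recs = [make_record(tvi=v, tve=v) for v in np.linspace(0.5, 3.0, 20)]
        acc_loose, _ = pl.apply_breath_filters(recs, pl.FilterRules(min_tidal_volume=1.0))
        acc_tight, _ = pl.apply_breath_filters(recs, pl.FilterRules(min_tidal_volume=2.0))
        assert {id(r) for r in acc_tight} <= {id(r) for r in acc_loose}


class TestAggregation:
    @staticmethod
    def records_with_bi(times, bi):
        return [make_record(start=t, end=t + 0.5, bi=b) for t, b in zip(times, bi)]

    def test_constant_bi_over_five_minutes(self):
        recs = self.records_with_bi(np.arange(0, 300, 1.0), np.full(300, 2.0))
        value, _ = pl.aggregate_bi(recs, t_end=300.0)
        assert value == pytest.approx(2.0)

    def test_only_last_five_minutes_counted(self):
        times = np.arange(0, 900, 1.0)
        bi = np.where(times < 600, 1.0, 4.0)
        value, series = pl.aggregate_bi(self.records_with_bi(times, bi), t_end=900.0)
        assert value == pytest.approx(4.0)
        assert np.all(np.diff(series.window_start) == 15.0)

    def test_no_accepted_breaths_gives_missing_value(self):
        recs = [make_record(start=10.0, bi=2.0, qc_pass=False, qc_reason="tidal_volume")]
        value, series = pl.aggregate_bi(recs, t_end=300.0)
        assert np.isnan(value) and series.bi_mean.size == 0

    def test_aggregate_lies_within_contributing_bi_range(self, rng):
        times = np.sort(rng.uniform(0, 300, 120))
        bi = rng.uniform(0.5, 5.0, 120)
        value, series = pl.aggregate_bi(self.records_with_bi(times, bi), t_end=300.0)
        assert bi.min() - 1e-12 <= value <= bi.max() + 1e-12
        for w0, m in zip(series.window_start, series.bi_mean):
            members = bi[(times >= w0) & (times < w0 + 15.0)]
            assert members.min() - 1e-12 <= m <= members.max() + 1e-12


class TestSessionSummary:
    def test_rmax_is_max_of_post_values(self):
        sess = pl.session_summary(1.0, [(5, 1.0), (10, 2.5), (25, 4.0), (40, 3.0)], 1.0)
        assert sess.rmax_obstruction == 4.0

    def test_delta_baseline_sign_convention(self):
        assert pl.session_summary(1.5, [(5, 2.0)], 1.0).delta_baseline_bi == pytest.approx(0.5)
        assert pl.session_summary(1.0, [(5, 2.0)], 1.0).delta_baseline_bi == 0.0

    def test_missing_baseline_or_schedule_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            pl.session_summary(float("nan"), [(5, 1.0)], 1.0)
        with pytest.raises(ValueError, match="increasing"):
            pl.session_summary(1.0, [(10, 1.0), (5, 2.0)], 1.0)
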