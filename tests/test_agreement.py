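import numpy as np
import pandas as pd
import pytest

from calanfeed import (
    ContingencyTable2x2,
    DataError,
    ObserverLog,
    align_to_sensor,
    classify_state,
    cohens_kappa,
    contingency,
    predictive_values,
)
from calanfeed.agreement import read_observer_csv, write_observer_csv
from calanfeed.simulate import simulate_bundle
from calanfeed.states import StateSeries
from calanfeed import TiltSeries


def _states(bits, start="2021-06-01 08:00:00"):
    tilt = TiltSeries(
        "d1", 30.0,
        pd.DatetimeIndex(pd.date_range(start, periods=len(bits), freq="30s")),
        np.where(np.asarray(bits) > 0, 70.0, 0.0),
    )
    return classify_state(tilt)


class TestAlignToSensor:
    def test_exact_timestamp_in_uniform_run(self):
        st = _states(np.ones(40))
        log = ObserverLog("d1", pd.DatetimeIndex([pd.Timestamp("2021-06-01 08:10:00")]), [1])
        pairs, dropped = align_to_sensor(log, st)
        assert dropped == 0
        assert pairs.iloc[0].tolist() == [1, 1]

    def test_window_mode_suppresses_single_glitch(self):
        bits = np.ones(40)
        bits[20] = 0  # one flipped sensor sample
        st = _states(bits)
        t_glitch = st.timestamps[20]
        log = ObserverLog("d1", pd.DatetimeIndex([t_glitch]), [1])
        pairs, _ = align_to_sensor(log, st, k=5)
        assert pairs.iloc[0]["sensor"] == 1

    def test_out_of_span_records_dropped(self):
        st = _states(np.ones(10))
        log = ObserverLog(
            "d1",
            pd.DatetimeIndex([pd.Timestamp("2021-06-01 07:00:00"),
                              pd.Timestamp("2021-06-01 08:02:00")]),
            [0, 1],
        )
        pairs, dropped = align_to_sensor(log, st)
        assert dropped == 1 and len(pairs) == 1

    def test_noise_free_scenario_agrees_everywhere(self, validation_scenario):
        bundle = simulate_bundle(validation_scenario)
        for cow, series in bundle.tilt.items():
            st = classify_state(series)
            pairs, dropped = align_to_sensor(bundle.observers[cow], st, k=5)
            assert dropped == 0
            assert (pairs["sensor"] == pairs["observer"]).all()


class TestContingency:
    def test_concordant_open_only(self):
        pairs = pd.DataFrame({"sensor": np.ones(10, int), "observer": np.ones(10, int)})
        t = contingency(pairs)
        assert (t.n11, t.n10, t.n01, t.n00) == (10, 0, 0, 0)

    def test_hand_tally(self):
        pairs = pd.DataFrame(
            {"sensor": [1, 1, 0, 0, 1, 0], "observer": [1, 0, 1, 0, 1, 0]}
        )
        t = contingency(pairs)
        assert (t.n11, t.n10, t.n01, t.n00) == (2, 1, 1, 2)

    def test_random_stream_matches_tally_oracle(self):
        rng = np.random.default_rng(3)
        s, o = rng.integers(0, 2, 500), rng.integers(0, 2, 500)
        t = contingency(pd.DataFrame({"sensor": s, "observer": o}))
        assert t.n11 == int(((s == 1) & (o == 1)).sum())
        assert t.n00 == int(((s == 0) & (o == 0)).sum())
        assert t.total == 500


class TestCohensKappa:
    def test_perfect_agreement(self):
        stats = cohens_kappa(ContingencyTable2x2(50, 0, 0, 50))
        assert stats.kappa == pytest.approx(1.0)
        assert stats.ppv == stats.npv == 1.0

    def test_chance_level_agreement(self):
        stats = cohens_kappa(ContingencyTable2x2(25, 25, 25, 25))
        assert stats.kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_definitional_formula_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        t = ContingencyTable2x2(40, 5, 10, 45)
        stats = cohens_kappa(t)
        n = t.total
        p_o = (t.n11 + t.n00) / n
        p_e = ((t.n11 + t.n10) * (t.n11 + t.n01) + (t.n01 + t.n00) * (t.n10 + t.n00)) / n**2
        assert stats.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        s = np.repeat([1, 1, 0, 0], [t.n11, t.n10, t.n01, t.n00])
        o = np.repeat([1, 0, 1, 0], [t.n11, t.n10, t.n01, t.n00])
        assert stats.kappa == pytest.approx(cohen_kappa_score(s, o))
        assert stats.ci95[0] < stats.kappa < stats.ci95[1]

    def test_symmetric_relabeling_invariance(self):
        a = cohens_kappa(ContingencyTable2x2(40, 5, 10, 45)).kappa
        b = cohens_kappa(ContingencyTable2x2(45, 10, 5, 40)).kappa
        assert a == pytest.approx(b)

    def test_kappa_bounded_by_observed_agreement(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = rng.integers(1, 100, 4)
            t = ContingencyTable2x2(*map(int, n))
            try:
                stats = cohens_kappa(t)
            except DataError:
                continue
            assert stats.kappa <= stats.observed_agreement + 1e-12
            assert -1 <= stats.kappa <= 1

    def test_degenerate_marginals_undefined(self):
        with pytest.raises(DataError):
            cohens_kappa(ContingencyTable2x2(100, 0, 0, 0))


class TestPredictiveValues:
    def test_published_style_table(self):
        ppv, npv = predictive_values(ContingencyTable2x2(98, 2, 3, 97))
        assert ppv == pytest.approx(0.98)
        assert npv == pytest.approx(0.97)

    def test_random_tables_match_definition(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n11, n10, n01, n00 = map(int, rng.integers(1, 50, 4))
            ppv, npv = predictive_values(ContingencyTable2x2(n11, n10, n01, n00))
            assert ppv == pytest.approx(n11 / (n11 + n10))
            assert npv == pytest.approx(n00 / (n00 + n01))

    def test_zero_denominator_flagged_nan(self):
        ppv, npv = predictive_values(ContingencyTable2x2(0, 0, 3, 97))
        assert np.isnan(ppv) and npv == pytest.approx(0.97)


def test_observer_csv_roundtrip(tmp_path):
    ts = pd.DatetimeIndex(pd.date_range("2021-06-01 08:00:00", periods=5, freq="170s"))
    log = ObserverLog("door7", ts, [1, 0, 1, 1, 0])
    path = tmp_path / "obs.csv"
    write_observer_csv([log], path)
    back = read_observer_csv(path)
    assert len(back) == 1 and back[0].door_id == "door7"
    assert (back[0].labels == log.labels).all()
    assert (back[0].timestamps == log.timestamps).all()
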