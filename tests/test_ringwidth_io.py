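"""Tucson I/O, latewood percentage, intercorrelation screening and rbar."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtring.ringwidth_io import (EmptyCollectionError, InsufficientOverlapError,
                                      RingDataError, RingSeries, RwlParseError,
                                      SeriesCollection, latewood_percentage, rbar,
                                      read_long_csv, read_rwl, screen_collection,
                                      series_intercorrelation, write_long_csv,
                                      write_rwl)


def make_collection(arrays, first_year=2000, site="S"):
    return SeriesCollection(
        series=[RingSeries(series_id=f"A{i}", first_year=first_year, rw=np.asarray(a))
                for i, a in enumerate(arrays)], site_id=site)


class TestRingSeries:
    def test_rejects_gaps_and_nonpositive(self):
        with pytest.raises(RingDataError, match="gaps"):
            RingSeries("x", 2000, [1.0, np.nan, 1.2])
        with pytest.raises(RingDataError, match="positive"):
            RingSeries("x", 2000, [1.0, 0.0, 1.2])

    def test_ew_lw_additivity_enforced(self):
        RingSeries("x", 2000, [2.0, 2.0], ew=[1.4, 1.5], lw=[0.6, 0.5])
        with pytest.raises(RingDataError, match="EW \\+ LW"):
            RingSeries("x", 2000, [2.0, 2.0], ew=[1.4, 1.5], lw=[0.8, 0.5])

    def test_duplicate_ids_rejected(self):
        s = RingSeries("dup", 2000, [1.0, 1.1])
        with pytest.raises(RingDataError, match="duplicate"):
            SeriesCollection(series=[s, RingSeries("dup", 2000, [1.0, 1.2])])


class TestRwlFormat:
    def test_basic_units_and_terminator(self, tmp_path):
        p = tmp_path / "one.rwl"
        p.write_text("TREE1   2000   250   260   999\n")
        coll = read_rwl(p)
        s = coll.get("TREE1")
        assert s.first_year == 2000
        np.testing.assert_allclose(s.rw, [2.50, 2.60])

    def test_dialects_agree(self, tmp_path):
        """A -9999/0.001 mm file parses to the same mm as its 999/0.01 mm twin."""
        a = tmp_path / "a.rwl"
        b = tmp_path / "b.rwl"
        a.write_text("S1      1995   123   210   305    87    55  1000   999\n")
        b.write_text("S1      1995  1230  2100  3050   870   550 10000 -9999\n")
        np.testing.assert_allclose(read_rwl(a).get("S1").rw,
                                   read_rwl(b).get("S1").rw)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.rwl"
        p.write_text("S1      2000   100   110   999\nS2      20xx   100   999\n")
        with pytest.raises(RwlParseError, match="line 2"):
            read_rwl(p)

    def test_misdated_decade_rejected(self, tmp_path):
        p = tmp_path / "bad.rwl"
        p.write_text("S1      2000   100   110\nS1      2005   120   999\n")
        with pytest.raises(RwlParseError, match="line 2"):
            read_rwl(p)

    def test_duplicate_series_rejected(self, tmp_path):
        p = tmp_path / "dup.rwl"
        p.write_text("S1      2000   100   999\nS2      2000   100   999\n"
                     "S1      2010   100   999\n")
        with pytest.raises(RwlParseError, match="duplicate"):
            read_rwl(p)

    def test_write_read_round_trip(self, tmp_path):
        coll = make_collection([[2.5, 2.6, 2.7], [1.0, 1.1]], first_year=1987)
        out = tmp_path / "rt.rwl"
        write_rwl(coll, out)
        back = read_rwl(out)
        assert back.ids == coll.ids
        for s in coll:
            b = back.get(s.series_id)
            assert b.first_year == s.first_year
            np.testing.assert_allclose(b.rw, s.rw)

    def test_single_ring_series(self, tmp_path):
        out = tmp_path / "one.rwl"
        write_rwl(make_collection([[1.23]]), out)
        text = out.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].split()[-1] == "999"
        np.testing.assert_allclose(read_rwl(out).get("A0").rw, [1.23])

    def test_empty_collection_writes_empty_payload(self, tmp_path):
        out = tmp_path / "empty.rwl"
        write_rwl(SeriesCollection(), out)
        assert out.read_text() == ""

    def test_unrepresentable_span_rejected(self, tmp_path):
        coll = make_collection([[1.0, 1.1]], first_year=9999)
        with pytest.raises(RwlParseError, match="not\\s+representable"):
            write_rwl(coll, tmp_path / "x.rwl")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_random_series_round_trip(self, tmp_path_factory, seed):
        """An 80-year series with random widths survives write+read exactly."""
        rng = np.random.default_rng(seed)
        rw = np.round(rng.uniform(0.05, 9.0, 80), 2)  # 0.01 mm resolution
        coll = SeriesCollection(series=[RingSeries("RND", 1931, rw)])
        path = tmp_path_factory.mktemp("rwl") / "r.rwl"
        write_rwl(coll, path)
        np.testing.assert_allclose(read_rwl(path).get("RND").rw, rw)


class TestLongForm:
    def test_round_trip(self, tmp_path, small_sim):
        _, _, coll, _ = small_sim
        path = tmp_path / "long.csv"
        write_long_csv(coll, path)
        back = read_long_csv(path)[coll.site_id]
        assert len(back) == len(coll)
        s0 = coll.series[0]
        b0 = back.get(s0.series_id)
        np.testing.assert_allclose(b0.rw, s0.rw)
        np.testing.assert_allclose(b0.lw, s0.lw)
        assert b0.provenance_id == s0.provenance_id
        assert b0.block_id == s0.block_id


class TestLatewoodPercentage:
    @pytest.mark.parametrize("lw,rw,expected", [
        (1.0, 4.0, 25.0),
        (0.0, 2.5, 0.0),
        (0.78, 2.81, 27.75800711743772),
    ])
    def test_values(self, lw, rw, expected):
        assert latewood_percentage(lw, rw) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(RingDataError):
            latewood_percentage(0.5, 0.0)
        with pytest.raises(RingDataError):
            latewood_percentage(3.0, 2.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 10), st.floats(0.1, 1000))
    def test_scale_invariance(self, frac_times_ten, k):
        lw, rw = frac_times_ten, 10.0
        assert latewood_percentage(k * lw, k * rw) == pytest.approx(
            latewood_percentage(lw, rw), rel=1e-9)


class TestIntercorrelation:
    def test_identical_series_give_one(self):
        coll = make_collection([np.linspace(1, 2, 30)] * 5)
        for sid in coll.ids:
            assert series_intercorrelation(coll, sid) == pytest.approx(1.0)

    def test_negated_deviations_give_minus_one(self):
        base = 2.0 + 0.3 * np.sin(np.arange(30))
        # log-deviations of the target are the exact negative of the master's
        target = 2.0 ** 2 / base
        coll = make_collection([base, base, base, target])
        assert series_intercorrelation(coll, "A3") == pytest.approx(-1.0)

    def test_matches_brute_force_master_rebuild(self, shared_signal_collection):
        """Against an independent pairwise master-rebuild implementation."""
        coll = shared_signal_collection
        filt = {s.series_id: pd.Series(np.diff(np.log(s.rw)), index=s.years[1:])
                for s in coll}
        for sid in coll.ids:
            others = pd.DataFrame({k: v for k, v in filt.items() if k != sid})
            master = others.sum(axis=1) / others.notna().sum(axis=1)
            merged = pd.concat([filt[sid], master], axis=1).dropna()
            expected = np.corrcoef(merged.iloc[:, 0], merged.iloc[:, 1])[0, 1]
            assert series_intercorrelation(coll, sid) == pytest.approx(
                expected, abs=1e-12)

    def test_short_overlap_flagged(self):
        coll = make_collection([np.full(5, 2.0) + 0.1 * np.arange(5)] * 3)
        with pytest.raises(InsufficientOverlapError):
            series_intercorrelation(coll, "A0")


class TestScreening:
    def test_identical_series_all_retained(self):
        coll = make_collection([np.linspace(1, 2, 30)] * 6)
        retained, rejected = screen_collection(coll)
        assert rejected == [] and len(retained) == 6

    def test_threshold_zero_rejects_nothing(self, shared_signal_collection):
        retained, rejected = screen_collection(shared_signal_collection, threshold=0)
        assert rejected == []

    def test_noise_series_rejected(self):
        """One pure-noise series among 20 shared-signal ones goes at 0.328."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            signal = rng.normal(0, 0.2, 50)
            arrays = [2.0 * np.exp(signal + rng.normal(0, 0.1, 50))
                      for _ in range(20)]
            arrays.append(2.0 * np.exp(rng.normal(0, 0.22, 50)))  # no signal
            coll = make_collection(arrays)
            _, rejected = screen_collection(coll, threshold=0.328)
            hits += "A20" in rejected
        assert hits / n_rep >= 0.95

    def test_monotone_in_threshold(self, shared_signal_collection):
        r1, _ = screen_collection(shared_signal_collection, threshold=0.2)
        r2, _ = screen_collection(shared_signal_collection, threshold=0.6)
        assert set(r2.ids) <= set(r1.ids)

    def test_all_rejected_is_an_error(self):
        rng = np.random.default_rng(0)
        coll = make_collection([2.0 * np.exp(rng.normal(0, 0.2, 40))
                                for _ in range(5)])
        with pytest.raises(EmptyCollectionError):
            screen_collection(coll, threshold=0.999)


class TestRbar:
    def test_identical_series(self):
        coll = make_collection([np.linspace(1, 2, 30)] * 4)
        assert rbar(coll) == pytest.approx(1.0)

    def test_sign_reversed_pair(self):
        x = 2.0 + 0.3 * np.sin(np.arange(30))
        coll = make_collection([x, 4.0 - x])
        assert rbar(coll) == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, shared_signal_collection):
        coll = shared_signal_collection
        vals = []
        series = coll.series
        for i in range(len(series)):
            for j in range(i + 1, len(series)):
                vals.append(np.corrcoef(series[i].rw, series[j].rw)[0, 1])
        assert rbar(coll) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_affine_rescaling_invariance(self, shared_signal_collection):
        coll = shared_signal_collection
        scaled = SeriesCollection(series=[
            RingSeries(s.series_id, s.first_year, s.rw * (2.0 + 0.1 * i))
            for i, s in enumerate(coll.series)], site_id=coll.site_id)
        assert rbar(scaled) == pytest.approx(rbar(coll), abs=1e-12)
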