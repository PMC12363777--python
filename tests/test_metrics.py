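"""Measurement procedures on constructed states and series."""

import numpy as np
import pandas as pd
import pytest

from corneasim import metrics
from corneasim.scenario import CellSample, RunResult
from corneasim.config import default_config
from corneasim.types import BASAL, STEM, SUPER, WING

from conftest import make_state


def _sample(mcs, specs):
    """specs: list of (id, type, x, y)."""
    ids = np.array([s[0] for s in specs], dtype=np.int32)
    ct = np.array([s[1] for s in specs], dtype=np.int8)
    xs = np.array([s[2] for s in specs], dtype=np.float32)
    ys = np.array([s[3] for s in specs], dtype=np.float32)
    return CellSample(mcs=mcs, ids=ids, ctype=ct, com_x=xs, com_y=ys,
                      volume=np.full(len(ids), 25, dtype=np.int32))


def _result(samples):
    return RunResult(config=default_config(), seed=0, samples=samples)


class TestThickness:
    def test_com_difference_arithmetic(self):
        # super layer mean y 60 px, basal+stem mean y 35 px -> 50 μm
        st, _ = make_state(10, 80, [
            (BASAL, 30, 40, 0, 10), (STEM, 30, 40, 0, 2),
            (SUPER, 55, 65, 0, 10)])
        # constructed COMs: basal/stem band centered at 34.5/35 -> use exact
        res = metrics.thickness_com(st)
        t = st.table
        sup = st.ids_of_type(SUPER)
        base = st.ids_of_type(BASAL, STEM)
        ys = lambda ids: np.mean(t.sum_y[ids] / t.volume[ids])
        assert res == pytest.approx((ys(sup) - ys(base)) * 2.0)

    def test_exact_example_from_constructed_sample(self):
        s = _sample(0, [(1, SUPER, 5, 60), (2, BASAL, 5, 35), (3, STEM, 8, 35)])
        r = _result([s])
        assert metrics.thickness_series(r).iloc[0] == pytest.approx(50.0)

    def test_missing_layer_gives_nan_marker(self):
        s = _sample(0, [(1, BASAL, 5, 35)])
        r = _result([s])
        assert np.isnan(metrics.thickness_series(r).iloc[0])

    def test_matches_rescan_on_simulated_state(self, injury_base):
        st = injury_base.sim.state
        t = st.table
        sup = st.ids_of_type(SUPER)
        base = st.ids_of_type(BASAL, STEM)
        expect = (np.mean(t.sum_y[sup] / t.volume[sup])
                  - np.mean(t.sum_y[base] / t.volume[base])) * st.pixel_um
        assert metrics.thickness_com(st) == pytest.approx(expect)


class TestSegments:
    def test_boundaries_are_20_voxel_bins(self):
        specs = [(i + 1, SUPER, x, 62) for i, x in enumerate((0, 19))]
        specs += [(10, SUPER, 20, 30)]
        s = _sample(0, specs)
        out = metrics.segment_surface_positions(s)
        assert out[0] == pytest.approx(62 * 2.0)   # both x=0 and x=19 in seg 1
        assert out[1] == pytest.approx(30 * 2.0)   # x=20 starts segment 2
        assert np.isnan(out[2:]).all()             # empty segments marked

    def test_flat_layer_gives_uniform_positions(self):
        specs = [(i + 1, SUPER, 10 + 20 * i, 62.0) for i in range(10)]
        s = _sample(0, specs)
        out = metrics.segment_surface_positions(s)
        assert np.allclose(out, 124.0)

    def test_cross_segment_sd_of_temporal_means(self):
        # two samples; per-segment temporal means then SD across segments
        specs_a = [(i + 1, SUPER, 10 + 20 * i, 60.0) for i in range(10)]
        specs_a += [(50 + i, BASAL, 10 + 20 * i, 40.0) for i in range(10)]
        specs_b = [(i + 1, SUPER, 10 + 20 * i, 64.0) for i in range(10)]
        specs_b += [(50 + i, BASAL, 10 + 20 * i, 40.0) for i in range(10)]
        r = _result([_sample(240 * 25, specs_a), _sample(240 * 26, specs_b)])
        assert metrics.segment_thickness_sd(r, (20, 30)) == pytest.approx(0.0)


class TestTurnover:
    def _run_with_attrition(self):
        samples = []
        ids = list(range(1, 21))
        for day in range(0, 12):
            keep = ids[: max(0, 20 - 2 * day)]
            specs = [(i, WING, 100.0, 50.0) for i in keep] or \
                [(99, WING, 100.0, 50.0)]
            samples.append(_sample(day * 240, specs))
        return _result(samples)

    def test_all_alive_means_fraction_one(self):
        specs = [(i, WING, 100.0, 50.0) for i in range(1, 11)]
        r = _result([_sample(0, specs), _sample(240, specs)])
        ts, fr = metrics.survival_curve(r, "peripheral", 0.0)
        assert fr[0] == 1.0 and fr[-1] == 1.0
        day, frac = metrics.turnover_time(r, "peripheral", 0.0)
        assert day is None and frac == 1.0

    def test_turnover_day_bounds_extinction(self):
        r = self._run_with_attrition()
        day, frac = metrics.turnover_time(r, "peripheral", 0.0)
        assert day is not None and day <= 10.0
        assert frac <= 0.05

    def test_survival_curve_monotone_non_increasing(self, homeo_runs):
        """IDs never resurrect, so the surviving fraction can only fall."""
        for region in ("peripheral", "limbal"):
            ts, fr = metrics.survival_curve(homeo_runs[0], region, 20.0)
            assert np.all(np.diff(fr) <= 1e-12)


class TestRecovery:
    def _series_result(self, totals, thicks):
        samples = []
        for d, (n, th) in enumerate(zip(totals, thicks)):
            specs = [(1000 * d + i, BASAL, 100.0, 40.0) for i in range(n // 2)]
            specs += [(5000 + 1000 * d + i, SUPER, 100.0, 40.0 + th / 2.0)
                      for i in range(n - n // 2)]
            samples.append(_sample(d * 240, specs))
        return _result(samples)

    def test_series_never_leaving_band_recovers_at_zero(self):
        r = self._series_result([100] * 20, [25.0] * 20)
        rec, recur = metrics.recovery_time(r, injury_day=10.0)
        assert rec == 0.0 and recur == 0

    def test_reentry_at_day_four_detected(self):
        totals = [100] * 11 + [60, 70, 80, 85, 95, 100, 100, 100, 100]
        r = self._series_result(totals, [25.0] * 20)
        rec, recur = metrics.recovery_time(r, injury_day=10.0)
        assert rec == pytest.approx(5.0, abs=1.01)
        assert recur == 0

    def test_recurrence_counts_band_exits(self):
        totals = [100] * 11 + [60, 95, 100, 60, 100, 55, 100, 100, 100]
        r = self._series_result(totals, [25.0] * 20)
        rec, recur = metrics.recovery_time(r, injury_day=10.0)
        assert rec is not None
        assert recur == 2

    def test_recurrent_collapse_counter(self):
        days = np.arange(0, 30, 0.5)
        base = 30.0
        vals = np.full_like(days, 30.0)
        vals[(days > 10) & (days < 12)] = 5.0      # injury trough
        vals[(days > 16) & (days < 17)] = 10.0     # collapse 1
        vals[(days > 20) & (days < 21)] = 12.0     # collapse 2
        series = pd.Series(vals, index=days)
        first, n = metrics.recurrent_collapses(series, base, 10.0,
                                               reclosure=0.6, collapse=0.5)
        assert first is not None
        assert n == 2


class TestStability:
    def _counts_result(self, per_day_counts):
        samples = []
        for d, c in enumerate(per_day_counts):
            specs = []
            nid = 1
            for code, n in zip((STEM, BASAL, WING, SUPER), c):
                for i in range(n):
                    specs.append((nid, code, 100.0, 50.0))
                    nid += 1
            for frac in (0.25, 0.75):
                samples.append(_sample(int((d + frac) * 240), specs))
        return _result(samples)

    def test_fires_after_counts_plateau(self):
        ramp = [(5, 10, 20 + 4 * d, 20 + 2 * d) for d in range(10)]
        flat = [(5, 10, 60, 40)] * 20
        r = self._counts_result(ramp + flat)
        st = metrics.stability_time(r)
        assert st is not None
        assert 10.0 <= st <= 18.0

    def test_never_fires_on_steady_growth(self):
        ramp = [(5, 10 + 2 * d, 20 + 6 * d, 20 + 5 * d) for d in range(25)]
        r = self._counts_result(ramp)
        assert metrics.stability_time(r) is None
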