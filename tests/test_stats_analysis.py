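"""Statistical layer: deltas, percent change, t-tests, variance partition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import voltigen as vg
from voltigen.datasets import load_annual_mean_projections


@pytest.fixture(scope="module")
def delta_summary():
    return vg.table_deltas(load_annual_mean_projections())


class TestTableDeltas:
    def test_single_cell_subtraction(self, delta_summary):
        d = delta_summary.deltas
        cell = d[
            (d.location == "Junagadh") & (d.scenario == "A2") & (d.period == 2050) & (d.variable == "tmax")
        ]["delta"].iloc[0]
        assert cell == pytest.approx(33.68 - 29.93)

    def test_cooling_cell_is_negative(self, delta_summary):
        d = delta_summary.deltas
        cell = d[
            (d.location == "Junagadh") & (d.scenario == "B1") & (d.period == 2020) & (d.variable == "tmax")
        ]["delta"].iloc[0]
        assert cell == pytest.approx(-0.82)

    def test_baseline_vs_itself_is_zero(self):
        table = load_annual_mean_projections()
        base = table[table.scenario == "BL"]
        clone = pd.concat(
            [base]
            + [
                base.assign(scenario=s, period=p)
                for s in ("A2", "A1B", "B1")
                for p in (2020, 2050, 2080)
            ]
        )
        summary = vg.table_deltas(clone)
        assert np.allclose(summary.deltas["delta"], 0.0)

    def test_missing_cells_named(self):
        table = load_annual_mean_projections()
        broken = table[~((table.location == "Raichur") & (table.scenario == "A2"))]
        with pytest.raises(ValueError, match="Raichur"):
            vg.table_deltas(broken)


class TestPercentChangeGT:
    @pytest.mark.parametrize(
        "future, baseline, expected",
        [
            (24.0, 30.0, 20.0),
            (30.0, 30.0, 0.0),
            (24.88, 28.35, 12.24),  # printed summary cells, two-decimal rounding
            (36.0, 30.0, -20.0),  # lengthening is negative by sign convention
        ],
    )
    def test_examples(self, future, baseline, expected):
        assert vg.percent_change_gt(future, baseline) == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            vg.percent_change_gt(20.0, 0.0)


class TestTwoSampleT:
    def test_identical_samples(self):
        r = vg.two_sample_t_equal_var([4, 5, 6], [4, 5, 6])
        assert r.statistic == pytest.approx(0.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        r = vg.two_sample_t_equal_var([1, 2, 3], [3, 4, 5])
        assert r.statistic == pytest.approx(-2.449, abs=1e-3)
        assert r.df == 4

    def test_matches_direct_formula(self, rng):
        a = rng.normal(5, 1, 20)
        b = rng.normal(6, 2, 15)
        r = vg.two_sample_t_equal_var(a, b)
        pooled = ((19) * a.var(ddof=1) + (14) * b.var(ddof=1)) / 33
        t_direct = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / 20 + 1 / 15))
        assert r.statistic == pytest.approx(t_direct, rel=1e-12)
        assert r.df == 33

    def test_degenerate_baseline_uses_other_samples_variance(self, rng):
        fut = rng.normal(5.0, 0.2, 20)
        base = np.full(20, 4.0)  # zero-variance baseline replicates
        r = vg.two_sample_t_equal_var(fut, base)
        pooled = 19 * fut.var(ddof=1) / 38
        t_direct = (fut.mean() - 4.0) / np.sqrt(pooled * (2 / 20))
        assert r.statistic == pytest.approx(t_direct, rel=1e-12)
        assert r.degenerate is not None

    def test_both_degenerate_equal_means_undefined(self):
        r = vg.two_sample_t_equal_var([4.0] * 5, [4.0] * 5)
        assert np.isnan(r.statistic) and np.isnan(r.pvalue)
        assert r.degenerate is not None
        assert not r.significant_at_01

    def test_sample_too_small_rejected(self):
        with pytest.raises(ValueError):
            vg.two_sample_t_equal_var([1.0], [2.0, 3.0])

    @given(
        a=st.lists(st.floats(-10, 10), min_size=3, max_size=8),
        b=st.lists(st.floats(-10, 10), min_size=3, max_size=8),
    )
    def test_swapping_samples_negates_t(self, a, b):
        fwd = vg.two_sample_t_equal_var(a, b)
        rev = vg.two_sample_t_equal_var(b, a)
        if np.isfinite(fwd.statistic):
            assert rev.statistic == pytest.approx(-fwd.statistic, abs=1e-9)
            assert rev.pvalue == pytest.approx(fwd.pvalue, abs=1e-12)


def _balanced_table(rng, levels=(3, 4, 2, 2), reps=4, noise=1.0):
    names = ("location", "period", "model", "scenario")
    rows = []
    for combo in itertools.product(*[range(k) for k in levels]):
        for r in range(reps):
            rows.append(dict(zip(names, [f"L{c}" for c in combo]), replicate=r))
    df = pd.DataFrame(rows)
    df["response"] = rng.normal(0, noise, len(df))
    return df


class TestAnovaPartition:
    def test_two_by_two_closed_form(self):
        # additive effects of 2 and 1 on a balanced 2x2 grid: SS ratio 4:1,
        # no interaction
        rows = []
        for loc in (0, 1):
            for per in (0, 1):
                for r in range(5):
                    rows.append(
                        {
                            "location": f"L{loc}",
                            "period": f"P{per}",
                            "response": 2.0 * loc + 1.0 * per,
                        }
                    )
        df = pd.DataFrame(rows)
        vp = vg.anova_partition(
            df, "response", sources=("location", "period"), interactions=(("location", "period"),)
        )
        ss = vp.table.set_index("source")["ss"]
        assert ss["location"] / ss["period"] == pytest.approx(4.0)
        assert ss["location:period"] == pytest.approx(0.0, abs=1e-9)
        assert ss["others"] == pytest.approx(0.0, abs=1e-9)

    def test_ss_conservation_and_percent_sum(self, rng):
        df = _balanced_table(rng)
        vp = vg.anova_partition(df, "response")
        assert vp.table["ss"].sum() == pytest.approx(vp.total_ss, rel=1e-9)
        assert vp.table["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        assert ((vp.table["percent"] >= -1e-9) & (vp.table["percent"] <= 100 + 1e-9)).all()

    def test_source_order_invariance(self, rng):
        df = _balanced_table(rng)
        orders = [
            ("location", "period", "model", "scenario"),
            ("scenario", "model", "period", "location"),
            ("model", "location", "scenario", "period"),
        ]
        tables = [
            vg.anova_partition(df, "response", sources=o, check_order_invariance=False)
            .table.set_index("source")["ss"]
            for o in orders
        ]
        for other in tables[1:]:
            for src in ("location", "period", "model", "scenario"):
                assert other[src] == pytest.approx(tables[0][src], rel=1e-9)

    def test_unbalanced_design_rejected_with_counts(self, rng):
        df = _balanced_table(rng)
        df = df.iloc[:-1]  # knock one observation out of the last cell
        with pytest.raises(ValueError, match="unbalanced"):
            vg.anova_partition(df, "response")

    def test_constant_response_rejected(self, rng):
        df = _balanced_table(rng)
        df["response"] = 7.0
        with pytest.raises(ValueError, match="constant"):
            vg.anova_partition(df, "response")

    def test_single_level_source_rejected(self, rng):
        df = _balanced_table(rng)
        df["scenario"] = "only"
        with pytest.raises(ValueError, match="two levels"):
            vg.anova_partition(df, "response")

    def test_planted_ranking_recovered_across_seeds(self):
        """Recovered proportion ranking matches the planted ranking in >=95% of runs."""
        names = ("location", "period", "model", "scenario")
        levels = (4, 3, 3, 2)
        planted_sd = {"location": 3.0, "period": 2.0, "model": 1.0, "scenario": 0.5}
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(10_000 + seed)
            effects = {f: rng.normal(0, planted_sd[f], k) for f, k in zip(names, levels)}
            for f in names:
                effects[f] -= effects[f].mean()
            rows = []
            for combo in itertools.product(*[range(k) for k in levels]):
                base = sum(effects[f][c] for f, c in zip(names, combo))
                for r in range(5):
                    rows.append(
                        dict(zip(names, [f"L{c}" for c in combo]), response=base)
                    )
            df = pd.DataFrame(rows)
            df["response"] += rng.normal(0, 0.3, len(df))
            vp = vg.anova_partition(
                df, "response", interactions=(), check_order_invariance=False
            )
            rec = vp.table.set_index("source")["percent"]
            order = tuple(rec.loc[list(names)].sort_values(ascending=False).index)
            planted_order = tuple(
                pd.Series({f: np.sum(effects[f] ** 2) / len(effects[f]) for f in names})
                .sort_values(ascending=False)
                .index
            )
            hits += order == planted_order
        assert hits / n_runs >= 0.95
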