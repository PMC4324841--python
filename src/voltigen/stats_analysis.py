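"""Statistical layer: temperature deltas, percent change, t-tests, ANOVA.

Covers the study's four statistical products: (1) warming offsets of each
scenario × period relative to the 1975 baseline, summarised from the
published annual-mean table; (2) percent shortening of generation time
relative to baseline; (3) equal-variance two-sample t-tests of future
cells against baseline cells; (4) a balanced fixed-effects ANOVA whose
sums of squares, divided by the total SS, partition the variance of the
voltinism predictions among location, period, model, scenario and their
interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DeltaSummary",
    "TTestResult",
    "VariancePartition",
    "table_deltas",
    "percent_change_gt",
    "two_sample_t_equal_var",
    "anova_partition",
]

_N_LOCATIONS = 6
_SCENARIOS = ("A2", "A1B", "B1")
_FUTURE_PERIODS = (2020, 2050, 2080)
_VDF_YEAR = 2080


@dataclass
class DeltaSummary:
    """Scenario-minus-baseline temperature deltas plus headline aggregates.

    ``deltas`` has one row per (location, variable, scenario, period)
    with the delta in °C; aggregates follow the conventions of the source
    summary: extremes per variable over all future cells, and per-scenario
    very-distant-future means over all locations × both variables.
    """

    deltas: pd.DataFrame

    def _var(self, variable: str) -> pd.Series:
        return self.deltas.loc[self.deltas["variable"] == variable, "delta"]

    def max_delta(self, variable: str) -> float:
        return float(self._var(variable).max())

    def min_positive_delta(self, variable: str) -> float:
        pos = self._var(variable)
        pos = pos[pos > 0]
        return float(pos.min())

    def min_delta(self, variable: str) -> float:
        return float(self._var(variable).min())

    def vdf_mean_delta(self, scenario: str) -> float:
        """Mean of the 12 very-distant-future deltas (6 locations × 2 variables)."""
        sel = self.deltas[
            (self.deltas["scenario"] == scenario) & (self.deltas["period"] == _VDF_YEAR)
        ]
        return float(sel["delta"].mean())


def table_deltas(table: pd.DataFrame) -> DeltaSummary:
    """Compute scenario-minus-baseline deltas from an annual-means table.

    ``table`` must hold columns (location, variable, scenario, period,
    value) with one baseline row (scenario ``BL``) per location ×
    variable and nine future rows (3 scenarios × 3 periods); the packaged
    projection table has exactly this shape.

    Raises
    ------
    ValueError
        If any required cell is absent (missing cells are named).
    """
    required = {"location", "variable", "scenario", "period", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table lacks columns {sorted(required - set(table.columns))}")

    base = table[table["scenario"] == "BL"].set_index(["location", "variable"])["value"]
    locations = sorted(table["location"].unique())
    variables = sorted(table["variable"].unique())

    missing = [
        f"BL:{loc}/{var}" for loc in locations for var in variables if (loc, var) not in base.index
    ]
    fut = table[table["scenario"] != "BL"]
    have = set(map(tuple, fut[["location", "variable", "scenario", "period"]].to_numpy()))
    for loc in locations:
        for var in variables:
            for scen in _SCENARIOS:
                for per in _FUTURE_PERIODS:
                    if (loc, var, scen, per) not in have:
                        missing.append(f"{scen}/{per}:{loc}/{var}")
    if missing:
        raise ValueError("missing cells: " + ", ".join(missing[:12]))

    out = fut.copy()
    out["delta"] = out["value"].to_numpy() - base.loc[
        list(zip(out["location"], out["variable"]))
    ].to_numpy()
    return DeltaSummary(
        deltas=out[["location", "variable", "scenario", "period", "delta"]].reset_index(drop=True)
    )


def percent_change_gt(gt_future: float, gt_baseline: float) -> float:
    """Percent shortening of generation time relative to baseline.

    Positive values mean the future generation time is shorter.
    """
    if not gt_baseline > 0:
        raise ValueError("baseline generation time must be positive")
    return 100.0 * (gt_baseline - gt_future) / gt_baseline


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test outcome.

    ``degenerate`` records a zero-variance sample: with one degenerate
    sample the pooled variance is carried entirely by the other sample
    (the standard pooled formula does this naturally); with both samples
    degenerate and equal means, t is undefined and reported as NaN.
    """

    statistic: float
    df: int
    pvalue: float
    degenerate: str | None = None

    @property
    def significant_at_01(self) -> bool:
        return bool(np.isfinite(self.pvalue) and self.pvalue < 0.01)


def two_sample_t_equal_var(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TTestResult:
    """Two-sample t-test assuming equal variances (pooled variance).

    df = n_a + n_b - 2, two-sided p-value.  Samples of size < 2 raise;
    zero-variance samples are handled as documented on
    :class:`TTestResult` and flagged.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    df = len(a) + len(b) - 2
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    # Replicates that are identical by construction can acquire O(eps)
    # spread through float summation; treat such variances as zero so the
    # degenerate path is taken instead of a catastrophically-cancelled t.
    tol_a = (1e-9 * max(1.0, float(np.abs(a).max()))) ** 2
    tol_b = (1e-9 * max(1.0, float(np.abs(b).max()))) ** 2
    var_a = 0.0 if var_a < tol_a else var_a
    var_b = 0.0 if var_b < tol_b else var_b

    if var_a == 0.0 and var_b == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(np.nan, df, np.nan, degenerate="both samples have zero variance")
        # infinite separation relative to zero spread
        sign = np.sign(np.mean(a) - np.mean(b))
        return TTestResult(float(sign * np.inf), df, 0.0, degenerate="both samples have zero variance")

    if var_a == 0.0 or var_b == 0.0:
        pooled = ((len(a) - 1) * var_a + (len(b) - 1) * var_b) / df
        stat = (np.mean(a) - np.mean(b)) / np.sqrt(pooled * (1 / len(a) + 1 / len(b)))
        p = 2.0 * scipy.stats.t.sf(abs(stat), df)
        which = "first" if var_a == 0.0 else "second"
        return TTestResult(
            float(stat),
            df,
            float(p),
            degenerate=f"{which} sample has zero variance; pooled variance from the other sample",
        )

    stat, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(stat), df, float(p))


@dataclass
class VariancePartition:
    """ANOVA sums of squares and their shares of the total.

    ``table`` has one row per source (each main effect, each requested
    pairwise interaction, and ``others``, which pools every remaining
    interaction with the replicate residual) with columns
    ``(source, df, ss, percent)``; percents sum to 100.
    """

    table: pd.DataFrame
    total_ss: float
    response: str

    def percent(self, source: str) -> float:
        row = self.table.loc[self.table["source"] == source, "percent"]
        if row.empty:
            raise KeyError(f"no source named {source!r}")
        return float(row.iloc[0])


def _check_balance(table: pd.DataFrame, sources: Sequence[str]) -> None:
    counts = table.groupby(list(sources), observed=True).size()
    full = 1
    for s in sources:
        full *= table[s].nunique()
    if len(counts) != full or counts.nunique() != 1:
        summary = counts[counts != counts.max()]
        raise ValueError(
            "design is unbalanced across "
            + "×".join(sources)
            + f": expected {full} equally-filled cells, got counts "
            + str(dict(list(summary.items())[:8]) or dict(list(counts.items())[:8]))
        )


def anova_partition(
    table: pd.DataFrame,
    response: str,
    sources: Sequence[str] = ("location", "period", "model", "scenario"),
    interactions: Sequence[tuple[str, str]] = (("location", "period"),),
    check_order_invariance: bool = True,
) -> VariancePartition:
    """Partition response variance by factor via balanced fixed-effects ANOVA.

    Sums of squares are sequential (Type I) from an OLS fit; on the
    balanced designs this study uses, all SS types coincide and the
    decomposition is order-independent — asserted by refitting with the
    source order reversed when ``check_order_invariance`` is set.
    Everything not attributed to a listed main effect or interaction
    (higher-order interactions and replicate noise) is pooled into an
    ``others`` row, so the percents always total 100.

    Raises
    ------
    ValueError
        On unbalanced designs (cell counts reported), sources with fewer
        than two levels, or a constant response (partition undefined).
    """
    for s in sources:
        if s not in table.columns:
            raise ValueError(f"source column {s!r} not in table")
        if table[s].nunique() < 2:
            raise ValueError(f"source {s!r} needs at least two levels")
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    _check_balance(table, sources)

    y = table[response].to_numpy(float)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if total_ss <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        raise ValueError("response is (numerically) constant; variance partition undefined")

    df = table[[*sources, response]].copy()
    df = df.rename(columns={response: "_y"})

    def _fit(order: Sequence[str]) -> pd.DataFrame:
        terms = [f"C({s})" for s in order]
        terms += [f"C({a}):C({b})" for a, b in interactions]
        model = smf.ols("_y ~ " + " + ".join(terms), data=df).fit()
        return sm.stats.anova_lm(model, typ=1)

    aov = _fit(sources)
    if check_order_invariance:
        aov_rev = _fit(list(sources)[::-1])
        for s in sources:
            a = float(aov.loc[f"C({s})", "sum_sq"])
            b = float(aov_rev.loc[f"C({s})", "sum_sq"])
            if not np.isclose(a, b, rtol=1e-8, atol=1e-6 * total_ss):
                raise AssertionError(
                    f"sequential SS for {s} depend on order ({a} vs {b}); design not balanced?"
                )

    rows = []
    attributed = 0.0
    for s in sources:
        ss = float(aov.loc[f"C({s})", "sum_sq"])
        rows.append({"source": s, "df": int(aov.loc[f"C({s})", "df"]), "ss": ss})
        attributed += ss
    for a, b in interactions:
        key = f"C({a}):C({b})"
        ss = float(aov.loc[key, "sum_sq"])
        rows.append({"source": f"{a}:{b}", "df": int(aov.loc[key, "df"]), "ss": ss})
        attributed += ss
    resid_ss = total_ss - attributed
    resid_df = int(aov.loc["Residual", "df"])
    rows.append({"source": "others", "df": resid_df, "ss": resid_ss})

    out = pd.DataFrame(rows)
    out["percent"] = 100.0 * out["ss"] / total_ss
    return VariancePartition(table=out, total_ss=total_ss, response=response)
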