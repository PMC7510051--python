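import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fungalscape.diversity import (
    depth_residual_richness,
    group_metrics,
    group_proportions,
    group_richness,
    ecm_lineage_count,
    hellinger,
    logratio_pct,
    rarefaction_curve,
    richness,
    shannon,
)
from fungalscape.errors import FungalscapeError, QCError
from fungalscape.io import OtuTable


class TestLogratio:
    @pytest.mark.parametrize(
        "pct,expected",
        [(0.0, -4.0), (50.0, 0.0), (100.0, 4.0)],
    )
    def test_printed_anchors(self, pct, expected):
        assert logratio_pct(pct) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry(self, p):
        assert logratio_pct(p) == pytest.approx(-logratio_pct(100.0 - p), abs=1e-9)

    def test_vectorized_over_frames(self):
        df = pd.DataFrame({"a": [0.0, 50.0], "b": [100.0, 25.0]})
        out = logratio_pct(df)
        assert out.shape == df.shape
        assert out.loc[0, "a"] == pytest.approx(-4.0, abs=5e-4)

    def test_domain_error(self):
        with pytest.raises(FungalscapeError):
            logratio_pct(101.0)
        with pytest.raises(FungalscapeError):
            logratio_pct(-0.5)


class TestHellinger:
    def test_row_values(self):
        t = OtuTable(pd.DataFrame([[1, 0, 3]], index=["s"], columns=list("abc")))
        out = hellinger(t)
        assert np.allclose(out.loc["s"], [0.5, 0.0, math.sqrt(0.75)])

    def test_rows_are_unit_vectors(self, small_survey):
        out = hellinger(small_survey.table)
        assert np.allclose((out**2).sum(axis=1), 1.0)

    def test_zero_total_row_rejected(self):
        t = OtuTable(pd.DataFrame([[0, 0]], index=["s"], columns=["a", "b"]))
        with pytest.raises(QCError):
            hellinger(t)


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([10, 10, 10, 10], math.log(4)),
            ([5], 0.0),
            # oracle: direct summation of -sum p ln p for [1,2,3,4]
            ([1, 2, 3, 4], -sum(c / 10 * math.log(c / 10) for c in (1, 2, 3, 4))),
        ],
    )
    def test_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-9)

    def test_frozen_oracle_value(self):
        assert shannon([1, 2, 3, 4]) == pytest.approx(1.27985, abs=1e-4)

    def test_zero_sample_rejected(self):
        with pytest.raises(QCError):
            shannon([0, 0])


class TestDepthResiduals:
    def test_residuals_sum_to_zero(self, small_survey):
        table = small_survey.table
        depths = table.sample_totals()
        keep = depths[depths > 0].index
        rich = richness(table).loc[keep]
        out = depth_residual_richness(rich, depths.loc[keep])
        assert abs(out["residual"].sum()) < 1e-6 * len(out)

    def test_constant_depth_fallback_is_mean_centering(self):
        rich = pd.Series([10.0, 20.0, 33.0])
        out = depth_residual_richness(rich, pd.Series([1000.0] * 3))
        assert np.allclose(out["residual"], rich - rich.mean())

    def test_matches_independent_two_regression_oracle(self):
        depths = np.array([1000.0, 2000.0, 4000.0, 2500.0, 800.0])
        rich = np.array([100.0, 130.0, 150.0, 120.0, 95.0])

        def ols_resid(x, y):
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            return y - X @ beta

        expected = 0.5 * (ols_resid(np.sqrt(depths), rich) + ols_resid(np.log(depths), rich))
        out = depth_residual_richness(rich, depths)
        assert np.allclose(out["residual"], expected, atol=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        depths = rng.uniform(500, 5000, 30)
        rich = rng.uniform(50, 200, 30)
        a = depth_residual_richness(rich, depths)["residual"]
        b = depth_residual_richness(rich + 77.0, depths)["residual"]
        assert np.allclose(a, b, atol=1e-8)


def enumeration_expected_richness(counts, m):
    """Exhaustive oracle: average richness over all C(N, m) subsets of reads."""
    reads = []
    for i, c in enumerate(counts):
        reads.extend([i] * c)
    vals = [len(set(combo)) for combo in itertools.combinations(range(len(reads)), m)]
    species = [reads[i] for i in range(len(reads))]
    vals = [
        len({species[i] for i in combo})
        for combo in itertools.combinations(range(len(reads)), m)
    ]
    return sum(vals) / len(vals)


class TestRarefaction:
    def test_enumeration_oracle_small_fixture(self):
        t = OtuTable(pd.DataFrame([[2, 1, 1]], index=["s"], columns=list("abc")))
        curve = rarefaction_curve(t, [2])
        assert curve["expected_richness"][0] == pytest.approx(
            enumeration_expected_richness([2, 1, 1], 2), abs=1e-12
        )
        assert curve["expected_richness"][0] == pytest.approx(11 / 6, abs=1e-12)

    def test_boundary_depths(self):
        t = OtuTable(pd.DataFrame([[2, 1, 1]], index=["s"], columns=list("abc")))
        curve = rarefaction_curve(t, [1, 4])
        assert curve["expected_richness"][0] == pytest.approx(1.0)
        assert curve["expected_richness"][1] == pytest.approx(3.0)

    def test_monte_carlo_oracle_five_otus(self):
        counts = np.array([40, 25, 10, 4, 1])
        t = OtuTable(pd.DataFrame([counts], index=["s"], columns=list("abcde")))
        m = 20
        analytic = rarefaction_curve(t, [m])["expected_richness"][0]
        rng = np.random.default_rng(123)
        pool = np.repeat(np.arange(5), counts)
        draws = np.array([
            len(np.unique(rng.choice(pool, size=m, replace=False)))
            for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(analytic - draws.mean()) < 3 * se

    def test_monotone_and_bounded(self, small_survey):
        t = small_survey.table
        total = int(t.counts.to_numpy().sum())
        depths = [1, 10, 100, 1000, total]
        curve = rarefaction_curve(t, depths)
        vals = curve["expected_richness"].to_numpy()
        assert (np.diff(vals) >= -1e-9).all()
        assert vals[-1] <= t.shape[1]

    def test_singleton_exclusion_lowers_curve(self, small_survey):
        t = small_survey.table
        inc = rarefaction_curve(t, [500], singleton_mode="include")
        exc = rarefaction_curve(t, [500], singleton_mode="exclude")
        assert exc["expected_richness"][0] <= inc["expected_richness"][0]

    def test_depth_beyond_total_rejected(self):
        t = OtuTable(pd.DataFrame([[2, 1]], index=["s"], columns=["a", "b"]))
        with pytest.raises(FungalscapeError):
            rarefaction_curve(t, [10])


class TestGroupMetrics:
    def test_lineage_count(self):
        counts = pd.DataFrame(
            [[5, 3, 2, 1], [0, 0, 4, 1]], index=["s1", "s2"],
            columns=["o1", "o2", "o3", "o4"],
        )
        assignments = pd.DataFrame(
            {
                "guild": ["EcM", "EcM", "EcM", "litter saprotroph"],
                "ecm_lineage": ["/inocybe", "/russula-lactarius", "/inocybe", ""],
                "exploration_type": ["short-distance-delicate", "contact",
                                     "short-distance-delicate", ""],
            },
            index=["o1", "o2", "o3", "o4"],
        )
        t = OtuTable(counts)
        assert ecm_lineage_count(t, assignments).tolist() == [2, 1]

    def test_ecm_proportion_and_logratio(self):
        counts = pd.DataFrame([[40, 60]], index=["s"], columns=["ecm", "sap"])
        assignments = pd.DataFrame(
            {"guild": ["EcM", "litter saprotroph"], "ecm_lineage": ["/inocybe", ""],
             "exploration_type": ["contact", ""]},
            index=["ecm", "sap"],
        )
        metrics = group_metrics(OtuTable(counts), assignments)
        assert metrics["guild_proportion"].loc["s", "EcM"] == pytest.approx(0.40)
        lr = logratio_pct(40.0)
        assert lr == pytest.approx(math.log10(40.01 / 60.01), abs=1e-12)

    def test_all_unassigned_gives_zero_proportions(self, tiny_table):
        assignments = pd.DataFrame(
            {"guild": ["unassigned"] * 3, "ecm_lineage": [""] * 3,
             "exploration_type": [""] * 3},
            index=tiny_table.otu_ids,
        )
        metrics = group_metrics(tiny_table, assignments)
        assert metrics["guild_proportion"].empty or (
            metrics["guild_proportion"].to_numpy() == 0
        ).all()

    def test_proportions_sum_below_one(self, small_survey):
        props = group_proportions(small_survey.table, small_survey.assignments["guild"])
        assert (props.sum(axis=1) <= 1.0 + 1e-9).all()
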