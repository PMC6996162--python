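"""Rank statistics, reference ranges and the endpoint-comparison harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from abrkit import synthetic_cochlea as sc
from abrkit.abr_io import ContractError
from abrkit.group_statistics import (
    bonferroni_alpha,
    check_normality,
    compare_endpoints,
    dunns_vs_control,
    format_alpha,
    kruskal_wallis,
    reference_range,
    threshold_endpoint_table,
)


from oracles import brute_force_h as _brute_force_h
from oracles import brute_force_q as _brute_force_q


class TestKruskalWallis:
    def test_two_group_hand_value(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27.0 / 7.0)  # 3.857...
        assert df == 1

    def test_identical_groups_h_zero(self):
        h, df, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_agrees_with_brute_force_ranks_on_tie_heavy_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = rng.integers(2, 4)
            sizes = rng.integers(1, 5, k)
            if sizes.sum() < 3:
                continue
            vals = rng.integers(0, 4, sizes.sum()).astype(float)
            groups = np.split(vals, np.cumsum(sizes)[:-1])
            h, _, _ = kruskal_wallis(groups)
            assert h == pytest.approx(_brute_force_h([g.tolist() for g in groups]))

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
            h, df, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestDunn:
    def test_hand_value_two_groups(self):
        (q, p), = dunns_vs_control([[1, 2, 3, 4], [5, 6, 7, 8]], 0, 1)
        assert q == pytest.approx(4.0 / np.sqrt(3.0))
        assert p == pytest.approx(2.0 * sps.norm.sf(4.0 / np.sqrt(3.0)))

    def test_group_identical_to_control(self):
        (q, p), = dunns_vs_control([[1, 2, 3], [1, 2, 3]], 0)
        assert q == 0.0 and p == 1.0

    def test_q_monotone_in_shift(self):
        control = list(range(8))
        qs = []
        for shift in (0.0, 2.0, 5.0, 10.0, 50.0):
            (q, _), = dunns_vs_control(
                [control, [v + shift for v in control]], 0
            )
            qs.append(q)
        assert qs == sorted(qs)

    def test_agrees_with_brute_force_on_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            sizes = rng.integers(2, 5, 3)
            vals = rng.integers(0, 4, sizes.sum()).astype(float)
            groups = [g.tolist() for g in np.split(vals, np.cumsum(sizes)[:-1])]
            got = [q for q, _ in dunns_vs_control(groups, 0)]
            assert got == pytest.approx(_brute_force_q(groups, 0))

    def test_p_adjustment_monotone_in_family_size(self):
        groups = [[1, 2, 3, 4], [3, 4, 5, 6]]
        ps = [dunns_vs_control(groups, 0, m)[0][1] for m in (1, 2, 4, 12)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))


class TestBonferroni:
    def test_printed_alphas(self):
        assert format_alpha(bonferroni_alpha(0.05, 12)) == "0.00417"
        assert format_alpha(bonferroni_alpha(0.05, 4)) == "0.0125"

    def test_identity_and_errors(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        with pytest.raises(ContractError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ContractError):
            bonferroni_alpha(1.5, 4)


class TestReferenceRange:
    def test_inclusive_percentiles_of_1_to_100(self):
        rr = reference_range(np.arange(1.0, 101.0))
        assert rr.lo == pytest.approx(3.475)
        assert rr.hi == pytest.approx(97.525)
        assert rr.n == 100

    def test_constant_vector(self):
        rr = reference_range([7.0] * 10)
        assert rr.lo == rr.hi == rr.mean == 7.0
        assert rr.sd == 0.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ContractError):
            reference_range([1.0])

    def test_coverage_property(self):
        """A 2.5-97.5 band built from n = 37 draws contains 35/37 of the
        sample itself (the interpolated bounds sit just inside the
        extremes).  Mean coverage of fresh draws matches the order-
        statistic expectation (j_hi - j_lo)/(n+1) ~= 0.90 - the usual
        undercoverage of an empirical percentile band at small n."""
        rng = np.random.default_rng(2)
        fresh_coverage = []
        for _ in range(200):
            x = rng.normal(size=37)
            rr = reference_range(x)
            inside = np.sum((x >= rr.lo) & (x <= rr.hi))
            assert inside == 35
            new = rng.normal(size=500)
            fresh_coverage.append(np.mean((new >= rr.lo) & (new <= rr.hi)))
        # interpolated bound positions 1.9 and 36.1 of 37: E[F] = j/(n+1)
        expected = (36.1 - 1.9) / 38.0
        assert np.mean(fresh_coverage) == pytest.approx(expected, abs=0.02)


class TestNormality:
    def test_bimodal_sample_strongly_rejected(self):
        x = [0.0] * 10 + [10.0] * 10
        # add jitter: Shapiro-Wilk needs non-degenerate values
        rng = np.random.default_rng(0)
        x = np.array(x) + rng.normal(0, 0.01, 20)
        assert check_normality(x) < 0.01

    def test_sample_size_contract(self):
        with pytest.raises(ContractError):
            check_normality([1.0, 2.0])

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        rejections = sum(
            check_normality(rng.normal(size=50)) < 0.05 for _ in range(1000)
        )
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)


class TestCompareEndpoints:
    def _table(self, groups):
        rows = []
        for g, values in groups.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "endpoint": "abr_threshold",
                        "condition": "click",
                        "group": g,
                        "mouse_id": f"{g}_{i}",
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_shifted_group_flagged_on_simulated_cohort(self):
        shift = {f: 30.0 for f in ("24kHz", "30kHz", "36kHz", "42kHz")}
        arch = sc.simulate_cohort(
            6,
            {"wildtype": sc.GenotypeEffect(),
             "mutant": sc.GenotypeEffect(threshold_shift_dB=shift)},
            "thresholds_only",
            seed=42,
        )
        extra = sc.simulate_cohort(
            31, {"wtB": sc.GenotypeEffect()}, "thresholds_only", seed=43
        )
        table = pd.concat(
            [
                threshold_endpoint_table(arch),
                threshold_endpoint_table(extra).assign(group="wildtype"),
            ]
        )
        results = compare_endpoints(table, "wildtype", family_size=12)
        flags = [
            c.significant for r in results for c in r.comparisons if c.group == "mutant"
        ]
        assert any(flags)

    def test_null_split_halves_not_significant(self):
        rng = np.random.default_rng(8)
        values = rng.normal(30.0, 5.0, 20)
        table = self._table({"a": values[:10], "b": values[10:]})
        results = compare_endpoints(table, "a", family_size=4)
        assert not any(c.significant for r in results for c in r.comparisons)

    def test_absent_group_reported_not_dropped(self):
        table = self._table({"wildtype": [1, 2, 3, 4], "mut": [2, 3, 4, 5]})
        other = table.assign(endpoint="recovery_tau")
        table = pd.concat([table, other[other["group"] == "wildtype"]])
        results = compare_endpoints(table, "wildtype", mode="pooled")
        tau_rows = [r for r in results if r.endpoint == "recovery_tau"]
        # mutant absent from the tau endpoint: comparison reported as NaN
        assert len(tau_rows) == 1
        assert any(np.isnan(c.q) for c in tau_rows[0].comparisons)

    def test_missing_control_rejected(self):
        table = self._table({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ContractError):
            compare_endpoints(table, "wildtype")
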