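import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import diurnalmeth as dm
from diurnalmeth.differential import (
    adjust_fdr,
    call_dmcs,
    call_dmrs,
    dmc_test,
    dmr_summary,
    fisher_exact_two_sided,
    pool_group_counts,
)


def fisher_oracle_exact(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational two-sided Fisher p by hypergeometric enumeration.

    All tables sharing the margins have the common denominator
    C(m+n, k); summing the integer numerators with pmf <= observed is an
    exact tie-safe computation.
    """
    m, n, k = a + b, c + d, a + c
    obs = math.comb(m, a) * math.comb(n, c)
    total = 0
    for x in range(max(0, k - n), min(k, m) + 1):
        num = math.comb(m, x) * math.comb(n, k - x)
        if num <= obs:
            total += num
    return float(Fraction(total, math.comb(m + n, k)))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Direct Benjamini–Hochberg step-up."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


class TestFisher:
    def test_identical_margins_p_one(self):
        p, diff = dmc_test((10, 10), (10, 10))
        assert p == pytest.approx(1.0)
        assert diff == 0.0

    def test_extreme_table(self):
        p, diff = dmc_test((20, 0), (0, 20))
        assert diff == pytest.approx(-1.0)
        assert p == pytest.approx(fisher_oracle_exact(20, 0, 0, 20), abs=1e-12)

    def test_half_shift_table(self):
        p, diff = dmc_test((15, 5), (5, 15))
        assert diff == pytest.approx(-0.5)
        assert p == pytest.approx(fisher_oracle_exact(15, 5, 5, 15), abs=1e-12)

    def test_matches_exact_enumeration_all_small_tables(self):
        """Every 2x2 table with total <= 40 agrees with the exact oracle."""
        tables = [
            (a, b, c, d)
            for total in range(2, 41)
            for a in range(total + 1)
            for b in range(total - a + 1)
            for c in range(total - a - b + 1)
            for d in [total - a - b - c]
            if (a + b) > 0 and (c + d) > 0
        ]
        arr = np.array(tables)
        p_impl = fisher_exact_two_sided(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
        p_oracle = np.array([fisher_oracle_exact(*t) for t in tables])
        np.testing.assert_allclose(p_impl, p_oracle, atol=1e-10, rtol=0)

    def test_cross_check_against_scipy(self, rng):
        """Independent library route on random larger tables."""
        tabs = rng.integers(0, 60, size=(300, 4))
        tabs[:, 0] += 1
        tabs[:, 2] += 1
        p_impl = fisher_exact_two_sided(*tabs.T)
        for (a, b, c, d), p in zip(tabs, p_impl):
            p_sp = sps.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(p_sp, rel=1e-6, abs=1e-12)

    def test_corrected_diff_uses_nonconversion(self):
        _, diff = dmc_test((505, 495), (10, 990), r=0.01)
        assert diff == pytest.approx(0.0 - 0.5)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            dmc_test((0, 0), (1, 1))


class TestAdjustFdr:
    def test_hand_computation(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_degenerate(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 10_000))
            p = rng.uniform(size=min(n, 200))  # mix of lengths, cheap oracle
            np.testing.assert_allclose(adjust_fdr(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestPooling:
    def test_counts_add(self):
        s1 = pd.DataFrame(
            [["c", 10, "+", "CG", 3, 1]],
            columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
        )
        s2 = pd.DataFrame(
            [["c", 10, "+", "CG", 2, 4]],
            columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
        )
        pooled = pool_group_counts({"a": s1, "b": s2}, ["a", "b"])
        assert pooled[["n_meth", "n_unmeth"]].iloc[0].tolist() == [5, 5]

    def test_missing_position_contributes_zero(self):
        s1 = pd.DataFrame(
            [["c", 10, "+", "CG", 3, 1], ["c", 20, "+", "CHH", 1, 1]],
            columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
        )
        s2 = s1.iloc[:1]
        pooled = pool_group_counts({"a": s1, "b": s2}, ["a", "b"])
        row20 = pooled[pooled["pos"] == 20]
        assert row20[["n_meth", "n_unmeth"]].iloc[0].tolist() == [1, 1]

    def test_conservation(self, small_methylome):
        sample_sites, *_ = small_methylome
        members = list(sample_sites)[:3]
        pooled = pool_group_counts(sample_sites, members)
        assert pooled["n_meth"].sum() == sum(
            sample_sites[s]["n_meth"].sum() for s in members
        )

    def test_duplicate_membership_rejected(self, small_methylome):
        sample_sites, *_ = small_methylome
        s = list(sample_sites)[0]
        with pytest.raises(ValueError, match="duplicate"):
            pool_group_counts(sample_sites, [s, s])


def _pooled_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


class TestCallDmcs:
    def test_thresholds_gate_jointly(self):
        # one strong true difference among sparse background
        a = _pooled_frame([["c", p, "+", "CG", 2, 38] for p in range(1, 40)])
        b_rows = [["c", p, "+", "CG", 2, 38] for p in range(1, 39)]
        b_rows.append(["c", 39, "+", "CG", 38, 2])
        b = _pooled_frame(b_rows)
        dmcs, stats = call_dmcs(a, b, "G2vG1")
        assert stats["n_tested"] == 39
        assert list(dmcs["pos"]) == [39]
        assert dmcs["direction"].iloc[0] == "hyper"

    def test_effect_size_gate_rejects_small_diff(self):
        # significant but |diff| <= 0.2 must not be retained
        a = _pooled_frame([["c", 1, "+", "CG", 100, 900]])
        b = _pooled_frame([["c", 1, "+", "CG", 250, 750]])
        dmcs, _ = call_dmcs(a, b, "cmp", alpha=0.5)
        assert len(dmcs) == 0

    def test_zero_coverage_positions_skipped_not_error(self):
        a = _pooled_frame([["c", 1, "+", "CG", 5, 5], ["c", 2, "+", "CG", 0, 0]])
        b = _pooled_frame([["c", 1, "+", "CG", 5, 5], ["c", 2, "+", "CG", 4, 4]])
        _, stats = call_dmcs(a, b, "cmp")
        assert stats["n_tested"] == 1
        assert stats["n_skipped_zero_coverage"] == 1

    def test_null_simulation_respects_alpha(self, rng):
        n = 100_000
        cov_a = rng.poisson(30, n).clip(min=1)
        cov_b = rng.poisson(30, n).clip(min=1)
        ma = rng.binomial(cov_a, 0.3)
        mb = rng.binomial(cov_b, 0.3)
        a = _pooled_frame(
            list(zip(["c"] * n, range(1, n + 1), "+" * n, ["CG"] * n, ma, cov_a - ma))
        )
        b = _pooled_frame(
            list(zip(["c"] * n, range(1, n + 1), "+" * n, ["CG"] * n, mb, cov_b - mb))
        )
        dmcs, stats = call_dmcs(a, b, "null")
        assert stats["n_significant"] <= 0.05 * n * 0.05  # BH leaves ~nothing under the null


def _dmc_frame(positions, directions, comparison="G2vG1", context="CHH"):
    return pd.DataFrame(
        {
            "chrom": "c",
            "pos": positions,
            "strand": "+",
            "context": context,
            "level_a": 0.1,
            "level_b": 0.5,
            "diff": [0.4 if d == "hyper" else -0.4 for d in directions],
            "p": 1e-6,
            "q": 1e-4,
            "direction": directions,
            "comparison": comparison,
        }
    )


def _background(positions, level_a, level_b, cov=50):
    a = _pooled_frame(
        [["c", p, "+", "CHH", int(level_a * cov), cov - int(level_a * cov)] for p in positions]
    )
    b = _pooled_frame(
        [["c", p, "+", "CHH", int(level_b * cov), cov - int(level_b * cov)] for p in positions]
    )
    return a, b


def dmr_brute_oracle(positions, directions, min_dmcs=3, max_gap=300):
    """Enumerate maximal same-direction clusters with all gaps < max_gap."""
    clusters = []
    cur = [0]
    for i in range(1, len(positions)):
        if positions[i] - positions[i - 1] < max_gap and directions[i] == directions[i - 1]:
            cur.append(i)
        else:
            clusters.append(cur)
            cur = [i]
    clusters.append(cur)
    return [
        (positions[c[0]], positions[c[-1]], len(c)) for c in clusters if len(c) >= min_dmcs
    ]


class TestCallDmrs:
    def test_three_dmc_cluster_becomes_dmr(self):
        dmcs = _dmc_frame([1000, 1150, 1400], ["hyper"] * 3)
        a, b = _background(range(990, 1411, 10), 0.1, 0.5)
        dmrs = call_dmrs(dmcs, a, b)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert (row.start, row.end, row.length, row.n_dmc) == (1000, 1400, 401, 3)
        assert row.direction == "hyper"
        assert row.n_chh == 3
        assert dmr_brute_oracle([1000, 1150, 1400], ["hyper"] * 3) == [(1000, 1400, 3)]

    def test_min_dmc_gate(self):
        dmcs = _dmc_frame([1000, 1150], ["hyper"] * 2)
        a, b = _background(range(990, 1160, 10), 0.1, 0.5)
        assert len(call_dmrs(dmcs, a, b)) == 0

    def test_gap_gate_at_300(self):
        dmcs = _dmc_frame([1000, 1150, 1550], ["hyper"] * 3)
        a, b = _background(range(990, 1560, 10), 0.1, 0.5)
        assert len(call_dmrs(dmcs, a, b)) == 0
        assert dmr_brute_oracle([1000, 1150, 1550], ["hyper"] * 3) == []

    def test_direction_change_breaks_cluster(self):
        dmcs = _dmc_frame(
            [1000, 1100, 1200, 1300, 1400, 1500], ["hyper"] * 3 + ["hypo"] * 3
        )
        a, b = _background(range(990, 1510, 10), 0.1, 0.5)
        dmrs = call_dmrs(dmcs, a, b)
        # region diff is computed from the background (all hyper): only the
        # hyper cluster survives the region-diff sign matching its DMCs
        assert (dmrs["direction"] == "hyper").all()
        assert dmr_brute_oracle(
            [1000, 1100, 1200, 1300, 1400, 1500], ["hyper"] * 3 + ["hypo"] * 3
        ) == [(1000, 1200, 3), (1300, 1500, 3)]

    def test_region_diff_gate_uses_all_cytosines(self):
        # DMCs say +0.4 but the surrounding span is flat: pooled diff ~ 0
        dmcs = _dmc_frame([1000, 1150, 1300], ["hyper"] * 3)
        positions = list(range(900, 1401, 2))
        a, b = _background(positions, 0.3, 0.3)
        assert len(call_dmrs(dmcs, a, b)) == 0

    def test_unsorted_input_rejected(self):
        dmcs = _dmc_frame([1400, 1000, 1150], ["hyper"] * 3)
        a, b = _background(range(990, 1410, 10), 0.1, 0.5)
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(dmcs, a, b)

    def test_monotonicity_in_min_diff(self, small_methylome, design):
        sample_sites, controls, truth, _ = small_methylome
        r = dm.pipeline.pooled_nonconversion_rate(controls)
        _, dmrs_01, _ = dm.pipeline.run_differential_pipeline(
            sample_sites, design, r=r, min_diff_dmr=0.1
        )
        _, dmrs_03, _ = dm.pipeline.run_differential_pipeline(
            sample_sites, design, r=r, min_diff_dmr=0.3
        )
        assert len(dmrs_03) <= len(dmrs_01)

    def test_emitted_dmrs_satisfy_all_constraints(self, small_methylome, design):
        sample_sites, controls, *_ = small_methylome
        r = dm.pipeline.pooled_nonconversion_rate(controls)
        dmcs, dmrs, _ = dm.pipeline.run_differential_pipeline(sample_sites, design, r=r)
        assert len(dmrs) > 0
        for row in dmrs.itertuples(index=False):
            assert row.n_dmc >= 3
            assert abs(row.diff) > 0.1
            members = dmcs[
                (dmcs["comparison"] == row.comparison)
                & (dmcs["chrom"] == row.chrom)
                & dmcs["pos"].between(row.start, row.end)
                & (dmcs["direction"] == row.direction)
            ]
            gaps = np.diff(sorted(members["pos"].unique()))
            assert (gaps < 300).all()


class TestDmrSummary:
    def test_ratio_arithmetic(self):
        dmrs = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(43) * 1000 + 1,
                "end": np.arange(43) * 1000 + 500,
                "comparison": "G2vG1",
                "n_dmc": 3,
                "diff": [-0.3] * 23 + [0.3] * 20,
                "direction": ["hypo"] * 23 + ["hyper"] * 20,
                "n_cg": 0,
                "n_chg": 0,
                "n_chh": 3,
                "n_mc": 5,
                "length": 500,
            }
        )
        dmcs = _dmc_frame([1000, 1150, 1400], ["hyper"] * 3)
        summary = dmr_summary(dmrs, dmcs)
        overall = summary[summary["comparison"] == "overall"].iloc[0]
        assert overall.hypo_hyper_ratio == pytest.approx(23 / 20)
        assert overall.hypo_hyper_ratio == pytest.approx(1.15)

    def test_context_percentages_sum_to_100(self, small_methylome, design):
        sample_sites, controls, *_ = small_methylome
        r = dm.pipeline.pooled_nonconversion_rate(controls)
        dmcs, dmrs, _ = dm.pipeline.run_differential_pipeline(sample_sites, design, r=r)
        summary = dmr_summary(dmrs, dmcs)
        overall = summary[summary["comparison"] == "overall"].iloc[0]
        assert overall.pct_cg + overall.pct_chg + overall.pct_chh == pytest.approx(100.0)

    def test_empty_input_zero_filled(self):
        summary = dmr_summary(
            pd.DataFrame(columns=dm.differential.DMR_COLUMNS),
            _dmc_frame([], []),
        )
        assert summary["n_dmr"].iloc[-1] == 0

    def test_planted_chh_only_composition(self, small_genome, design):
        genome, genes, tes = small_genome
        plants = dm.synthetic_data.plan_dmr_regions(
            genome, design, n_regions=3, delta=0.5, contexts=("CHH",), seed=3
        )
        sample_sites, controls, truth = dm.synthetic_data.simulate_methylome(
            genome, genes, tes, design, planted_dmrs=plants, coverage_mean=40, seed=4
        )
        r = dm.pipeline.pooled_nonconversion_rate(controls)
        dmcs, dmrs, _ = dm.pipeline.run_differential_pipeline(sample_sites, design, r=r)
        summary = dmr_summary(dmrs, dmcs)
        overall = summary[summary["comparison"] == "overall"].iloc[0]
        assert overall.pct_chh > 95.0
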