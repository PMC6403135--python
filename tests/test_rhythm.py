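import numpy as np
import pandas as pd
import pytest

import diurnalmeth as dm
from diurnalmeth.io_formats import GeneModel
from diurnalmeth.rhythm import (
    ddct_fold_change,
    detect_rhythmic_genes,
    gene_region_methylation,
    integrate_dmr_rhythm,
    methylation_expression_correlation,
    region_interval,
)


def _expr(design, rows: dict):
    return pd.DataFrame(rows, columns=design.samples).T.pipe(
        lambda d: pd.DataFrame(d.values.T, index=list(rows), columns=design.samples)
    )


class TestRegionWindows:
    def test_promoter_500_plus(self):
        g = GeneModel("g", "c", "+", 5001, 8000)
        assert region_interval(g, "promoter_500") == (4501, 5000)

    def test_downstream_500_minus_is_strand_aware(self):
        g = GeneModel("g", "c", "-", 5001, 8000)
        assert region_interval(g, "downstream_500") == (4501, 5000)

    def test_gene_body(self):
        g = GeneModel("g", "c", "-", 5001, 8000)
        assert region_interval(g, "gene_body") == (5001, 8000)

    def test_unknown_region_rejected(self):
        g = GeneModel("g", "c", "+", 5001, 8000)
        with pytest.raises(ValueError, match="region"):
            region_interval(g, "promoter_750")

    def test_pooled_level(self):
        g = GeneModel("g", "c", "+", 10, 30)
        sites = pd.DataFrame(
            [["c", 12, "+", "CG", 3, 1], ["c", 20, "-", "CHH", 1, 3]],
            columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
        )
        out = gene_region_methylation({"G1": sites}, [g], "gene_body")
        assert out["level"].iloc[0] == pytest.approx(0.5)

    def test_uncovered_gene_is_nan(self):
        g = GeneModel("g", "c", "+", 1000, 2000)
        sites = pd.DataFrame(
            [["c", 12, "+", "CG", 3, 1]],
            columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
        )
        out = gene_region_methylation({"G1": sites}, [g], "gene_body")
        assert np.isnan(out["level"].iloc[0])


class TestRhythmDetection:
    def test_noiseless_cosine_recovered_exactly(self, design):
        t = np.array([design.timepoints[s] for s in design.samples])
        y = 5 + 2 * np.cos(2 * np.pi * (t - 8) / 24)
        expr = pd.DataFrame([2.0**y], index=["gA"], columns=design.samples)
        fit = detect_rhythmic_genes(expr, design.timepoints, log_transform=False).iloc[0]
        # log_transform=False: feed the log2 scale directly
        expr_log = pd.DataFrame([y], index=["gA"], columns=design.samples)
        fit = detect_rhythmic_genes(
            expr_log, design.timepoints, log_transform=False
        ).iloc[0]
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.phase == pytest.approx(8.0, abs=1e-9)
        assert fit.mesor == pytest.approx(5.0, abs=1e-9)
        assert fit.p < 1e-12

    def test_constant_gene_not_rhythmic(self, design):
        expr = pd.DataFrame(
            [[7.0] * 9, [0.0] * 9], index=["flat", "zero"], columns=design.samples
        )
        fits = detect_rhythmic_genes(expr, design.timepoints)
        assert (fits["p"] == 1.0).all()
        assert not fits["rhythmic"].any()

    def test_too_few_timepoints_rejected(self, design):
        expr = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=design.samples[:4])
        with pytest.raises(ValueError, match="5"):
            detect_rhythmic_genes(expr, design.timepoints)

    def test_type_i_error_on_flat_genes(self, design):
        expr, _ = dm.synthetic_data.simulate_expression(
            [f"g{i}" for i in range(3000)], design, rhythmic_fraction=0.0, seed=42
        )
        fits = detect_rhythmic_genes(expr, design.timepoints)
        assert fits["rhythmic"].mean() <= 0.05

    def test_planted_recovery_sensitivity_and_fdr(self, design):
        """Monte Carlo: 12% planted cosines at 3x noise SD among 2000 genes.

        FDR is a ratio estimate pooled over replicate cohorts; the bound
        is checked up to twice its binomial Monte-Carlo standard error.
        """
        tp = fp = fn = 0
        for seed in range(201, 213):
            expr, truth = dm.synthetic_data.simulate_expression(
                [f"g{i}" for i in range(2000)],
                design,
                rhythmic_fraction=0.12,
                amplitude_range=(0.75, 0.75),
                noise_sd=0.25,
                seed=seed,
            )
            fits = detect_rhythmic_genes(expr, design.timepoints)
            planted = {p.gene_id for p in truth.planted_rhythmic_genes}
            called = set(fits.loc[fits["rhythmic"], "gene_id"])
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        sensitivity = tp / (tp + fn)
        fdr = fp / (tp + fp)
        assert sensitivity >= 0.9
        assert fdr <= 0.05 + 2 * np.sqrt(fdr * (1 - fdr) / (tp + fp))


class TestCorrelation:
    def test_perfectly_monotone_coupling(self, design):
        genes = [f"g{i}" for i in range(30)]
        meth = np.linspace(0.05, 0.9, 30)
        levels = pd.DataFrame(
            [
                dict(gene_id=g, region="gene_body", group_id=gid, level=m)
                for g, m in zip(genes, meth)
                for gid in design.groups
            ]
        )
        expr = pd.DataFrame(
            np.tile(2.0 ** (10 * meth), (9, 1)).T, index=genes, columns=design.samples
        )
        corr, _ = methylation_expression_correlation(levels, expr, design)
        assert corr["correlation"].iloc[0] == pytest.approx(1.0)

    def test_rank_based_invariance_to_monotone_transform(self, design, rng):
        genes = [f"g{i}" for i in range(50)]
        meth = rng.uniform(0, 1, 50)
        base = rng.uniform(1, 100, 50)
        levels = pd.DataFrame(
            [
                dict(gene_id=g, region="gene_body", group_id=gid, level=m)
                for g, m in zip(genes, meth)
                for gid in design.groups
            ]
        )
        e1 = pd.DataFrame(np.tile(base, (9, 1)).T, index=genes, columns=design.samples)
        e2 = e1**3  # strictly monotone transform
        c1, _ = methylation_expression_correlation(levels, e1, design)
        c2, _ = methylation_expression_correlation(levels, e2, design)
        assert c1["correlation"].iloc[0] == pytest.approx(c2["correlation"].iloc[0])

    def test_too_few_pairs_is_nan(self, design):
        levels = pd.DataFrame(
            [dict(gene_id="g0", region="gene_body", group_id="G1", level=0.5)]
        )
        expr = pd.DataFrame([[1.0] * 9], index=["g0"], columns=design.samples)
        corr, _ = methylation_expression_correlation(levels, expr, design)
        assert np.isnan(corr["correlation"].iloc[0])

    def test_planted_rank_correlation_recovered(self, design, rng):
        genes = [f"g{i}" for i in range(500)]
        gene_meth = {g: float(rng.uniform(0.05, 0.8)) for g in genes}
        expr, _ = dm.synthetic_data.simulate_expression(
            genes,
            design,
            rhythmic_fraction=0.0,
            coupling={"region": "gene_body", "rho": 0.5, "sign": 1},
            gene_meth=gene_meth,
            seed=77,
        )
        levels = pd.DataFrame(
            [
                dict(gene_id=g, region="gene_body", group_id=gid, level=gene_meth[g])
                for g in genes
                for gid in design.groups
            ]
        )
        corr, pairs = methylation_expression_correlation(levels, expr, design)
        assert corr["correlation"].iloc[0] == pytest.approx(0.5, abs=0.1)
        assert len(pairs) == 500 * 5

    def test_null_coupling_is_near_zero(self, design, rng):
        genes = [f"g{i}" for i in range(500)]
        gene_meth = {g: float(rng.uniform(0.05, 0.8)) for g in genes}
        expr, _ = dm.synthetic_data.simulate_expression(
            genes, design, rhythmic_fraction=0.0, seed=78
        )
        levels = pd.DataFrame(
            [
                dict(gene_id=g, region="gene_body", group_id=gid, level=gene_meth[g])
                for g in genes
                for gid in design.groups
            ]
        )
        corr, _ = methylation_expression_correlation(levels, expr, design)
        assert abs(corr["correlation"].iloc[0]) < 4 / np.sqrt(500)


class TestIntegration:
    def _setup(self, design):
        rhythm = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "rhythmic": [True, True, True, False],
            }
        )
        links = pd.DataFrame(
            [
                dict(comparison="G2vG1", gene_id="g1", direction="hyper"),
                dict(comparison="G2vG1", gene_id="g2", direction="hypo"),
                dict(comparison="G3vG2", gene_id="g1", direction="hypo"),
                dict(comparison="G2vG1", gene_id="g4", direction="hyper"),
            ]
        )
        by_group = {
            "G1": [10, 4, 20, 5],
            "G2": [4, 10, 20, 5],
            "G3": [10, 10, 20, 5],
            "G4": [10, 10, 20, 5],
            "G5": [10, 4, 20, 5],
        }
        cols = {}
        for gid, members in design.groups.items():
            for s in members:
                cols.setdefault(s, by_group[gid])
        expr = pd.DataFrame(cols, index=["g1", "g2", "g3", "g4"], dtype=float)
        return rhythm, links, expr

    def test_quadrant_classification(self, design):
        rhythm, links, expr = self._setup(design)
        table, per_gene = integrate_dmr_rhythm(rhythm, links, expr, design)
        g2vg1 = table[table["comparison"] == "G2vG1"].iloc[0]
        # g1: hyper DMR, expression falls G1->G2 => (hyper, down)
        # g2: hypo DMR, expression rises => (hypo, up); g4 not rhythmic
        assert g2vg1.hyper_down == 1
        assert g2vg1.hypo_up == 1
        assert g2vg1.hyper_up == 0 and g2vg1.hypo_down == 0

    def test_per_comparison_semantics(self, design):
        rhythm, links, expr = self._setup(design)
        _, per_gene = integrate_dmr_rhythm(rhythm, links, expr, design)
        g1_rows = per_gene[per_gene["gene_id"] == "g1"]
        assert set(g1_rows["comparison"]) == {"G2vG1", "G3vG2"}

    def test_quadrants_sum_to_classified_genes(self, design):
        rhythm, links, expr = self._setup(design)
        table, per_gene = integrate_dmr_rhythm(rhythm, links, expr, design)
        for comp, sub in per_gene.groupby("comparison"):
            row = table[table["comparison"] == comp].iloc[0]
            assert row.hyper_down + row.hyper_up + row.hypo_down + row.hypo_up == len(sub)

    def test_anticorrelated_planting_dominates_quadrants(self, design):
        """Planted hyper->down / hypo->up coupling shows up as the majority."""
        rng = np.random.default_rng(12)
        n = 120
        genes = [f"g{i}" for i in range(n)]
        direction = np.where(rng.random(n) < 0.5, "hyper", "hypo")
        base = rng.uniform(5, 50, n)
        fc = np.where(direction == "hyper", 0.5, 2.0)  # anti-correlated change
        expr = pd.DataFrame(index=genes, columns=design.samples, dtype=float)
        g2 = set(design.groups["G2"])
        for s in design.samples:
            expr[s] = base * np.where([s in g2], fc, 1.0)
        rhythm = pd.DataFrame({"gene_id": genes, "rhythmic": True})
        links = pd.DataFrame(
            dict(comparison="G2vG1", gene_id=genes, direction=direction)
        )
        table, _ = integrate_dmr_rhythm(rhythm, links, expr, design)
        row = table[table["comparison"] == "G2vG1"].iloc[0]
        assert row.hyper_down + row.hypo_up == n
        assert row.hyper_up + row.hypo_down == 0


class TestDdct:
    @pytest.mark.parametrize(
        "tt,rt,tc,rc,expected",
        [
            (20, 18, 22, 20, 1.0),
            (20, 18, 23, 20, 2.0),
            (22, 18, 22, 20, 0.25),
        ],
    )
    def test_fold_change(self, tt, rt, tc, rc, expected):
        assert ddct_fold_change(tt, rt, tc, rc) == pytest.approx(expected)
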