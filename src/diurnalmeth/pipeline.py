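"""End-to-end orchestration helpers and truth-recovery scoring.

These functions chain the module-level operations the way the analysis
scripts and the acceptance checks run them: estimate the non-conversion
rate from the pooled lambda spike-ins, pool counts per group, call DMCs
and DMRs for every comparison of the design, and score calls against a
simulation truth ledger.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import differential as _diff
from . import methylome_core as _core
from .io_formats import StudyDesign
from .methylome_core import ConversionControl
from .synthetic_data import PlantedDMR, SimulationTruth


def pooled_nonconversion_rate(controls: Mapping[str, ConversionControl]) -> float:
    """Non-conversion rate from the lambda controls pooled over samples."""
    pooled = ConversionControl(
        n_converted=sum(c.n_converted for c in controls.values()),
        n_unconverted=sum(c.n_unconverted for c in controls.values()),
    )
    return _core.estimate_nonconversion(pooled)


def run_differential_pipeline(
    sample_sites: Mapping[str, pd.DataFrame],
    design: StudyDesign,
    r: float = 0.0,
    alpha: float = 0.05,
    min_diff_dmc: float = 0.2,
    min_diff_dmr: float = 0.1,
    min_dmcs: int = 3,
    max_gap: int = 300,
    count_methylated: bool = False,
    min_coverage: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DMCs and DMRs for every comparison of the design.

    Returns ``(dmcs, dmrs, test_stats)`` with the per-comparison tables
    concatenated. With ``count_methylated`` the union counts of each
    comparison are flagged by the binomial methylation caller so DMRs
    carry their methylated-cytosine content (n_mc).
    """
    pooled: dict[str, pd.DataFrame] = {}
    for gid, members in design.groups.items():
        pooled[gid] = _diff.pool_group_counts(sample_sites, members)
    dmc_frames, dmr_frames, stat_rows = [], [], []
    for a, b in design.comparisons:
        comp = design.comparison_id(a, b)
        dmcs, stats = _diff.call_dmcs(
            pooled[a], pooled[b], comp, r=r, alpha=alpha, min_diff=min_diff_dmc
        )
        methylated = None
        if count_methylated:
            union = _diff.pool_group_counts(
                {"a": pooled[a], "b": pooled[b]}, ["a", "b"]
            )
            flags = _core.call_methylated_sites(
                union, r=r, alpha=alpha, min_coverage=min_coverage
            )
            methylated = union[["chrom", "pos", "strand"]].assign(methylated=flags)
        dmrs = _diff.call_dmrs(
            dmcs,
            pooled[a],
            pooled[b],
            r=r,
            min_diff=min_diff_dmr,
            min_dmcs=min_dmcs,
            max_gap=max_gap,
            methylated=methylated,
        )
        dmc_frames.append(dmcs)
        dmr_frames.append(dmrs)
        stat_rows.append(stats)
    non_empty_dmc = [f for f in dmc_frames if len(f)] or dmc_frames[:1]
    non_empty_dmr = [f for f in dmr_frames if len(f)] or dmr_frames[:1]
    dmcs_all = pd.concat(non_empty_dmc, ignore_index=True)
    dmrs_all = pd.concat(non_empty_dmr, ignore_index=True)
    return dmcs_all, dmrs_all, pd.DataFrame(stat_rows)


def _overlaps(dmr_row, effect: PlantedDMR) -> bool:
    return (
        dmr_row.comparison == effect.comparison
        and dmr_row.chrom == effect.chrom
        and dmr_row.start <= effect.end
        and dmr_row.end >= effect.start
    )


def evaluate_dmr_recovery(
    dmrs: pd.DataFrame, truth: SimulationTruth | Sequence[PlantedDMR]
) -> dict[str, float]:
    """Sensitivity and precision of DMR calls against the truth ledger.

    A planted effect is recovered when >= 1 emitted DMR of the same
    comparison overlaps it with the matching direction; an emitted DMR is
    correct when it overlaps >= 1 same-comparison planted effect.
    """
    effects = truth.planted_dmrs if isinstance(truth, SimulationTruth) else list(truth)
    recovered = 0
    for eff in effects:
        hit = any(
            _overlaps(row, eff) and row.direction == eff.direction
            for row in dmrs.itertuples(index=False)
        )
        recovered += bool(hit)
    correct = 0
    for row in dmrs.itertuples(index=False):
        if any(_overlaps(row, eff) for eff in effects):
            correct += 1
    sensitivity = recovered / len(effects) if effects else float("nan")
    precision = correct / len(dmrs) if len(dmrs) else float("nan")
    return {
        "n_planted_effects": float(len(effects)),
        "n_called": float(len(dmrs)),
        "sensitivity": sensitivity,
        "precision": precision,
    }


def evaluate_rhythm_recovery(
    fits: pd.DataFrame, truth: SimulationTruth
) -> dict[str, float]:
    """Sensitivity and empirical FDR of rhythm calls against the ledger."""
    planted = {p.gene_id for p in truth.planted_rhythmic_genes}
    called = set(fits.loc[fits["rhythmic"], "gene_id"])
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return {
        "n_planted": float(len(planted)),
        "n_called": float(len(called)),
        "sensitivity": sensitivity,
        "empirical_fdr": fdr,
    }


def true_gene_body_levels(
    genes, sites: pd.DataFrame, counts: pd.DataFrame | None = None
) -> dict[str, float]:
    """Observed pooled gene-body level per gene from one site table."""
    from .rhythm import gene_region_methylation

    table = gene_region_methylation({"all": sites if counts is None else counts},
                                    genes, "gene_body")
    return {
        row.gene_id: row.level
        for row in table.itertuples(index=False)
        if np.isfinite(row.level)
    }
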