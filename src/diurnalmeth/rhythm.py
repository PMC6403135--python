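"""Methylation–expression integration and rhythmic-gene detection.

Rhythmicity over the 48-h light/dark -> continuous-light time course is
assessed by fixed-period cosinor (harmonic) regression on log2(FPKM+1):

    y(t) = mesor + a*cos(2*pi*t/T) + b*sin(2*pi*t/T) + e,   T = 24 h

with amplitude sqrt(a^2+b^2), peak phase atan2(b, a)*T/(2*pi) in [0, T),
an F-test of the two harmonic terms against the intercept-only model, and
Benjamini–Hochberg control across genes. Gene-level methylation is pooled
over strand-aware windows (0.5/1.0/1.5/2.0 kb upstream of the TSS, the
gene body, 0.5 kb downstream of the TES) and related to expression by
rank correlation. DMR-overlapping rhythmic genes are cross-classified by
methylation direction and expression change into hyper/hypo x up/down
quadrants.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import methylome_core as _core
from .io_formats import GeneModel, StudyDesign

REGION_SPECS = {
    "promoter_500": 500,
    "promoter_1000": 1000,
    "promoter_1500": 1500,
    "promoter_2000": 2000,
    "gene_body": None,
    "downstream_500": 500,
}


def region_interval(gene: GeneModel, region: str) -> tuple[int, int] | None:
    """Strand-aware genomic window for one of the six supported regions."""
    if region not in REGION_SPECS:
        raise ValueError(f"unknown region spec {region!r}")
    if region == "gene_body":
        return gene.start, gene.end
    size = REGION_SPECS[region]
    if region.startswith("promoter"):
        if gene.strand == "+":
            start, end = gene.start - size, gene.start - 1
        else:
            start, end = gene.end + 1, gene.end + size
    else:  # downstream of TES
        if gene.strand == "+":
            start, end = gene.end + 1, gene.end + size
        else:
            start, end = gene.start - size, gene.start - 1
    start = max(1, start)
    if start > end:
        return None
    return start, end


def gene_region_methylation(
    group_sites: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    region: str,
    r: float = 0.0,
) -> pd.DataFrame:
    """Pooled corrected methylation level per gene per group in one region.

    ``group_sites`` maps group id -> pooled site table for that group.
    Genes with zero covered cytosines in the window get level NaN.
    """
    rows = []
    for group_id, sites in group_sites.items():
        by_chrom = {
            ch: sub.sort_values("pos") for ch, sub in sites.groupby("chrom", sort=False)
        }
        for g in genes:
            iv = region_interval(g, region)
            level = np.nan
            if iv is not None and g.chrom in by_chrom:
                sub = by_chrom[g.chrom]
                pos = sub["pos"].to_numpy()
                lo = np.searchsorted(pos, iv[0], side="left")
                hi = np.searchsorted(pos, iv[1], side="right")
                if hi > lo:
                    nm = int(sub["n_meth"].to_numpy()[lo:hi].sum())
                    nu = int(sub["n_unmeth"].to_numpy()[lo:hi].sum())
                    if nm + nu > 0:
                        level = _core.correct_level(_core.methylation_level(nm, nu), r)
            rows.append(
                dict(gene_id=g.gene_id, region=region, group_id=group_id, level=level)
            )
    return pd.DataFrame(rows, columns=["gene_id", "region", "group_id", "level"])


def methylation_expression_correlation(
    levels: pd.DataFrame,
    expression: pd.DataFrame,
    design: StudyDesign,
    method: str = "spearman",
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate region methylation with expression over gene x group points.

    Expression is averaged over each group's member samples and
    log2(x+1)-transformed; the per-region correlation is Spearman's rank
    coefficient by default (Pearson available via ``method``). Returns
    (per-region correlation table, scatter-ready pair table). Regions with
    fewer than ``min_pairs`` complete pairs report NaN.
    """
    group_expr = pd.DataFrame(
        {
            gid: expression[members].mean(axis=1)
            for gid, members in design.groups.items()
            if all(m in expression.columns for m in members)
        }
    )
    log_expr = np.log2(group_expr + 1.0)
    pairs = levels.merge(
        log_expr.stack().rename("log2_expr").rename_axis(["gene_id", "group_id"]).reset_index(),
        on=["gene_id", "group_id"],
        how="inner",
    ).dropna(subset=["level", "log2_expr"])
    rows = []
    for region, sub in pairs.groupby("region", sort=False):
        if len(sub) < min_pairs:
            rows.append(dict(region=region, n=len(sub), correlation=np.nan, p=np.nan))
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(sub["level"], sub["log2_expr"])
        elif method == "pearson":
            rho, p = stats.pearsonr(sub["level"], sub["log2_expr"])
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append(dict(region=region, n=len(sub), correlation=float(rho), p=float(p)))
    return pd.DataFrame(rows, columns=["region", "n", "correlation", "p"]), pairs


def _squeeze_variance(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene residual variances.

    Models s2 as scaled chi-square draws around a common prior variance
    s0^2 with prior degrees of freedom d0, estimated by the closed-form
    method-of-moments fit on log s2 (digamma/trigamma matching). Returns
    the posterior variances (d0*s0^2 + df*s2)/(d0 + df) and d0 (inf when
    the observed spread of s2 is no wider than chi-square sampling noise,
    in which case all variances collapse to the common value).
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    # only model heterogeneity the data can distinguish from chi-square
    # sampling noise: under homogeneous variances the sample variance of e
    # fluctuates around trigamma(df/2) with variance ~ (psi'''(df/2) +
    # 2*psi'(df/2)^2)/n; below the one-sided 95% bound, collapse to the
    # common-variance limit
    n_ok = int(ok.sum())
    sd_evar = np.sqrt(
        (float(polygamma(3, df / 2.0)) + 2.0 * float(polygamma(1, df / 2.0)) ** 2)
        / n_ok
    )
    if e_var <= 1.645 * sd_evar:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
        return np.full_like(s2, s0_2), d0
    # invert trigamma(d0/2) = e_var by Newton iteration on 1/trigamma,
    # which is nearly linear in its argument
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = float(polygamma(1, x))
        delta = tri * (1.0 - tri / e_var) / float(polygamma(2, x))
        x = x + delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_2 = float(np.exp(np.mean(e) + digamma(x) - np.log(x)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    post[~ok] = s0_2 * d0 / (d0 + df) if np.isfinite(d0) else s0_2
    return post, d0


def detect_rhythmic_genes(
    expression: pd.DataFrame,
    timepoints: Mapping[str, float],
    period: float = 24.0,
    q_threshold: float = 0.05,
    log_transform: bool = True,
    moderate_variance: bool = True,
) -> pd.DataFrame:
    """Fixed-period cosinor fit per gene with F-test and BH correction.

    Requires at least five sampled time points (the three-parameter model
    needs residual degrees of freedom). The F statistic compares the
    harmonic terms against the intercept-only model; with
    ``moderate_variance`` (default) the residual variance is shrunk
    across genes by the empirical-Bayes scaled-chi-square model before
    forming F, which restores power at these small per-gene residual
    degrees of freedom while keeping the null F distribution exact.
    Constant genes get p = 1 by convention. Returns a table with mesor,
    amplitude, phase (hours of peak after the time origin, in
    [0, period)), p, q and the rhythmic flag q < ``q_threshold``.
    """
    from .differential import adjust_fdr

    samples = [s for s in expression.columns if s in timepoints]
    if len(samples) < 5:
        raise ValueError("need at least 5 timed samples for the cosinor fit")
    t = np.array([timepoints[s] for s in samples], dtype=float)
    y = expression[samples].to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    omega = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # 3 x genes
    fitted = X @ beta
    rss1 = ((y.T - fitted) ** 2).sum(axis=0)
    rss0 = ((y.T - y.T.mean(axis=0)) ** 2).sum(axis=0)
    df1, df2 = k - 1, n - k
    s2 = rss1 / df2
    if moderate_variance:
        s2_post, d0 = _squeeze_variance(s2, df2)
        df2_eff = df2 + (d0 if np.isfinite(d0) else 1e6)
    else:
        s2_post, df2_eff = s2, df2
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss0 - rss1) / df1) / s2_post
    p = np.where(
        rss0 <= np.finfo(float).eps * n,  # constant series
        1.0,
        np.where(s2_post <= 0, 0.0, stats.f.sf(F, df1, df2_eff)),
    )
    q = adjust_fdr(p)
    a, b = beta[1], beta[2]
    amplitude = np.hypot(a, b)
    phase = (np.arctan2(b, a) / omega) % period
    out = pd.DataFrame(
        {
            "gene_id": expression.index,
            "period": period,
            "mesor": beta[0],
            "amplitude": amplitude,
            "phase": phase,
            "p": p,
            "q": q,
        }
    )
    out["rhythmic"] = out["q"] < q_threshold
    return out


def integrate_dmr_rhythm(
    rhythm: pd.DataFrame,
    dmg_links: pd.DataFrame,
    expression: pd.DataFrame,
    design: StudyDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-classify rhythmic DMR-overlapping genes by direction x change.

    For each comparison (a, b) and each rhythmic gene linked to a DMR of
    that comparison: the gene is "up" when the log2 ratio of group-b to
    group-a mean expression (pseudocount 1) is positive and "down" when
    negative. Counts the four (hyper/hypo x down/up) quadrants per
    comparison plus a union rollup over distinct (gene, direction, change)
    classifications; genes with zero expression in both groups, or zero
    change, are tallied separately and excluded from quadrants.
    """
    rhythmic_ids = set(rhythm.loc[rhythm["rhythmic"], "gene_id"])
    group_expr = {
        gid: expression[members].mean(axis=1) for gid, members in design.groups.items()
    }
    rows = []
    per_gene = []
    for a, b in design.comparisons:
        comp = design.comparison_id(a, b)
        links = dmg_links[dmg_links["comparison"] == comp]
        genes = set(links["gene_id"]) & rhythmic_ids
        quad = {("hyper", "down"): 0, ("hyper", "up"): 0, ("hypo", "down"): 0, ("hypo", "up"): 0}
        n_excluded_zero, n_excluded_nochange = 0, 0
        for gid in sorted(genes):
            directions = set(links.loc[links["gene_id"] == gid, "direction"])
            ea = float(group_expr[a].get(gid, np.nan))
            eb = float(group_expr[b].get(gid, np.nan))
            if not np.isfinite(ea) or not np.isfinite(eb) or (ea == 0 and eb == 0):
                n_excluded_zero += 1
                continue
            lfc = np.log2((eb + 1.0) / (ea + 1.0))
            if lfc == 0:
                n_excluded_nochange += 1
                continue
            change = "up" if lfc > 0 else "down"
            for direction in directions:
                quad[(direction, change)] += 1
                per_gene.append(
                    dict(
                        comparison=comp,
                        gene_id=gid,
                        direction=direction,
                        change=change,
                        log2_fc=float(lfc),
                    )
                )
        rows.append(
            dict(
                comparison=comp,
                n_rhythmic_dmg=len(genes),
                hyper_down=quad[("hyper", "down")],
                hyper_up=quad[("hyper", "up")],
                hypo_down=quad[("hypo", "down")],
                hypo_up=quad[("hypo", "up")],
                n_excluded_zero_expression=n_excluded_zero,
                n_excluded_no_change=n_excluded_nochange,
            )
        )
    per_gene_df = pd.DataFrame(
        per_gene, columns=["comparison", "gene_id", "direction", "change", "log2_fc"]
    )
    union = (
        per_gene_df.drop_duplicates(subset=["gene_id", "direction", "change"])
        if len(per_gene_df)
        else per_gene_df
    )
    union_genes = dmg_links.merge(
        pd.DataFrame({"gene_id": sorted(rhythmic_ids)}), on="gene_id"
    )["gene_id"].nunique()
    rows.append(
        dict(
            comparison="union",
            n_rhythmic_dmg=int(union_genes),
            hyper_down=int(((union["direction"] == "hyper") & (union["change"] == "down")).sum()),
            hyper_up=int(((union["direction"] == "hyper") & (union["change"] == "up")).sum()),
            hypo_down=int(((union["direction"] == "hypo") & (union["change"] == "down")).sum()),
            hypo_up=int(((union["direction"] == "hypo") & (union["change"] == "up")).sum()),
            n_excluded_zero_expression=sum(r["n_excluded_zero_expression"] for r in rows),
            n_excluded_no_change=sum(r["n_excluded_no_change"] for r in rows),
        )
    )
    return pd.DataFrame(rows), per_gene_df


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR quantification by the 2^-ddCt method."""
    ddct = (ct_target_test - ct_ref_test) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
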