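"""DMC and DMR calling between sample groups.

Per position and comparison, read counts are pooled (summed) within each
group and a two-sided Fisher exact test is applied to the 2x2 table
[[mC_a, umC_a], [mC_b, umC_b]]. Positions with BH-adjusted q < 0.05 and a
corrected-level difference > 0.2 are differentially methylated cytosines
(DMCs). Same-direction DMCs closer than 300 bp are single-linkage
clustered; clusters of >= 3 DMCs whose region-wide pooled level difference
exceeds 0.1 are differentially methylated regions (DMRs). All thresholds
are parameters with those defaults.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import methylome_core as _core

# relative tolerance when deciding whether an alternative table's point
# probability counts as "as extreme as" the observed one; absorbs float
# rounding on mathematically tied probabilities
_TIE_RTOL = 1e-9


def fisher_exact_two_sided(a, b, c, d, chunk: int = 50_000) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for 2x2 tables [[a,b],[c,d]].

    p is the sum of hypergeometric point probabilities not exceeding the
    observed table's, over all tables with the same margins.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("table entries must be nonnegative")
    out = np.empty(a.shape[0], dtype=float)
    for lo_i in range(0, a.shape[0], chunk):
        sl = slice(lo_i, lo_i + chunk)
        out[sl] = _fisher_chunk(a[sl], b[sl], c[sl], d[sl])
    return out


def _fisher_chunk(a, b, c, d) -> np.ndarray:
    m = a + b  # row 1 total
    n = c + d  # row 2 total
    k = a + c  # column 1 total
    lo = np.maximum(0, k - n)
    hi = np.minimum(k, m)
    width = int((hi - lo).max()) + 1 if a.size else 1
    x = lo[:, None] + np.arange(width)[None, :]
    support = x <= hi[:, None]
    xs = np.where(support, x, lo[:, None])
    # log point probability of table with top-left entry x at fixed margins
    def _lchoose(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logp = (
        _lchoose(m[:, None], xs)
        + _lchoose(n[:, None], k[:, None] - xs)
        - _lchoose((m + n)[:, None], k[:, None])
    )
    logp_obs = (
        _lchoose(m, a) + _lchoose(n, c) - _lchoose(m + n, k)
    )
    ratio = np.exp(logp - logp_obs[:, None])
    take = support & (ratio <= 1.0 + _TIE_RTOL)
    p = np.exp(logp_obs) * (ratio * take).sum(axis=1)
    return np.minimum(p, 1.0)


def dmc_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int], r: float = 0.0
) -> tuple[float, float]:
    """Test one position: two-sided Fisher p and corrected level difference.

    ``counts_*`` are (n_meth, n_unmeth) pooled within each group; ``diff``
    is level_b - level_a on non-conversion-corrected levels.
    """
    ma, ua = counts_a
    mb, ub = counts_b
    if ma + ua <= 0 or mb + ub <= 0:
        raise ValueError("both groups need coverage > 0; skip such positions upstream")
    p = float(fisher_exact_two_sided(ma, ua, mb, ub)[0])
    la = _core.correct_level(_core.methylation_level(ma, ua), r)
    lb = _core.correct_level(_core.methylation_level(mb, ub), r)
    return p, float(lb - la)


def adjust_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                   dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def pool_group_counts(
    sample_sites: Mapping[str, pd.DataFrame], members: Iterable[str]
) -> pd.DataFrame:
    """Sum per-position counts across the member samples of one group.

    Positions absent from a member contribute (0, 0). The result carries
    the union position universe sorted by (chrom, pos, strand).
    """
    members = list(members)
    if len(set(members)) != len(members):
        raise ValueError("duplicate sample in group membership")
    frames = [
        sample_sites[s][["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]]
        for s in members
    ]
    cat = pd.concat(frames, ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos", "strand", "context"], observed=True, sort=True)[
            ["n_meth", "n_unmeth"]
        ]
        .sum()
        .reset_index()
    )
    return pooled


def call_dmcs(
    pooled_a: pd.DataFrame,
    pooled_b: pd.DataFrame,
    comparison: str,
    r: float = 0.0,
    alpha: float = 0.05,
    min_diff: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Call DMCs for one comparison from the two groups' pooled counts.

    Positions covered in both groups are tested jointly across contexts;
    BH runs over all tested positions of the comparison. Returns the
    retained DMC table (q < alpha and |diff| > min_diff) and a stats dict
    with n_tested / n_skipped_zero_coverage / n_significant.
    """
    merged = pooled_a.merge(
        pooled_b,
        on=["chrom", "pos", "strand", "context"],
        how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0)
    for col in ("n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b"):
        merged[col] = merged[col].astype(np.int64)
    cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    testable = (cov_a > 0) & (cov_b > 0)
    n_skipped = int((~testable).sum())
    t = merged[testable].reset_index(drop=True)
    p = fisher_exact_two_sided(
        t["n_meth_a"], t["n_unmeth_a"], t["n_meth_b"], t["n_unmeth_b"]
    )
    level_a = _core.correct_level(
        _core.methylation_level(t["n_meth_a"], t["n_unmeth_a"]), r
    )
    level_b = _core.correct_level(
        _core.methylation_level(t["n_meth_b"], t["n_unmeth_b"]), r
    )
    diff = level_b - level_a
    q = adjust_fdr(p)
    keep = (q < alpha) & (np.abs(diff) > min_diff)
    dmcs = t.loc[keep, ["chrom", "pos", "strand", "context"]].copy()
    dmcs["level_a"] = level_a[keep]
    dmcs["level_b"] = level_b[keep]
    dmcs["diff"] = diff[keep]
    dmcs["p"] = p[keep]
    dmcs["q"] = q[keep]
    dmcs["direction"] = np.where(diff[keep] > 0, "hyper", "hypo")
    dmcs["comparison"] = comparison
    dmcs = dmcs.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    stats = {
        "comparison": comparison,
        "n_tested": int(len(t)),
        "n_skipped_zero_coverage": n_skipped,
        "n_significant": int(keep.sum()),
    }
    return dmcs, stats


DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "comparison",
    "n_dmc",
    "diff",
    "direction",
    "n_cg",
    "n_chg",
    "n_chh",
    "n_mc",
    "length",
]


def call_dmrs(
    dmcs: pd.DataFrame,
    pooled_a: pd.DataFrame,
    pooled_b: pd.DataFrame,
    r: float = 0.0,
    min_diff: float = 0.1,
    min_dmcs: int = 3,
    max_gap: int = 300,
    methylated: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster DMCs of one comparison into DMRs.

    Same-direction DMCs on one chromosome whose adjacent distance is
    < ``max_gap`` bp form a cluster (a direction change or a gap of
    >= max_gap breaks it). Clusters with >= ``min_dmcs`` members span the
    candidate region [first DMC pos, last DMC pos]; the region difference
    is the pooled corrected-level difference over ALL covered cytosines in
    the span, and candidates with |diff| > ``min_diff`` are emitted. When a
    ``methylated`` table (columns chrom, pos, strand, methylated) is given,
    n_mc counts flagged positions inside each DMR.
    """
    if dmcs.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    pos_arr = dmcs["pos"].to_numpy()
    chrom_arr = dmcs["chrom"].to_numpy()
    order_ok = True
    for ch in pd.unique(chrom_arr):
        p = pos_arr[chrom_arr == ch]
        if not (np.diff(p) >= 0).all():
            order_ok = False
    if not order_ok:
        raise ValueError("DMCs must be sorted by position within chromosome")

    merged = pooled_a.merge(
        pooled_b,
        on=["chrom", "pos", "strand", "context"],
        how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0)
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if methylated is not None:
        merged = merged.merge(
            methylated[["chrom", "pos", "strand", "methylated"]],
            on=["chrom", "pos", "strand"],
            how="left",
        )
        merged["methylated"] = merged["methylated"].fillna(False).astype(bool)

    rows = []
    for ch, sub in dmcs.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        direc = sub["direction"].to_numpy()
        ctx = sub["context"].to_numpy()
        breaks = np.zeros(len(sub), dtype=bool)
        if len(sub) > 1:
            breaks[1:] = (np.diff(pos) >= max_gap) | (direc[1:] != direc[:-1])
        cluster_id = np.cumsum(breaks)
        msub = merged[merged["chrom"] == ch]
        mpos = msub["pos"].to_numpy()
        for cid in np.unique(cluster_id):
            sel = cluster_id == cid
            if sel.sum() < min_dmcs:
                continue
            start, end = int(pos[sel].min()), int(pos[sel].max())
            in_span = (mpos >= start) & (mpos <= end)
            span = msub[in_span]
            ma, ua = int(span["n_meth_a"].sum()), int(span["n_unmeth_a"].sum())
            mb, ub = int(span["n_meth_b"].sum()), int(span["n_unmeth_b"].sum())
            if ma + ua == 0 or mb + ub == 0:
                continue
            la = _core.correct_level(_core.methylation_level(ma, ua), r)
            lb = _core.correct_level(_core.methylation_level(mb, ub), r)
            region_diff = lb - la
            if abs(region_diff) <= min_diff:
                continue
            # the region-wide difference must agree in sign with the
            # cluster's DMC direction, or the hyper/hypo label is void
            if (region_diff > 0) != (direc[sel][0] == "hyper"):
                continue
            n_mc = np.nan
            if methylated is not None:
                n_mc = int(span["methylated"].sum())
            rows.append(
                dict(
                    chrom=ch,
                    start=start,
                    end=end,
                    comparison=sub["comparison"].iloc[0],
                    n_dmc=int(sel.sum()),
                    diff=float(region_diff),
                    direction=str(direc[sel][0]),
                    n_cg=int((ctx[sel] == "CG").sum()),
                    n_chg=int((ctx[sel] == "CHG").sum()),
                    n_chh=int((ctx[sel] == "CHH").sum()),
                    n_mc=n_mc,
                    length=end - start + 1,
                )
            )
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def dmr_summary(dmrs: pd.DataFrame, dmcs: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison and overall DMR/DMC accounting.

    Reports DMR counts, hypo/hyper counts and their ratio, maximum DMR
    length and methylated-cytosine content, and the context composition
    of member DMCs as percentages.
    """
    def _one(comp: str, d: pd.DataFrame, c: pd.DataFrame) -> dict:
        n_hypo = int((d["direction"] == "hypo").sum()) if len(d) else 0
        n_hyper = int((d["direction"] == "hyper").sum()) if len(d) else 0
        ctx_counts = {
            ctx: (int((c["context"] == ctx).sum()) if len(c) else 0)
            for ctx in ("CG", "CHG", "CHH")
        }
        n_ctx = sum(ctx_counts.values())
        return dict(
            comparison=comp,
            n_dmr=int(len(d)),
            n_hypo=n_hypo,
            n_hyper=n_hyper,
            hypo_hyper_ratio=(n_hypo / n_hyper if n_hyper else np.nan),
            max_length=(int(d["length"].max()) if len(d) else 0),
            max_n_mc=(
                int(d["n_mc"].max())
                if len(d) and d["n_mc"].notna().any()
                else 0
            ),
            n_dmc=int(len(c)),
            pct_cg=(100 * ctx_counts["CG"] / n_ctx if n_ctx else 0.0),
            pct_chg=(100 * ctx_counts["CHG"] / n_ctx if n_ctx else 0.0),
            pct_chh=(100 * ctx_counts["CHH"] / n_ctx if n_ctx else 0.0),
        )

    comps = sorted(
        set(dmrs["comparison"]) | set(dmcs["comparison"])
        if len(dmrs) or len(dmcs)
        else set()
    )
    rows = [
        _one(
            comp,
            dmrs[dmrs["comparison"] == comp] if len(dmrs) else dmrs,
            dmcs[dmcs["comparison"] == comp] if len(dmcs) else dmcs,
        )
        for comp in comps
    ]
    rows.append(_one("overall", dmrs, dmcs))
    return pd.DataFrame(rows)
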