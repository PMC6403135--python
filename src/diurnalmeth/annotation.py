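"""Strand-aware feature decomposition and annotation of methylation calls.

The genome is decomposed into promoter (2 kb upstream of the TSS),
5'/3'-UTR, exon, intron, 2-kb up-/downstream flanks, TE copies (labelled
by family), and the intergenic complement. Sites, DMCs and DMRs are
assigned to every overlapping feature, with a fixed precedence
(promoter > UTR > exon > intron > flank > intergenic) deciding the
single "primary" label used for composition tables. Also provides the
differentially-methylated-gene definition (a gene whose body or promoter
overlaps a DMR), per-feature methylation levels, and TSS/TES-anchored
metagene profiles.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import methylome_core as _core
from .io_formats import GeneModel, TEAnnotation

PRIMARY_PRECEDENCE = [
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "upstream2k",
    "downstream2k",
    "TE",
    "intergenic",
]

GENIC_FEATURES = ["promoter", "five_prime_utr", "three_prime_utr", "exon", "intron"]


def promoter_interval(gene: GeneModel, size: int = 2000, chrom_length: int | None = None
                      ) -> tuple[int, int] | None:
    """The ``size`` bp immediately upstream of the TSS, clipped to the chromosome."""
    if gene.strand == "+":
        start, end = gene.start - size, gene.start - 1
    else:
        start, end = gene.end + 1, gene.end + size
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start > end:
        return None
    return start, end


def downstream_interval(gene: GeneModel, size: int = 2000, chrom_length: int | None = None
                        ) -> tuple[int, int] | None:
    """The ``size`` bp immediately downstream of the TES, strand-aware."""
    if gene.strand == "+":
        start, end = gene.end + 1, gene.end + size
    else:
        start, end = gene.start - size, gene.start - 1
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start > end:
        return None
    return start, end


class FeatureIndex:
    """Interval index answering "which features overlap here?" queries."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        tes: Sequence[TEAnnotation],
        chrom_lengths: Mapping[str, int],
        flank: int = 2000,
    ) -> None:
        self.chrom_lengths = dict(chrom_lengths)
        self.flank = flank
        self.genes = list(genes)
        self.tes = list(tes)
        self._trees: dict[str, IntervalTree] = {
            chrom: IntervalTree() for chrom in chrom_lengths
        }
        for g in genes:
            if g.chrom not in self._trees:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > chrom_lengths[g.chrom] or g.start < 1:
                raise ValueError(f"gene {g.gene_id} extends off chromosome {g.chrom}")
            L = chrom_lengths[g.chrom]
            self._add(g.chrom, g.start, g.end, ("gene_body", g.gene_id))
            prom = promoter_interval(g, flank, L)
            if prom:
                self._add(g.chrom, *prom, ("promoter", g.gene_id))
                self._add(g.chrom, *prom, ("upstream2k", g.gene_id))
            down = downstream_interval(g, flank, L)
            if down:
                self._add(g.chrom, *down, ("downstream2k", g.gene_id))
            for s, e in g.exons:
                self._add(g.chrom, s, e, ("exon", g.gene_id))
            for s, e in g.introns:
                self._add(g.chrom, s, e, ("intron", g.gene_id))
            for s, e in g.five_prime_utr:
                self._add(g.chrom, s, e, ("five_prime_utr", g.gene_id))
            for s, e in g.three_prime_utr:
                self._add(g.chrom, s, e, ("three_prime_utr", g.gene_id))
        for te in tes:
            if te.chrom not in self._trees:
                raise ValueError(f"TE on unknown chromosome {te.chrom}")
            self._add(te.chrom, te.start, te.end, (f"TE:{te.family}", None))

    def _add(self, chrom: str, start: int, end: int, label) -> None:
        # IntervalTree is half-open; internal coords are 1-based inclusive
        self._trees[chrom].addi(start, end + 1, label)

    def query(self, chrom: str, start: int, end: int | None = None) -> set[str]:
        """Feature labels overlapping [start, end] (or the single position).

        Intergenic is reported iff no other feature covers any queried base.
        """
        if chrom not in self._trees:
            raise ValueError(f"unknown chromosome {chrom}")
        end = start if end is None else end
        hits = self._trees[chrom].overlap(start, end + 1)
        labels = {iv.data[0] for iv in hits}
        labels.discard("gene_body")
        if not labels:
            labels = {"intergenic"}
        return labels

    def query_genes(self, chrom: str, start: int, end: int | None = None,
                    which: tuple[str, ...] = ("gene_body", "promoter")) -> dict[str, set[str]]:
        """Gene ids whose body/promoter (etc.) overlaps the interval, by label."""
        end = start if end is None else end
        hits = self._trees[chrom].overlap(start, end + 1)
        out: dict[str, set[str]] = {w: set() for w in which}
        for iv in hits:
            label, gid = iv.data
            if label in out and gid is not None:
                out[label].add(gid)
        return out


def primary_label(labels: set[str]) -> str:
    """Resolve multiple overlapping labels to one by fixed precedence."""
    for feat in PRIMARY_PRECEDENCE:
        if feat == "TE":
            te = sorted(l for l in labels if l.startswith("TE:"))
            if te:
                return te[0]
        elif feat in labels:
            return feat
    return "intergenic"


def assign_features(items: pd.DataFrame, index: FeatureIndex) -> pd.DataFrame:
    """Annotate items (chrom + pos, or chrom + start/end) with features.

    Adds ``features`` (sorted ';'-joined full label set) and ``feature``
    (the primary label) columns; returns a copy.
    """
    out = items.copy()
    if "start" in out.columns:
        spans = zip(out["chrom"], out["start"], out["end"])
    else:
        spans = zip(out["chrom"], out["pos"], out["pos"])
    full, prim = [], []
    for chrom, s, e in spans:
        labels = index.query(chrom, int(s), int(e))
        full.append(";".join(sorted(labels)))
        prim.append(primary_label(labels))
    out["features"] = full
    out["feature"] = prim
    return out


def feature_composition(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of items per primary feature label.

    ``pct`` is over all items; ``pct_genic`` re-normalizes over items whose
    primary label is a genic feature (promoter/UTR/exon/intron).
    """
    counts = annotated["feature"].value_counts()
    df = counts.rename_axis("feature").reset_index(name="n")
    df["pct"] = 100 * df["n"] / df["n"].sum()
    genic = df["feature"].isin(GENIC_FEATURES)
    genic_total = df.loc[genic, "n"].sum()
    df["pct_genic"] = np.where(
        genic, 100 * df["n"] / (genic_total if genic_total else 1), np.nan
    )
    return df


def differentially_methylated_genes(
    dmrs: pd.DataFrame, genes: Sequence[GeneModel], index: FeatureIndex
) -> pd.DataFrame:
    """Genes whose body or 2-kb promoter overlaps at least one DMR.

    Returns one link row per (comparison, gene, DMR) with the overlap
    region and DMR direction; a gene appears once per distinct DMR even
    if both its body and promoter overlap it (region reports both).
    """
    rows = []
    for i, row in dmrs.iterrows():
        hit = index.query_genes(row["chrom"], int(row["start"]), int(row["end"]))
        for gid in sorted(hit["gene_body"] | hit["promoter"]):
            region = []
            if gid in hit["promoter"]:
                region.append("promoter")
            if gid in hit["gene_body"]:
                region.append("gene_body")
            rows.append(
                dict(
                    comparison=row["comparison"],
                    gene_id=gid,
                    dmr_index=i,
                    chrom=row["chrom"],
                    dmr_start=int(row["start"]),
                    dmr_end=int(row["end"]),
                    direction=row["direction"],
                    region="+".join(region),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "gene_id",
            "dmr_index",
            "chrom",
            "dmr_start",
            "dmr_end",
            "direction",
            "region",
        ],
    )


def feature_methylation_profile(
    sites: pd.DataFrame, index: FeatureIndex, r: float = 0.0
) -> pd.DataFrame:
    """Coverage-weighted corrected mean level per feature class and context.

    A site contributes to every feature it overlaps. Feature/context cells
    with zero covered cytosines are absent from the table.
    """
    annotated = assign_features(sites, index)
    expanded = annotated.assign(
        feature_list=annotated["features"].str.split(";")
    ).explode("feature_list")
    g = expanded.groupby(["feature_list", "context"], observed=True)
    out = g.agg(
        n_sites=("n_meth", "size"),
        n_meth=("n_meth", "sum"),
        n_unmeth=("n_unmeth", "sum"),
    ).reset_index()
    out = out.rename(columns={"feature_list": "feature"})
    out = out[out["n_meth"] + out["n_unmeth"] > 0].reset_index(drop=True)
    out["level"] = _core.correct_level(
        _core.methylation_level(out["n_meth"], out["n_unmeth"]), r
    )
    return out


def metagene_profile(
    items: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 2000,
    n_bins: int = 20,
    body_bins: int = 20,
    value: str | None = None,
) -> pd.DataFrame:
    """TSS/TES-anchored profile: flank bins + proportionally scaled body bins.

    Each flank is cut into ``n_bins`` fixed-width bins (100 bp at
    defaults) and the gene body into ``body_bins`` proportional bins;
    minus-strand genes are orientation-flipped so bin 0 is always the most
    5' upstream bin. Items are positions (``pos``) or intervals
    (``start``/``end``; their midpoint is used). With ``value=None`` the
    profile is item density (items per bp per gene); with ``value=<col>``
    it is the unweighted mean of that column per bin.

    Bins are indexed 0..n_bins-1 (upstream), n_bins..n_bins+body_bins-1
    (body), n_bins+body_bins..n_bins+body_bins+n_bins-1 (downstream).
    """
    if flank % n_bins:
        raise ValueError("flank must be divisible by n_bins")
    bw = flank // n_bins
    total_bins = 2 * n_bins + body_bins
    counts = np.zeros(total_bins, dtype=float)
    sums = np.zeros(total_bins, dtype=float)
    bp_per_bin = np.zeros(total_bins, dtype=float)

    if "pos" in items.columns:
        ipos = items["pos"].to_numpy(dtype=np.int64)
    else:
        ipos = ((items["start"].to_numpy() + items["end"].to_numpy()) // 2).astype(np.int64)
    ichrom = items["chrom"].to_numpy()
    ival = items[value].to_numpy(dtype=float) if value else None

    by_chrom: dict[str, np.ndarray] = {}
    for ch in np.unique(ichrom):
        sel = np.nonzero(ichrom == ch)[0]
        order = np.argsort(ipos[sel])
        by_chrom[ch] = sel[order]

    for g in genes:
        glen = g.end - g.start + 1
        bp_per_bin[:n_bins] += bw
        bp_per_bin[n_bins : n_bins + body_bins] += glen / body_bins
        bp_per_bin[n_bins + body_bins :] += bw
        if g.chrom not in by_chrom:
            continue
        idx = by_chrom[g.chrom]
        pos_sorted = ipos[idx]
        lo = np.searchsorted(pos_sorted, g.start - flank, side="left")
        hi = np.searchsorted(pos_sorted, g.end + flank, side="right")
        if lo == hi:
            continue
        sub = idx[lo:hi]
        p = ipos[sub]
        rel_bins = np.empty(len(p), dtype=np.int64)
        before = p < g.start
        after = p > g.end
        body = ~(before | after)
        # 5' flank in genomic coordinates; flipped later for minus strand
        rel_bins[before] = (p[before] - (g.start - flank)) // bw
        rel_bins[body] = n_bins + np.minimum(
            ((p[body] - g.start) * body_bins) // glen, body_bins - 1
        )
        rel_bins[after] = n_bins + body_bins + (p[after] - g.end - 1) // bw
        if g.strand == "-":
            rel_bins = total_bins - 1 - rel_bins
        np.add.at(counts, rel_bins, 1.0)
        if ival is not None:
            np.add.at(sums, rel_bins, ival[sub])

    segment = (
        ["upstream"] * n_bins + ["body"] * body_bins + ["downstream"] * n_bins
    )
    out = pd.DataFrame(
        {
            "bin": np.arange(total_bins),
            "segment": segment,
            "n_items": counts,
            "bp": bp_per_bin,
        }
    )
    if value:
        with np.errstate(invalid="ignore"):
            out["mean_" + value] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["density"] = np.where(bp_per_bin > 0, counts / np.maximum(bp_per_bin, 1e-300), np.nan)
    return out
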