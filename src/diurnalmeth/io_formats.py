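"""Readers and writers for every on-disk format the pipeline touches.

Internal coordinate convention is 1-based inclusive on both ends, matching
the cytosine report and GFF3. BED input/output converts at the boundary
(BED is 0-based, half-open). Site tables are pandas DataFrames with the
columns of :data:`SITE_COLUMNS`; one row per strand-specific cytosine.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

SITE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]

#: hours after the LD0 time origin for the nine samples of the
#: light/dark -> continuous-light design
DEFAULT_TIMEPOINTS = {
    "LD0": 0.0,
    "LD4": 4.0,
    "LD8": 8.0,
    "LD16": 16.0,
    "CL0": 24.0,
    "CL4": 28.0,
    "CL8": 32.0,
    "CL16": 40.0,
    "CL24": 48.0,
}


@dataclass(frozen=True)
class MethylationSite:
    """One strand-specific cytosine with its bisulfite read counts."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int
    trinucleotide: str

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class GeneModel:
    """A gene with strand-aware structure in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    five_prime_utr: list[tuple[int, int]] = field(default_factory=list)
    three_prime_utr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: missing or bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}] outside gene bounds "
                    f"[{self.start},{self.end}]"
                )

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, within the transcribed region."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element copy; 1-based inclusive, family from BED name."""

    chrom: str
    start: int
    end: int
    family: str


@dataclass
class StudyDesign:
    """Sample grouping and the ordered group comparisons.

    The default design has nine samples over 48 h grouped into five
    time-of-day groups of two (one light/dark-cycle sample and one
    continuous-light sample each); CL0 serves in both G1 and G5, closing
    the free-running day. A sample may belong to several groups but never
    to both sides of a single comparison.
    """

    groups: dict[str, list[str]]
    comparisons: list[tuple[str, str]]
    timepoints: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, members in self.groups.items():
            if len(set(members)) != len(members):
                raise ValueError(f"group {gid}: duplicate member")
        for a, b in self.comparisons:
            if a not in self.groups or b not in self.groups:
                raise ValueError(f"comparison {a} vs {b} references undefined group")
            shared = set(self.groups[a]) & set(self.groups[b])
            if shared:
                raise ValueError(
                    f"samples {sorted(shared)} appear on both sides of {b} vs {a}"
                )

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.groups.values():
            for s in members:
                seen.setdefault(s)
        return list(seen)

    def comparison_id(self, a: str, b: str) -> str:
        return f"{b}v{a}"


def default_design() -> StudyDesign:
    """The five-group, four-comparison design of the 48-h sampling course."""
    return StudyDesign(
        groups={
            "G1": ["LD0", "CL0"],
            "G2": ["LD4", "CL4"],
            "G3": ["LD8", "CL8"],
            "G4": ["LD16", "CL16"],
            "G5": ["CL0", "CL24"],
        },
        comparisons=[("G1", "G2"), ("G2", "G3"), ("G3", "G4"), ("G4", "G5")],
        timepoints=dict(DEFAULT_TIMEPOINTS),
    )


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------


def read_cytosine_report(path: str | os.PathLike, min_coverage: int = 0) -> pd.DataFrame:
    """Read a 7-column per-cytosine methylation report.

    Columns: chrom, 1-based pos, strand, methylated count, unmethylated
    count, context (CG/CHG/CHH), trinucleotide. Keeps sites with coverage
    >= ``min_coverage``; order is preserved. Raises ``ValueError`` naming
    the offending line for malformed rows, unknown context tokens, or
    positions not sorted within a chromosome.
    """
    rows = []
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            chrom, pos_s, strand, nm_s, nu_s, context, tri = parts
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(nm_s), int(nu_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if strand not in "+-":
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ValueError(f"{path}: line {lineno}: unknown context token {context!r}")
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative count or position")
            if chrom in last and pos < last[chrom]:
                raise ValueError(f"{path}: line {lineno}: positions not sorted within {chrom}")
            last[chrom] = pos
            rows.append((chrom, pos, strand, n_meth, n_unmeth, context, tri))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if min_coverage > 0:
        df = df[df["n_meth"] + df["n_unmeth"] >= min_coverage].reset_index(drop=True)
    return df


def write_cytosine_report(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    sites.to_csv(path, sep="\t", header=False, index=False, columns=SITE_COLUMNS)


def sites_to_records(sites: pd.DataFrame) -> list[MethylationSite]:
    return [MethylationSite(*row) for row in sites[SITE_COLUMNS].itertuples(index=False)]


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Parse GFF3 gene models into :class:`GeneModel` objects.

    TSS/TES are derived strand-aware and introns as the gaps between
    exons; exon/UTR features are gathered across all mRNA children of
    each gene.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons: list[tuple[int, int]] = []
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        for f in db.children(g.id):
            iv = (f.start, f.end)
            if f.featuretype == "exon" and iv not in exons:
                exons.append(iv)
            elif f.featuretype == "five_prime_UTR" and iv not in utr5:
                utr5.append(iv)
            elif f.featuretype == "three_prime_UTR" and iv not in utr3:
                utr3.append(iv)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "?",
                start=g.start,
                end=g.end,
                exons=exons,
                five_prime_utr=sorted(utr5),
                three_prime_utr=sorted(utr3),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.five_prime_utr, 1):
                fh.write(
                    f"{g.chrom}\tsim\tfive_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.utr5p{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.three_prime_utr, 1):
                fh.write(
                    f"{g.chrom}\tsim\tthree_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.utr3p{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# TE annotations (BED)
# ---------------------------------------------------------------------------


def read_te_bed(path: str | os.PathLike) -> list[TEAnnotation]:
    """Read BED3+name TE annotations, converting to 1-based inclusive."""
    tes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 columns")
            chrom, start_s, end_s, name = parts[:4]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: degenerate interval start={start} end={end}"
                )
            tes.append(TEAnnotation(chrom=chrom, start=start + 1, end=end, family=name))
    return tes


def write_te_bed(tes: Iterable[TEAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for te in tes:
            fh.write(f"{te.chrom}\t{te.start - 1}\t{te.end}\t{te.family}\n")


# ---------------------------------------------------------------------------
# DMR BED6+
# ---------------------------------------------------------------------------

DMR_BED_EXTRA = ["n_dmc", "diff", "direction", "n_cg", "n_chg", "n_chh", "n_mc"]


def write_dmr_bed(dmrs: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write DMRs as BED6+ (0-based half-open; score = round(1000*|diff|))."""
    with open(path, "w") as fh:
        for row in dmrs.itertuples(index=False):
            score = int(round(1000 * abs(row.diff)))
            extras = "\t".join(
                [
                    str(int(row.n_dmc)),
                    f"{row.diff:.6g}",
                    row.direction,
                    str(int(row.n_cg)),
                    str(int(row.n_chg)),
                    str(int(row.n_chh)),
                    str(int(row.n_mc)) if pd.notna(row.n_mc) else "NA",
                ]
            )
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.comparison}\t"
                f"{score}\t.\t{extras}\n"
            )


def read_dmr_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a BED6+ DMR file written by :func:`write_dmr_bed`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            rows.append(
                dict(
                    chrom=p[0],
                    start=int(p[1]) + 1,
                    end=int(p[2]),
                    comparison=p[3],
                    n_dmc=int(p[6]),
                    diff=float(p[7]),
                    direction=p[8],
                    n_cg=int(p[9]),
                    n_chg=int(p[10]),
                    n_chh=int(p[11]),
                    n_mc=(np.nan if p[12] == "NA" else int(p[12])),
                )
            )
    cols = ["chrom", "start", "end", "comparison"] + DMR_BED_EXTRA
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# expression matrices and config
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x sample FPKM-scale abundance table (TSV, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative abundance value")
    return df


def write_expression_matrix(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_config(path: str | os.PathLike) -> dict[str, str]:
    """Flat ``key = value`` configuration; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg


def write_config(cfg: Mapping[str, object], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


def design_from_config(cfg: Mapping[str, str]) -> StudyDesign:
    """Build a :class:`StudyDesign` from flat config keys.

    Keys: ``group.<id> = s1,s2`` ; ``comparisons = G2vG1,G3vG2`` ;
    optional ``time.<sample> = hours``.
    """
    groups = {
        key.split(".", 1)[1]: [s.strip() for s in val.split(",")]
        for key, val in cfg.items()
        if key.startswith("group.")
    }
    comparisons = []
    for token in cfg.get("comparisons", "").split(","):
        token = token.strip()
        if not token:
            continue
        b, a = token.split("v")
        comparisons.append((a, b))
    times = {
        key.split(".", 1)[1]: float(val) for key, val in cfg.items() if key.startswith("time.")
    }
    return StudyDesign(groups=groups, comparisons=comparisons, timepoints=times)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a genome as ``{chrom: uppercase sequence}``."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
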