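"""Per-site and regional methylation arithmetic.

Covers sequence-context classification (CG/CHG/CHH, H = A, C or T),
methylation-level estimation with bisulfite non-conversion correction,
statistical calling of methylated positions against the conversion error
rate, methylation density, 3,000-bp/600-bp sliding-window aggregation,
genome summaries, and the clone-based amplicon estimator used for
BS-PCR validation.

A site's raw methylation level is ML = mC/(mC + umC). Because bisulfite
conversion is imperfect, a fraction r of truly unmethylated cytosines is
read as methylated; the corrected level deconvolves this error as
max(0, (ML - r)/(1 - r)), with r estimated from the unmethylated lambda
spike-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ConversionControl:
    """Read counts at cytosine reference positions of the lambda spike-in."""

    n_converted: int
    n_unconverted: int

    @property
    def total(self) -> int:
        return self.n_converted + self.n_unconverted


def classify_context(
    genome: Mapping[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """Sequence context of the cytosine at ``pos`` (1-based) on ``strand``.

    The context is read 5'->3' on the cytosine's own strand; on the minus
    strand this walks leftward over complemented bases. Returns None when
    fewer than two downstream bases exist or an N intervenes. Raises
    ``ValueError`` if the addressed base is not a C on that strand.
    """
    seq = genome[chrom]
    i = pos - 1
    if i < 0 or i >= len(seq):
        raise ValueError(f"position {pos} outside {chrom}")
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"{chrom}:{pos}:+ is {seq[i]!r}, not C")
        tri = seq[i : i + 3]
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(f"{chrom}:{pos}:- is {seq[i]!r} on +, not C on -")
        tri = seq[max(0, i - 2) : i + 1][::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"bad strand {strand!r}")
    if len(tri) < 3 or "N" in tri:
        return None
    return context_from_trinucleotide(tri)


def context_from_trinucleotide(tri: str) -> str:
    """CG if the next base is G; CHG if the base after next is G; else CHH."""
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def genome_cytosines(genome: Mapping[str, str]) -> pd.DataFrame:
    """All strand-specific cytosines of a genome with context/trinucleotide.

    Vectorized scan over both strands; cytosines too close to a chromosome
    end for a full trinucleotide, or with an intervening N, are skipped.
    """
    comp_lut = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp_lut[x] = y
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(arr)
        if n < 3:
            continue
        b0, b1, b2 = arr[:-2], arr[1:-1], arr[2:]
        valid = (b0 != ord("N")) & (b1 != ord("N")) & (b2 != ord("N"))
        # plus strand: C at offset i, trinucleotide seq[i:i+3]
        idx_p = np.nonzero((b0 == ord("C")) & valid)[0]
        ctx_p = np.where(b1[idx_p] == ord("G"), "CG",
                         np.where(b2[idx_p] == ord("G"), "CHG", "CHH"))
        tri_p = np.stack([b0[idx_p], b1[idx_p], b2[idx_p]], axis=1)
        # minus strand: a G on plus at offset i+2 is a C on minus whose
        # downstream bases are the complements of seq[i+1] and seq[i]
        idx_m = np.nonzero((b2 == ord("G")) & valid)[0]
        rc1, rc2 = comp_lut[b1[idx_m]], comp_lut[b0[idx_m]]
        ctx_m = np.where(rc1 == ord("G"), "CG",
                         np.where(rc2 == ord("G"), "CHG", "CHH"))
        tri_m = np.stack([np.full_like(rc1, ord("C")), rc1, rc2], axis=1)

        def _tri_strings(mat: np.ndarray) -> np.ndarray:
            return mat.astype(np.uint8).view("S3").ravel().astype("U3")

        f_p = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": idx_p + 1,
                "strand": "+",
                "context": ctx_p,
                "trinucleotide": _tri_strings(tri_p),
            }
        )
        f_m = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": idx_m + 3,
                "strand": "-",
                "context": ctx_m,
                "trinucleotide": _tri_strings(tri_m),
            }
        )
        both = pd.concat([f_p, f_m]).sort_values(["pos", "strand"], kind="stable")
        frames.append(both)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    return pd.concat(frames, ignore_index=True)


def methylation_level(n_meth, n_unmeth):
    """Raw level ML = mC/(mC+umC); NaN where coverage is zero.

    Accepts scalars or arrays.
    """
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        ml = np.where(cov > 0, n_meth / np.where(cov > 0, cov, 1.0), np.nan)
    if ml.ndim == 0:
        return float(ml)
    return ml


def estimate_nonconversion(control: ConversionControl) -> float:
    """Non-conversion rate: unconverted fraction at lambda cytosine positions."""
    if control.total <= 0:
        raise ValueError("conversion control has zero total reads")
    return control.n_unconverted / control.total


def correct_level(ml, r: float):
    """Deconvolve the non-conversion error: max(0, (ML - r)/(1 - r)).

    Identity at r=0; monotone nondecreasing in ML; floors at 0 so a site
    reading exactly at the error rate is reported unmethylated.
    """
    if r >= 1:
        raise ValueError("non-conversion rate must be < 1")
    if r < 0:
        raise ValueError("non-conversion rate must be >= 0")
    ml = np.asarray(ml, dtype=float)
    out = np.maximum(0.0, (ml - r) / (1.0 - r))
    if out.ndim == 0:
        return float(out)
    return out


def call_methylated_sites(
    sites: pd.DataFrame,
    r: float,
    alpha: float = 0.05,
    min_coverage: int = 5,
) -> pd.Series:
    """Flag positions whose counts exceed the conversion error rate.

    A position is called methylated iff coverage >= ``min_coverage`` and a
    one-sided binomial test of n_meth successes out of coverage against
    success probability ``r`` rejects at BH-adjusted q < ``alpha``. BH is
    applied over all positions passing the coverage gate.
    """
    from .differential import adjust_fdr

    if not 0 <= r < 1:
        raise ValueError("r must be in [0,1)")
    n_meth = sites["n_meth"].to_numpy()
    cov = n_meth + sites["n_unmeth"].to_numpy()
    testable = cov >= max(min_coverage, 1)
    flags = np.zeros(len(sites), dtype=bool)
    if testable.any():
        # one-sided upper tail P(X >= n_meth), X ~ Binomial(cov, r)
        p = stats.binom.sf(n_meth[testable] - 1, cov[testable], r)
        q = adjust_fdr(p)
        sub = flags[testable]
        sub[(q < alpha) & (n_meth[testable] > 0)] = True
        flags[testable] = sub
    return pd.Series(flags, index=sites.index, name="methylated")


def methylation_density(methylated_flags: Sequence[bool] | pd.Series) -> float:
    """Fraction of cytosine positions in a region called methylated."""
    flags = np.asarray(methylated_flags, dtype=bool)
    if flags.size == 0:
        return float("nan")
    return float(flags.mean())


def sliding_windows(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 3000,
    step: int = 600,
) -> pd.DataFrame:
    """Pool counts in sliding windows (defaults 3,000 bp / 600 bp step).

    Windows start at 1, 1+step, 1+2*step, ... on every chromosome; the
    final windows are truncated at the chromosome end. Output rows carry
    per-context pooled counts and levels plus an all-context pool.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out_frames = []
    max_span = -(-window // step)  # windows overlapping one position
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        n_windows = (length - 1) // step + 1
        starts = 1 + step * np.arange(n_windows)
        ends = np.minimum(starts + window - 1, length)
        acc: dict[str, np.ndarray] = {}
        for ctx in ("CG", "CHG", "CHH"):
            acc[f"n_meth_{ctx.lower()}"] = np.zeros(n_windows, dtype=np.int64)
            acc[f"n_unmeth_{ctx.lower()}"] = np.zeros(n_windows, dtype=np.int64)
        if len(sub):
            pos = sub["pos"].to_numpy()
            nm = sub["n_meth"].to_numpy()
            nu = sub["n_unmeth"].to_numpy()
            ctx_codes = sub["context"].to_numpy()
            i_max = (pos - 1) // step
            i_min = np.maximum(0, -(-(pos - window) // step))
            for j in range(max_span):
                i = i_max - j
                ok = i >= i_min
                for ctx in ("CG", "CHG", "CHH"):
                    sel = ok & (ctx_codes == ctx)
                    np.add.at(acc[f"n_meth_{ctx.lower()}"], i[sel], nm[sel])
                    np.add.at(acc[f"n_unmeth_{ctx.lower()}"], i[sel], nu[sel])
        frame = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, **acc})
        out_frames.append(frame)
    out = pd.concat(out_frames, ignore_index=True)
    for ctx in ("cg", "chg", "chh"):
        out[f"level_{ctx}"] = methylation_level(
            out[f"n_meth_{ctx}"], out[f"n_unmeth_{ctx}"]
        )
    out["n_meth"] = out[["n_meth_cg", "n_meth_chg", "n_meth_chh"]].sum(axis=1)
    out["n_unmeth"] = out[["n_unmeth_cg", "n_unmeth_chg", "n_unmeth_chh"]].sum(axis=1)
    out["level"] = methylation_level(out["n_meth"], out["n_unmeth"])
    return out


def genome_summary(
    sites: pd.DataFrame,
    methylated: pd.Series | None = None,
    r: float = 0.0,
) -> pd.DataFrame:
    """Per-context / per-chromosome methylation summary with genome rollups.

    For each (chromosome, context) cell and each rollup row: pooled
    coverage-weighted corrected level, number of sites, and — when
    ``methylated`` flags are supplied — the fraction of positions called
    methylated. Contexts absent from the input are simply absent from the
    table. Rollup rows use chrom/context label "all".
    """
    if sites.empty:
        raise ValueError("genome_summary requires a non-empty site table")
    work = sites[["chrom", "context", "n_meth", "n_unmeth"]].copy()
    if methylated is not None:
        work["methylated"] = np.asarray(methylated, dtype=bool)

    def _agg(group_cols: list[str]) -> pd.DataFrame:
        g = work.groupby(group_cols, observed=True)
        agg = g.agg(
            n_sites=("n_meth", "size"),
            n_meth=("n_meth", "sum"),
            n_unmeth=("n_unmeth", "sum"),
        ).reset_index()
        if methylated is not None:
            agg["fraction_methylated"] = g["methylated"].mean().to_numpy()
        return agg

    per_cc = _agg(["chrom", "context"])
    per_ctx = _agg(["context"])
    per_ctx.insert(0, "chrom", "all")
    per_chrom = _agg(["chrom"])
    per_chrom.insert(1, "context", "all")
    overall = pd.DataFrame(
        {
            "chrom": ["all"],
            "context": ["all"],
            "n_sites": [len(work)],
            "n_meth": [int(work["n_meth"].sum())],
            "n_unmeth": [int(work["n_unmeth"].sum())],
        }
    )
    if methylated is not None:
        overall["fraction_methylated"] = [float(work["methylated"].mean())]
    out = pd.concat([per_cc, per_ctx, per_chrom, overall], ignore_index=True)
    out["level"] = correct_level(
        methylation_level(out["n_meth"], out["n_unmeth"]), r
    )
    return out


def amplicon_methylation_level(clones: Sequence[str], reference: str) -> float:
    """Clone-based estimate: retained C at reference-C positions over clones.

    Each clone is a Sanger-sequenced bisulfite-PCR product aligned to the
    reference amplicon; a C that survives conversion marks methylation.
    """
    c_positions = [i for i, base in enumerate(reference) if base.upper() == "C"]
    if not c_positions:
        raise ValueError("reference amplicon contains no cytosine")
    kept = 0
    for clone in clones:
        if len(clone) != len(reference):
            raise ValueError("clone length differs from reference amplicon")
        kept += sum(1 for i in c_positions if clone[i].upper() == "C")
    return kept / (len(c_positions) * len(clones))
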