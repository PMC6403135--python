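"""Synthetic genomes, methylomes and expression with a planted-truth ledger.

Generates everything downstream stages consume — genome FASTA, gene GFF3,
TE BED, per-sample cytosine reports, lambda spike-in conversion counts,
and an FPKM-scale expression matrix — with every planted effect recorded
in a :class:`SimulationTruth` so parameter-recovery tests need no external
data.

The generative model, per strand-specific cytosine and sample:

* coverage ~ NegativeBinomial(mean=coverage_mean, dispersion k), the
  overdispersed count spread typical of WGBS;
* the true level is the context baseline (defaults: the leaf methylome
  means CG 0.4399, CHG 0.2984, CHH 0.1157) times a feature multiplier
  (TEs elevated, UTRs depressed, flanks mildly elevated, intergenic 1.0),
  plus any planted group-difference effect and a per-sample jitter;
* the observed methylated count ~ Binomial(coverage, level + (1-level)*r):
  non-conversion at rate r reads unmethylated molecules as methylated,
  which is exactly what the unmethylated lambda spike-in measures.

Planted differential regions are step changes: the effect switches on in
the onset group of a comparison and persists through later groups of the
chained design, so each planting induces a +delta difference in its own
comparison and a -delta difference in the following one; both induced
effects are recorded in the truth ledger.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import methylome_core as _core
from .io_formats import (
    GeneModel,
    StudyDesign,
    TEAnnotation,
    default_design,
)
from .methylome_core import ConversionControl

DEFAULT_BASELINES = {"CG": 0.4399, "CHG": 0.2984, "CHH": 0.1157}

DEFAULT_TE_FAMILIES = ("hAT", "CMC-EnSpm", "Gypsy", "Copia", "LINE/L1")

#: multiplicative modulation of the context baseline by feature class;
#: intergenic is the reference (1.0)
DEFAULT_FEATURE_MULTIPLIERS = {
    "intergenic": 1.0,
    "flank": 1.2,
    "exon": 0.8,
    "intron": 0.85,
    "utr": 0.4,
    "TE": 1.8,
    "TE:hAT": 2.2,
    "TE:CMC-EnSpm": 2.2,
}


@dataclass(frozen=True)
class PlantedDMR:
    """One induced differential effect: group b minus group a in a region."""

    comparison: str
    chrom: str
    start: int
    end: int
    contexts: tuple[str, ...]
    delta: float
    direction: str


@dataclass(frozen=True)
class PlantedRhythm:
    gene_id: str
    amplitude: float
    phase: float


@dataclass(frozen=True)
class PlantedCoupling:
    gene_id: str
    region: str
    sign: int


@dataclass
class SimulationTruth:
    """Ledger of every planted effect and the generative parameters."""

    baseline_levels: dict[str, float] = field(default_factory=dict)
    nonconversion_rate: float = 0.0
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    planted_rhythmic_genes: list[PlantedRhythm] = field(default_factory=list)
    planted_couplings: list[PlantedCoupling] = field(default_factory=list)

    _DMR_COLS = ["comparison", "chrom", "start", "end", "contexts", "delta", "direction"]
    _RHYTHM_COLS = ["gene_id", "amplitude", "phase"]
    _COUPLING_COLS = ["gene_id", "region", "sign"]

    def write(self, out_dir: str | os.PathLike) -> None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        dmrs = pd.DataFrame(
            [asdict(x) for x in self.planted_dmrs], columns=self._DMR_COLS
        )
        dmrs["contexts"] = dmrs["contexts"].map(lambda c: ",".join(c))
        dmrs.to_csv(os.path.join(out_dir, "planted_dmrs.tsv"), sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(
            [asdict(x) for x in self.planted_rhythmic_genes], columns=self._RHYTHM_COLS
        ).to_csv(os.path.join(out_dir, "planted_rhythms.tsv"), sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(
            [asdict(x) for x in self.planted_couplings], columns=self._COUPLING_COLS
        ).to_csv(os.path.join(out_dir, "planted_couplings.tsv"), sep="\t", index=False)
        manifest = {
            "baseline_levels": self.baseline_levels,
            "nonconversion_rate": self.nonconversion_rate,
        }
        with open(os.path.join(out_dir, "truth_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, out_dir: str | os.PathLike) -> "SimulationTruth":
        out_dir = str(out_dir)
        with open(os.path.join(out_dir, "truth_manifest.json")) as fh:
            manifest = json.load(fh)
        truth = cls(
            baseline_levels=manifest["baseline_levels"],
            nonconversion_rate=manifest["nonconversion_rate"],
        )
        dmrs = pd.read_csv(os.path.join(out_dir, "planted_dmrs.tsv"), sep="\t",
                           float_precision="round_trip")
        for row in dmrs.itertuples(index=False):
            truth.planted_dmrs.append(
                PlantedDMR(
                    comparison=row.comparison,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    contexts=tuple(row.contexts.split(",")),
                    delta=float(row.delta),
                    direction=row.direction,
                )
            )
        rhy = pd.read_csv(os.path.join(out_dir, "planted_rhythms.tsv"), sep="\t",
                          float_precision="round_trip")
        for row in rhy.itertuples(index=False):
            truth.planted_rhythmic_genes.append(
                PlantedRhythm(row.gene_id, float(row.amplitude), float(row.phase))
            )
        coup = pd.read_csv(os.path.join(out_dir, "planted_couplings.tsv"), sep="\t")
        for row in coup.itertuples(index=False):
            truth.planted_couplings.append(
                PlantedCoupling(row.gene_id, row.region, int(row.sign))
            )
        return truth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(
    n_chrom: int = 2,
    chrom_length: int = 200_000,
    n_genes: int = 100,
    n_tes: int = 40,
    te_families: Sequence[str] = DEFAULT_TE_FAMILIES,
    seed: int | np.random.Generator = 0,
    mean_gene_length: int = 2500,
    max_retries_factor: int = 200,
) -> tuple[dict[str, str], list[GeneModel], list[TEAnnotation]]:
    """Random genome with non-overlapping gene models and intergenic TEs.

    Sequence composition is uniform over ACGT. Genes carry 1-6 exons with
    terminal UTRs on both strands; TEs (200-2000 bp) are dropped into the
    space left between genes and labelled with families drawn from
    ``te_families``. Raises ``RuntimeError`` when the requested annotation
    load cannot be packed after bounded retries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome = {
        f"Chr{i + 1:02d}": "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=chrom_length)]
        )
        for i in range(n_chrom)
    }
    chroms = list(genome)
    placed: dict[str, list[tuple[int, int]]] = {ch: [] for ch in chroms}

    def _fits(ch: str, start: int, end: int, margin: int) -> bool:
        return all(
            end + margin < s or start - margin > e for s, e in placed[ch]
        )

    genes: list[GeneModel] = []
    attempts = 0
    max_attempts = max_retries_factor * max(n_genes, 1)
    while len(genes) < n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_genes} genes of mean span {mean_gene_length} "
                f"in {n_chrom} x {chrom_length} bp after {max_attempts} attempts"
            )
        length = int(rng.integers(mean_gene_length // 2, mean_gene_length * 3 // 2 + 1))
        ch = chroms[int(rng.integers(len(chroms)))]
        if chrom_length < length + 2:
            continue
        start = int(rng.integers(1, chrom_length - length + 1))
        end = start + length - 1
        if not _fits(ch, start, end, margin=200):
            continue
        placed[ch].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 7))
        exons = _partition_exons(rng, start, end, n_ex)
        utr5, utr3 = _terminal_utrs(rng, exons, strand)
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes) + 1:05d}",
                chrom=ch,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                five_prime_utr=utr5,
                three_prime_utr=utr3,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))

    tes: list[TEAnnotation] = []
    attempts = 0
    max_attempts = max_retries_factor * max(n_tes, 1)
    while len(tes) < n_tes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"could not place {n_tes} TEs after {max_attempts} attempts")
        length = int(rng.integers(200, 2001))
        ch = chroms[int(rng.integers(len(chroms)))]
        if chrom_length < length + 2:
            continue
        start = int(rng.integers(1, chrom_length - length + 1))
        end = start + length - 1
        if not _fits(ch, start, end, margin=0):
            continue
        placed[ch].append((start, end))
        family = te_families[int(rng.integers(len(te_families)))]
        tes.append(TEAnnotation(chrom=ch, start=start, end=end, family=family))
    tes.sort(key=lambda t: (t.chrom, t.start))
    return genome, genes, tes


def _partition_exons(
    rng: np.random.Generator, start: int, end: int, n_ex: int
) -> list[tuple[int, int]]:
    """Split [start, end] into n_ex exons separated by introns >= 30 bp."""
    length = end - start + 1
    min_exon, min_intron = 60, 30
    need = n_ex * min_exon + (n_ex - 1) * min_intron
    while n_ex > 1 and need > length:
        n_ex -= 1
        need = n_ex * min_exon + (n_ex - 1) * min_intron
    if n_ex == 1:
        return [(start, end)]
    spare = length - need
    cuts = np.sort(rng.integers(0, spare + 1, size=2 * n_ex - 2))
    pieces = np.diff(np.concatenate([[0], cuts, [spare]]))
    exons = []
    cursor = start
    for i in range(n_ex):
        exon_len = min_exon + int(pieces[2 * i])
        exons.append((cursor, cursor + exon_len - 1))
        cursor += exon_len
        if i < n_ex - 1:
            cursor += min_intron + int(pieces[2 * i + 1])
    # stretch the last exon to the gene end (rounding slack)
    exons[-1] = (exons[-1][0], end)
    return exons


def _terminal_utrs(
    rng: np.random.Generator, exons: list[tuple[int, int]], strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    first, last = exons[0], exons[-1]
    left_len = min(int(rng.integers(30, 151)), (first[1] - first[0] + 1) // 3)
    right_len = min(int(rng.integers(30, 151)), (last[1] - last[0] + 1) // 3)
    left = [(first[0], first[0] + left_len - 1)] if left_len > 0 else []
    right = [(last[1] - right_len + 1, last[1])] if right_len > 0 else []
    if strand == "+":
        return left, right
    return right, left


# ---------------------------------------------------------------------------
# planted differential regions
# ---------------------------------------------------------------------------


def plan_dmr_regions(
    genome: Mapping[str, str],
    design: StudyDesign,
    n_regions: int = 12,
    region_length: tuple[int, int] = (600, 1000),
    delta: float = 0.4,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
    seed: int | np.random.Generator = 0,
    min_separation: int = 2000,
) -> list[dict]:
    """Choose planted differential regions and their onset groups.

    Onset groups are drawn from the comparisons' later groups whose member
    samples serve in no other group, so a step change at the onset group
    induces exactly two differential effects (its own comparison and the
    opposite sign in the next one). Returns plant dicts consumed by
    :func:`simulate_methylome`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    multi = {
        s
        for s in design.samples
        if sum(s in members for members in design.groups.values()) > 1
    }
    onset_choices = [
        b for _, b in design.comparisons if not (set(design.groups[b]) & multi)
    ]
    if not onset_choices:
        raise ValueError("no comparison has an overlap-free onset group")
    chroms = list(genome)
    occupied: dict[str, list[tuple[int, int]]] = {ch: [] for ch in chroms}
    plants = []
    attempts = 0
    while len(plants) < n_regions:
        attempts += 1
        if attempts > 200 * n_regions:
            raise RuntimeError("could not place planted regions")
        length = int(rng.integers(region_length[0], region_length[1] + 1))
        ch = chroms[int(rng.integers(len(chroms)))]
        L = len(genome[ch])
        if L < length + 2:
            raise ValueError("planted region longer than chromosome")
        start = int(rng.integers(1, L - length + 1))
        end = start + length - 1
        if any(
            end + min_separation >= s and start - min_separation <= e
            for s, e in occupied[ch]
        ):
            continue
        occupied[ch].append((start, end))
        onset = onset_choices[int(rng.integers(len(onset_choices)))]
        sign = 1 if rng.random() < 0.5 else -1
        plants.append(
            dict(
                chrom=ch,
                start=start,
                end=end,
                onset_group=onset,
                delta=sign * delta,
                contexts=tuple(contexts),
            )
        )
    return plants


def _affected_samples(design: StudyDesign, onset_group: str) -> set[str]:
    """Samples carrying a step change that switches on at ``onset_group``.

    The step persists through later groups of the chain but stops before
    any group sharing samples with a pre-onset group (in the default
    design CL0 closes the free-running day by serving in both G1 and G5,
    so a step planted at G2..G4 stops before G5's CL0 would leak back
    into the G1 baseline).
    """
    order = list(design.groups)
    gi = order.index(onset_group)
    before = set().union(*(design.groups[g] for g in order[:gi])) if gi else set()
    affected: set[str] = set()
    for g in order[gi:]:
        members = set(design.groups[g])
        if members & before:
            break
        affected |= members
    return affected


def _induced_effects(design: StudyDesign, plant: dict) -> list[PlantedDMR]:
    """Truth records induced by one step-change planting.

    For each comparison (a, b) the induced difference is
    delta * (affected fraction of b - affected fraction of a); with
    whole-group steps these fractions are 0 or 1, so each planting yields
    a +delta effect where it switches on and a -delta effect where it
    switches off.
    """
    affected = _affected_samples(design, plant["onset_group"])
    effects = []
    for a, b in design.comparisons:
        fa = np.mean([s in affected for s in design.groups[a]])
        fb = np.mean([s in affected for s in design.groups[b]])
        d = plant["delta"] * (fb - fa)
        if abs(d) < 1e-12:
            continue
        effects.append(
            PlantedDMR(
                comparison=design.comparison_id(a, b),
                chrom=plant["chrom"],
                start=plant["start"],
                end=plant["end"],
                contexts=tuple(plant["contexts"]),
                delta=float(d),
                direction="hyper" if d > 0 else "hypo",
            )
        )
    return effects


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def simulate_methylome(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    tes: Sequence[TEAnnotation],
    design: StudyDesign | None = None,
    baseline_levels: Mapping[str, float] | None = None,
    planted_dmrs: Sequence[dict] | None = None,
    coverage_mean: float = 30.0,
    coverage_dispersion: float = 10.0,
    nonconversion_rate: float = 0.005,
    sample_jitter: float = 0.02,
    lambda_total: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, ConversionControl], SimulationTruth]:
    """Per-sample cytosine reports plus lambda controls and the truth ledger.

    Returns ``(sample_sites, lambda_controls, truth)`` where
    ``sample_sites[sample]`` is a site table in cytosine-report column
    order (zero-coverage sites included, as a reference-anchored report
    lists every cytosine).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = design or default_design()
    baselines = dict(DEFAULT_BASELINES if baseline_levels is None else baseline_levels)
    for ctx, lv in baselines.items():
        if not 0 <= lv <= 1:
            raise ValueError(f"baseline level for {ctx} outside [0,1]")
    if not 0 <= nonconversion_rate < 1:
        raise ValueError("nonconversion_rate must be in [0,1)")
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    planted = list(planted_dmrs or [])
    for plant in planted:
        if plant["chrom"] not in genome:
            raise ValueError(f"planted DMR on unknown chromosome {plant['chrom']}")
        if plant["start"] < 1 or plant["end"] > len(genome[plant["chrom"]]):
            raise ValueError("planted DMR outside the genome")
        if not 0 < abs(plant["delta"]) <= 1:
            raise ValueError("planted effect size must be in (0,1]")

    sites = _core.genome_cytosines(genome)
    base = sites["context"].map(baselines).to_numpy(dtype=float)
    mult = _feature_multipliers_per_site(sites, genes, tes, genome)
    level0 = np.clip(base * mult, 0.0, 0.995)

    sample_effect = {s: np.zeros(len(sites)) for s in design.samples}
    truth = SimulationTruth(
        baseline_levels=baselines, nonconversion_rate=nonconversion_rate
    )
    for plant in planted:
        affected_samples = _affected_samples(design, plant["onset_group"])
        in_region = (
            (sites["chrom"] == plant["chrom"]).to_numpy()
            & (sites["pos"].to_numpy() >= plant["start"])
            & (sites["pos"].to_numpy() <= plant["end"])
            & sites["context"].isin(plant["contexts"]).to_numpy()
        )
        for s in affected_samples:
            sample_effect[s][in_region] += plant["delta"]
        truth.planted_dmrs.extend(_induced_effects(design, plant))

    sample_sites: dict[str, pd.DataFrame] = {}
    lambda_controls: dict[str, ConversionControl] = {}
    r = nonconversion_rate
    nb_p = coverage_dispersion / (coverage_dispersion + coverage_mean)
    # between-sample jitter is variation around the cohort mean: centre the
    # draws so the cohort-pooled level stays at the planted baseline
    if sample_jitter > 0:
        offsets = rng.normal(0.0, sample_jitter, size=len(design.samples))
        offsets -= offsets.mean()
    else:
        offsets = np.zeros(len(design.samples))
    for sample, offset in zip(design.samples, offsets):
        level = np.clip(level0 + sample_effect[sample] + offset, 0.0, 0.999)
        p_obs = level + (1.0 - level) * r
        coverage = rng.negative_binomial(coverage_dispersion, nb_p, size=len(sites))
        n_meth = rng.binomial(coverage, p_obs)
        df = sites.copy()
        df["n_meth"] = n_meth
        df["n_unmeth"] = coverage - n_meth
        sample_sites[sample] = df[
            ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
        ]
        unconverted = int(rng.binomial(lambda_total, r))
        lambda_controls[sample] = ConversionControl(
            n_converted=lambda_total - unconverted, n_unconverted=unconverted
        )
    return sample_sites, lambda_controls, truth


def _feature_multipliers_per_site(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    tes: Sequence[TEAnnotation],
    genome: Mapping[str, str],
    multipliers: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Per-site level multiplier painted chromosome-wide by feature class.

    Painting order (later wins): intergenic, flank, intron, exon, UTR, TE.
    """
    m = dict(DEFAULT_FEATURE_MULTIPLIERS)
    if multipliers:
        m.update(multipliers)
    arrays = {
        ch: np.full(len(seq), m["intergenic"], dtype=float) for ch, seq in genome.items()
    }

    def paint(ch: str, start: int, end: int, value: float) -> None:
        arr = arrays[ch]
        arr[max(0, start - 1) : min(len(arr), end)] = value

    from .annotation import downstream_interval, promoter_interval

    for g in genes:
        L = len(genome[g.chrom])
        for iv in (promoter_interval(g, 2000, L), downstream_interval(g, 2000, L)):
            if iv:
                paint(g.chrom, iv[0], iv[1], m["flank"])
    for g in genes:
        for s, e in g.introns:
            paint(g.chrom, s, e, m["intron"])
        for s, e in g.exons:
            paint(g.chrom, s, e, m["exon"])
        for s, e in g.five_prime_utr + g.three_prime_utr:
            paint(g.chrom, s, e, m["utr"])
    for te in tes:
        paint(te.chrom, te.start, te.end, m.get(f"TE:{te.family}", m["TE"]))

    out = np.empty(len(sites), dtype=float)
    for ch, sub in sites.groupby("chrom", sort=False):
        out[sub.index.to_numpy()] = arrays[ch][sub["pos"].to_numpy() - 1]
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: Sequence[GeneModel] | Sequence[str],
    design: StudyDesign | None = None,
    rhythmic_fraction: float = 0.12,
    amplitude_range: tuple[float, float] = (0.75, 1.5),
    coupling: Mapping[str, object] | None = None,
    noise_sd: float = 0.25,
    seed: int | np.random.Generator = 0,
    gene_meth: Mapping[str, float] | None = None,
    mesor_mean: float = 4.0,
    mesor_sd: float = 1.5,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """FPKM-scale expression over the timed samples with planted truth.

    The model lives on the shifted log scale the analysis uses: for a
    ``rhythmic_fraction`` of genes,

        log2(FPKM + 1) = mesor + A*cos(2*pi*(t - phase)/24) + eps,

    with amplitude drawn from ``amplitude_range`` (log2 units), uniform
    phase, and i.i.d. Gaussian ``eps`` of SD ``noise_sd`` log2 units per
    sample (multiplicative lognormal noise on the shifted FPKM scale);
    flat genes have A = 0. Defining amplitude and noise on this scale
    keeps their ratio exact for the downstream detector. With
    ``coupling`` (keys ``region``, ``rho``, ``sign``) and ``gene_meth``,
    mesors are tied to the per-gene methylation level so that the latent
    rank correlation equals ``rho``; couplings are recorded in the truth
    ledger.
    """
    if not 0 <= rhythmic_fraction <= 1:
        raise ValueError("rhythmic_fraction must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = design or default_design()
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    samples = design.samples
    t = np.array([design.timepoints[s] for s in samples], dtype=float)
    n = len(gene_ids)

    truth = SimulationTruth()
    z_noise = rng.normal(size=n)
    if coupling is not None:
        if gene_meth is None:
            raise ValueError("coupling requires gene_meth levels")
        rho_s = float(coupling.get("rho", 0.5))
        sign = int(coupling.get("sign", 1))
        region = str(coupling.get("region", "gene_body"))
        # bivariate-normal Pearson value whose Spearman correlation is rho_s
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        meth = np.array([gene_meth.get(gid, np.nan) for gid in gene_ids])
        ranks = pd.Series(meth).rank().to_numpy()
        z_m = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
        z = sign * rho_p * z_m + np.sqrt(max(0.0, 1 - rho_p**2)) * z_noise
        truth.planted_couplings.extend(
            PlantedCoupling(gid, region, sign) for gid in gene_ids
        )
    else:
        z = z_noise
    mesor = mesor_mean + mesor_sd * z

    is_rhythmic = rng.random(n) < rhythmic_fraction
    amplitude = np.where(
        is_rhythmic, rng.uniform(amplitude_range[0], amplitude_range[1], size=n), 0.0
    )
    phase = rng.uniform(0, 24, size=n)
    omega = 2 * np.pi / 24.0
    signal = mesor[:, None] + amplitude[:, None] * np.cos(
        omega * (t[None, :] - phase[:, None])
    )
    log2_expr = signal + rng.normal(0.0, noise_sd, size=(n, len(samples)))
    expr = pd.DataFrame(
        np.clip(2.0**log2_expr - 1.0, 0.0, None),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    truth.planted_rhythmic_genes.extend(
        PlantedRhythm(gid, float(a), float(ph))
        for gid, a, ph, rhy in zip(gene_ids, amplitude, phase, is_rhythmic)
        if rhy
    )
    return expr, truth
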