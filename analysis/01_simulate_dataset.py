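#!/usr/bin/env python
"""Simulate the full study dataset: genome, annotations, methylomes, expression.

Generates a 2 x 200-kb genome with 100 genes and 40 TEs, nine per-sample
cytosine reports under the five-group light/dark -> continuous-light
design with 12 planted differential regions (delta = 0.4), lambda
spike-in controls, and a 2,000-gene expression matrix with 12% planted
24-h cosines and positive gene-body methylation coupling. Everything is
written under results/dataset/ in the exact formats the downstream
scripts read, together with the planted-truth ledger.
"""

import argparse
import json
import os

import numpy as np

import diurnalmeth as dm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/dataset")
    args = ap.parse_args()
    out = args.out_dir
    os.makedirs(out, exist_ok=True)

    ss = np.random.SeedSequence(args.seed)
    s_genome, s_plant, s_meth, s_expr = [int(x) % (2**31 - 1) for x in ss.generate_state(4)]

    genome, genes, tes = dm.synthetic_data.simulate_genome(
        n_chrom=2, chrom_length=200_000, n_genes=100, n_tes=40, seed=s_genome
    )
    design = dm.default_design()
    plants = dm.synthetic_data.plan_dmr_regions(
        genome, design, n_regions=12, delta=0.4, seed=s_plant
    )
    sites, controls, truth = dm.synthetic_data.simulate_methylome(
        genome, genes, tes, design, planted_dmrs=plants, coverage_mean=30, seed=s_meth
    )

    gene_meth = dm.pipeline.true_gene_body_levels(
        genes, dm.differential.pool_group_counts(sites, design.samples)
    )
    expr, expr_truth = dm.synthetic_data.simulate_expression(
        genes,
        design,
        rhythmic_fraction=0.12,
        coupling={"region": "gene_body", "rho": 0.5, "sign": 1},
        gene_meth=gene_meth,
        seed=s_expr,
    )
    truth.planted_rhythmic_genes = expr_truth.planted_rhythmic_genes
    truth.planted_couplings = expr_truth.planted_couplings

    dm.io_formats.write_genome_fasta(genome, f"{out}/genome.fa")
    dm.io_formats.write_gene_models(genes, f"{out}/genes.gff3")
    dm.io_formats.write_te_bed(tes, f"{out}/tes.bed")
    for sample, df in sites.items():
        dm.io_formats.write_cytosine_report(df, f"{out}/{sample}.cytosine_report.tsv")
    dm.io_formats.write_expression_matrix(expr, f"{out}/expression.tsv")
    truth.write(f"{out}/truth")
    with open(f"{out}/lambda_controls.json", "w") as fh:
        json.dump(
            {s: [c.n_converted, c.n_unconverted] for s, c in controls.items()}, fh, indent=1
        )
    dm.io_formats.write_config(
        {
            "seed": args.seed,
            "coverage_mean": 30,
            "n_planted_regions": 12,
            "delta": 0.4,
            **{f"group.{g}": ",".join(m) for g, m in design.groups.items()},
            "comparisons": ",".join(dm.default_design().comparison_id(a, b) for a, b in design.comparisons),
            **{f"time.{s}": design.timepoints[s] for s in design.samples},
        },
        f"{out}/config.txt",
    )
    n_sites = len(next(iter(sites.values())))
    print(f"wrote {len(sites)} cytosine reports ({n_sites} sites each), "
          f"{len(genes)} genes, {len(tes)} TEs, {len(plants)} planted regions -> {out}")


if __name__ == "__main__":
    main()
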