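#!/usr/bin/env python
"""Feature annotation of the methylome and of the differential calls.

Decomposes the genome into promoters (2 kb upstream of the TSS), UTRs,
exons, introns, 2-kb flanks, TE families and intergenic space; writes
per-feature corrected methylation levels by context, the primary-label
composition of DMRs and DMCs, and the differentially methylated genes
(body or promoter overlapping a DMR).
"""

import argparse
import json

import pandas as pd

import diurnalmeth as dm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="results/dataset")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    cfg = dm.io_formats.read_config(f"{args.data_dir}/config.txt")
    design = dm.io_formats.design_from_config(cfg)
    genome = dm.io_formats.read_genome_fasta(f"{args.data_dir}/genome.fa")
    genes = dm.io_formats.read_gene_models(f"{args.data_dir}/genes.gff3")
    tes = dm.io_formats.read_te_bed(f"{args.data_dir}/tes.bed")
    sites = {
        s: dm.io_formats.read_cytosine_report(f"{args.data_dir}/{s}.cytosine_report.tsv")
        for s in design.samples
    }
    with open(f"{args.data_dir}/lambda_controls.json") as fh:
        controls = {
            s: dm.methylome_core.ConversionControl(*v) for s, v in json.load(fh).items()
        }
    r = dm.pipeline.pooled_nonconversion_rate(controls)
    lengths = {ch: len(s) for ch, s in genome.items()}
    index = dm.annotation.FeatureIndex(genes, tes, lengths)

    pooled = dm.differential.pool_group_counts(sites, design.samples)
    profile = dm.annotation.feature_methylation_profile(pooled, index, r=r)
    profile.to_csv(f"{args.out_dir}/feature_levels.tsv", sep="\t", index=False)

    dmrs = pd.read_csv(f"{args.out_dir}/dmrs.tsv", sep="\t")
    dmcs = pd.read_csv(f"{args.out_dir}/dmcs.tsv", sep="\t")
    dmr_comp = dm.annotation.feature_composition(dm.annotation.assign_features(dmrs, index))
    dmc_comp = dm.annotation.feature_composition(dm.annotation.assign_features(dmcs, index))
    dmr_comp.to_csv(f"{args.out_dir}/dmr_feature_composition.tsv", sep="\t", index=False)
    dmc_comp.to_csv(f"{args.out_dir}/dmc_feature_composition.tsv", sep="\t", index=False)

    links = dm.annotation.differentially_methylated_genes(dmrs, genes, index)
    links.to_csv(f"{args.out_dir}/dm_genes.tsv", sep="\t", index=False)

    cg = profile[profile["context"] == "CG"].set_index("feature")["level"]
    shown = [f for f in ("upstream2k", "exon", "intron", "five_prime_utr") if f in cg]
    print("CG level by feature:",
          ", ".join(f"{f} {100 * cg[f]:.1f}%" for f in shown))
    te_rows = cg[[f for f in cg.index if f.startswith("TE:")]]
    if len(te_rows):
        print("TE families:",
              ", ".join(f"{f[3:]} {100 * v:.1f}%" for f, v in te_rows.items()))
    print(f"{links['gene_id'].nunique()} differentially methylated genes "
          f"({len(links)} gene-DMR links)")


if __name__ == "__main__":
    main()
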