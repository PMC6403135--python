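#!/usr/bin/env python
"""Genome-wide methylome description: levels, methylated sites, windows.

Reads the per-sample cytosine reports, estimates the bisulfite
non-conversion rate from the lambda spike-ins, and writes per-context /
per-chromosome corrected level summaries, binomial methylated-position
calls, and the 3,000-bp / 600-bp sliding-window level track.
"""

import argparse
import json

import diurnalmeth as dm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="results/dataset")
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--min-coverage", type=int, default=5)
    args = ap.parse_args()

    cfg = dm.io_formats.read_config(f"{args.data_dir}/config.txt")
    design = dm.io_formats.design_from_config(cfg)
    genome = dm.io_formats.read_genome_fasta(f"{args.data_dir}/genome.fa")
    sites = {
        s: dm.io_formats.read_cytosine_report(f"{args.data_dir}/{s}.cytosine_report.tsv")
        for s in design.samples
    }
    with open(f"{args.data_dir}/lambda_controls.json") as fh:
        controls = {
            s: dm.methylome_core.ConversionControl(*v) for s, v in json.load(fh).items()
        }
    r = dm.pipeline.pooled_nonconversion_rate(controls)

    pooled = dm.differential.pool_group_counts(sites, design.samples)
    flags = dm.methylome_core.call_methylated_sites(
        pooled, r=r, min_coverage=args.min_coverage
    )
    summary = dm.methylome_core.genome_summary(pooled, methylated=flags, r=r)
    summary.to_csv(f"{args.out_dir}/genome_summary.tsv", sep="\t", index=False)

    lengths = {ch: len(s) for ch, s in genome.items()}
    windows = dm.methylome_core.sliding_windows(pooled, lengths)
    windows.to_csv(f"{args.out_dir}/windows_3000_600.tsv", sep="\t", index=False)

    rows = summary[summary["chrom"] == "all"].set_index("context")
    print(f"non-conversion rate: {100 * r:.3f}%")
    for ctx in ("CG", "CHG", "CHH"):
        print(
            f"{ctx}: mean corrected level {100 * rows.loc[ctx, 'level']:.2f}% "
            f"({int(rows.loc[ctx, 'n_sites'])} sites, "
            f"{100 * rows.loc[ctx, 'fraction_methylated']:.1f}% called methylated)"
        )
    print(f"wrote genome_summary.tsv and windows_3000_600.tsv -> {args.out_dir}")


if __name__ == "__main__":
    main()
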