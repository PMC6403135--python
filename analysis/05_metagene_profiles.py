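#!/usr/bin/env python
"""Metagene profiles of DMC and DMR density around gene models.

Aligns all genes at TSS/TES, cuts each 2-kb flank into 20 fixed
100-bp bins and the body into 20 proportional bins, and writes the
per-bin density of DMCs and DMRs plus the mean site-level methylation
profile.
"""

import argparse

import pandas as pd

import diurnalmeth as dm
from diurnalmeth.methylome_core import correct_level, methylation_level


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="results/dataset")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    genes = dm.io_formats.read_gene_models(f"{args.data_dir}/genes.gff3")
    cfg = dm.io_formats.read_config(f"{args.data_dir}/config.txt")
    design = dm.io_formats.design_from_config(cfg)

    dmcs = pd.read_csv(f"{args.out_dir}/dmcs.tsv", sep="\t")
    dmrs = pd.read_csv(f"{args.out_dir}/dmrs.tsv", sep="\t")
    prof_dmc = dm.annotation.metagene_profile(dmcs, genes)
    prof_dmr = dm.annotation.metagene_profile(dmrs, genes)
    prof_dmc.to_csv(f"{args.out_dir}/metagene_dmc.tsv", sep="\t", index=False)
    prof_dmr.to_csv(f"{args.out_dir}/metagene_dmr.tsv", sep="\t", index=False)

    sites = {
        s: dm.io_formats.read_cytosine_report(f"{args.data_dir}/{s}.cytosine_report.tsv")
        for s in design.samples
    }
    pooled = dm.differential.pool_group_counts(sites, design.samples)
    pooled["level"] = correct_level(
        methylation_level(pooled["n_meth"], pooled["n_unmeth"]), 0.0
    )
    prof_level = dm.annotation.metagene_profile(
        pooled.dropna(subset=["level"]), genes, value="level"
    )
    prof_level.to_csv(f"{args.out_dir}/metagene_level.tsv", sep="\t", index=False)

    for name, prof in (("DMC", prof_dmc), ("DMR", prof_dmr)):
        seg = prof.groupby("segment")["density"].mean()
        print(
            f"{name} density per bp per gene: upstream {seg.get('upstream', 0):.2e}, "
            f"body {seg.get('body', 0):.2e}, downstream {seg.get('downstream', 0):.2e}"
        )
    print("wrote metagene_dmc.tsv, metagene_dmr.tsv, metagene_level.tsv")


if __name__ == "__main__":
    main()
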