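#!/usr/bin/env python
"""Patterns of variation: per-locus synonymous statistics.

Applies the Var-dataset rules (12x depth, GQ 20, outgroup aligned, 70% ORF
coverage in >= 3 individuals per species, density and paralog exclusions) to
the simulated dataset, then computes per-locus pi, Watterson's theta,
Tajima's D, F_ST, d_XY, d_A and the private/shared/fixed SNP categories at
synonymous sites.

Reads results/data/, writes results/variation/.
"""

from pathlib import Path

import pandas as pd

from newtflow.builder import read_dataset, var_alignments
from newtflow.sumstats import locus_stats, summarize_dataset

data = read_dataset("results/data/dataset.vcf", "results/data/loci.tsv",
                    "results/data/samples.tsv")
alignments = var_alignments(data, categories=("synonymous",))
stats = [locus_stats(g, s, name) for name, (g, s) in alignments.items()]
summary = summarize_dataset(stats)

out = Path("results/variation")
out.mkdir(parents=True, exist_ok=True)
pd.DataFrame([s.as_dict() for s in stats]).to_csv(
    out / "locus_stats.tsv", sep="\t", index=False)
summary["statistics"].to_csv(out / "summary.tsv", sep="\t", index=False)

tab = summary["statistics"].set_index("statistic")
print(f"analyzed {len(stats)} loci at synonymous sites")
for label, key in [("pi(Lv)", "pi_1"), ("pi(Lm)", "pi_2"),
                   ("thetaW(Lv)", "thetaw_1"), ("thetaW(Lm)", "thetaw_2"),
                   ("F_ST", "fst"), ("d_XY", "dxy"), ("d_A", "da")]:
    print(f"  {label:11s} {tab.loc[key, 'mean']:.4f} "
          f"+/- {tab.loc[key, 'sd']:.4f} (n={int(tab.loc[key, 'n_loci'])})")
cats, pct = summary["snp_categories"], summary["snp_percent"]
print(f"  SNPs: {summary['snp_total']} "
      f"(Sf {pct['sf']:.1f}%, Ss {pct['ss']:.1f}%, "
      f"Sx_Lv {pct['sx1']:.1f}%, Sx_Lm {pct['sx2']:.1f}%)")
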