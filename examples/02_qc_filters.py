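"""Paralog detection and region exclusion on contaminated genotype data.

Simulates a clean targeted-sequencing genotype matrix, injects 10%
collapsed-paralog sites (every individual apparently heterozygous, with
skewed pooled read ratios), and runs the HDplot filter plus the windowed
region rule.  Prints the recall and the excluded regions.
"""

import numpy as np

import glacialsfs as g
from glacialsfs.qcfilters import flag_paralog_sites, hdplot, paralog_window_filter

clean = g.simulate_genotype_matrix(
    g.Demography(((2e4, 0.0),)), n_ind=25, L=1e5, mu=1e-7, seed=1, reps=250
)
gm, reads = g.inject_paralogs(clean, prop=0.10, depth=25, seed=2)

stats = hdplot(gm, reads)
flags = flag_paralog_sites(stats)  # H > 0.6 or |D| > 20
truth = gm.paralog_mask
print(f"sites: {gm.n_sites}, injected paralogs: {truth.sum()}")
print(f"flagged: {flags.sum()}, recall: {flags[truth].mean():.3f}, "
      f"false-flag rate: {flags[~truth].mean():.4f}")

excluded, regions = paralog_window_filter(gm.positions, flags, contig=gm.contig)
print(f"window rule (>10% paralogs within 250 bp): {excluded.sum()} SNPs excluded "
      f"in {len(regions)} regions")
print("first regions (0-based half-open):", regions.regions[:3])
# region limits sit at mid-distance between the last paralog and the
# next retained SNP, so monomorphic accounting can use the same mask
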