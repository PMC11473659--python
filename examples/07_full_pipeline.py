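"""End-to-end pipeline run from a VCF.

Writes a synthetic two-population VCF (with injected paralogs and
missing data), then runs the configured stages -- INFO/genotype/paralog
filters, per-population folded SFS, diversity -- and lists the artifact
files with the diversity table.
"""

import tempfile
from pathlib import Path

import glacialsfs as g
from glacialsfs import io as gio
from glacialsfs.pipeline import PipelineConfig, run_pipeline

work = Path(tempfile.mkdtemp(prefix="glacialsfs_"))
gm = g.simulate_genotype_matrix(
    g.Demography(((1e4, 0.0),)), n_ind=12, L=5e4, mu=1e-7,
    missing_rate=0.05, seed=31, reps=100,
)
gm, reads = g.inject_paralogs(gm, prop=0.05, depth=30, seed=32)
vcf = work / "cohort.vcf"
gio.write_vcf(gm, vcf, reads)
print("wrote", vcf)

cfg = PipelineConfig(vcf=str(vcf), out_dir=str(work / "out"), seed=5,
                     pi_resamples=200, l_total=5e4)  # surveyed bp incl. monomorphic
out = run_pipeline(cfg)
print("artifacts:", sorted(p.name for p in out.iterdir()))
print((out / "diversity.tsv").read_text())
# pi_projected is the deterministic hypergeometric value; pi_resampled
# averages stochastic down-sampling replicates of the same data
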