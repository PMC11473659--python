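"""Pipeline configuration and the end-to-end stage runner.

Stage order mirrors the analysis workflow: variant/genotype filtering,
folded-SFS construction, diversity and spatial statistics, demographic
model fitting, and (when trajectory inputs are available) the
synchronicity test.  Every threshold defaults to the study value, all
applied thresholds and removed-site counts are logged, and outputs are
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from . import qcfilters, sfs as sfsmod, spatial
from .core import FoldedSFS

logger = logging.getLogger("glacialsfs")

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    """Plain key-value configuration with study-default thresholds."""

    vcf: str = ""
    pop_map: str = ""  # optional TSV: sample <tab> population
    l_total: float = 0.0  # surveyed sites incl. monomorphic; 0 = variant count
    coords: str = ""
    out_dir: str = "glacialsfs_out"
    seed: int = 0
    # stage toggles
    run_filter: bool = True
    run_sfs: bool = True
    run_diversity: bool = True
    run_spatial: bool = True
    run_demography: bool = False
    # genotype/site filters
    dp_min: int = 8
    gq_min: int = 20
    site_missing_max: float = 0.5
    qd_min: float = 0.25
    qual_min: float = 20.0
    sor_max: float = 3.0
    mq_min: float = 30.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    # paralog detection
    h_max: float = 0.6
    d_abs: float = 20.0
    paralog_window: int = 250
    paralog_frac: float = 0.10
    # scaling
    mu: float = 7.77e-9
    gen_time_years: float = 15.0
    # diversity
    pi_resamples: int = 1000
    # demography stage sizing
    fit_n_starts: int = 100

    def to_file(self, path) -> None:
        lines = [f"#glacialsfs-config v{CONFIG_VERSION}"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import ast

        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = ast.literal_eval(value.strip())
        return cls(**kwargs)


def _info_thresholds(cfg: PipelineConfig) -> dict:
    return {
        "QD": (cfg.qd_min, "lt"),
        "QUAL": (cfg.qual_min, "lt"),
        "SOR": (cfg.sor_max, "gt"),
        "MQ": (cfg.mq_min, "lt"),
        "MQRankSum": (cfg.mqranksum_min, "lt"),
        "ReadPosRankSum": (cfg.readposranksum_min, "lt"),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages on a VCF; returns the artifact directory.

    Halts with the stage name on failure; downstream stages that depend
    on a disabled stage raise an informative error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    stage = "input"
    try:
        pop_map = None
        if config.pop_map:
            pop_map = dict(
                line.split("\t")[:2]
                for line in Path(config.pop_map).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            )
        gm, reads = gio.read_vcf(config.vcf, pop_map=pop_map,
                                 l_total=config.l_total or None)
        logger.info("loaded %d sites, %d individuals (%d multiallelic dropped)",
                    gm.n_sites, gm.n_ind, getattr(gm, "n_multiallelic_dropped", 0))

        filtered = gm
        if config.run_filter:
            stage = "filter"
            keep = qcfilters.site_info_filter(gm.info, _info_thresholds(config))
            logger.info("INFO filter: removed %d of %d sites (thresholds %s)",
                        int((~keep).sum()), gm.n_sites, _info_thresholds(config))
            if len(reads):
                stats = qcfilters.hdplot(gm, reads)
                flags = qcfilters.flag_paralog_sites(stats, config.h_max, config.d_abs)
                excluded, regions = qcfilters.paralog_window_filter(
                    gm.positions, flags, config.paralog_window, config.paralog_frac,
                    contig=gm.contig,
                )
                gio.write_bed(regions, out / "paralog_regions.bed")
                logger.info("HDplot: %d flagged, %d excluded in %d regions",
                            int(flags.sum()), int(excluded.sum()), len(regions))
                keep &= ~excluded
            filtered = gm.subset_sites(keep)
            n_before = filtered.n_sites
            filtered = qcfilters.genotype_filter(
                filtered, config.dp_min, config.gq_min, config.site_missing_max
            )
            logger.info("genotype filter DP<%d/GQ<%d, >%d%% missing: removed %d sites",
                        config.dp_min, config.gq_min,
                        int(100 * config.site_missing_max), n_before - filtered.n_sites)

        spectra = {}
        if config.run_sfs:
            stage = "sfs"
            for pop in pd.unique(filtered.pop):
                sub = filtered.subset_individuals(filtered.pop == pop)
                spectrum = sfsmod.build_folded_sfs(sub, max_missing=config.site_missing_max)
                spectra[pop] = spectrum
                gio.write_sfs_obs(spectrum, out / f"sfs_{pop}.obs")
                gio.write_sfs_tsv(spectrum, out / f"sfs_{pop}.tsv")

        if config.run_diversity:
            stage = "diversity"
            if not spectra:
                raise RuntimeError("diversity stage needs the sfs stage enabled")
            rows = []
            for pop, spectrum in spectra.items():
                pi_det = sfsmod.pi_from_sfs(spectrum)
                sub = filtered.subset_individuals(filtered.pop == pop)
                pi_res = sfsmod.resampled_pi(
                    sub, n_reps=config.pi_resamples, seed=config.seed,
                    max_missing=config.site_missing_max,
                )
                rows.append({"pop": pop, "pi_projected": pi_det, "pi_resampled": pi_res,
                             "S": spectrum.segregating, "L": spectrum.L, "n": spectrum.n})
            pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)

        if config.run_spatial:
            stage = "spatial"
            pops = list(pd.unique(filtered.pop))
            if len(pops) >= 2:
                fst = spatial.pairwise_fst(filtered, pops)
                gio.write_fst_tsv(fst, out / "fst.tsv")
                if config.coords:
                    coords = gio.read_coords_tsv(config.coords)
                    fit = spatial.ibd_regression(fst, coords)
                    pd.DataFrame(
                        [{"beta": fit.beta, "alpha": fit.alpha, "r2": fit.r2}]
                    ).to_csv(out / "ibd.tsv", sep="\t", index=False)
                    spatial.scaled_population_fst(fst, coords).to_csv(
                        out / "scaled_fst.tsv", sep="\t", header=True
                    )
            else:
                logger.info("spatial stage skipped: fewer than two populations")

        if config.run_demography:
            stage = "demography"
            if not spectra:
                raise RuntimeError("demography stage needs the sfs stage enabled")
            from . import demography as demo

            rows = []
            for pop, spectrum in spectra.items():
                fits = [
                    demo.fit_epoch_model(
                        spectrum, m, config.mu, n_starts=config.fit_n_starts,
                        seed=config.seed,
                    )
                    for m in demo.EPOCH_MODELS
                ]
                table = demo.compare_models_aic(fits)
                best = table.iloc[0]["model"]
                for f in fits:
                    rows.append({"pop": pop, "model": f.model_name, "loglik": f.loglik,
                                 "aic": f.aic, "best": f.model_name == best, **f.params})
            pd.DataFrame(rows).to_csv(out / "epoch_fits.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
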