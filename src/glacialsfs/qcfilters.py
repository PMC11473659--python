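"""Variant-, genotype- and region-level quality filters.

Three layers mirror a standard short-read SNP-calling cleanup:

* site-level caller-annotation thresholds (QD, QUAL, SOR, MQ, MQRankSum,
  ReadPosRankSum), strict inequalities;
* genotype-level masking of low-depth / low-quality calls (DP < 8 or
  GQ < 20 set missing) and removal of sites with > 50% missing calls;
* paralog detection with HDplot (heterozygote excess H and pooled
  read-ratio deviation D) followed by a windowed exclusion of regions
  dense in paralog-derived SNPs, with region limits at mid-distance
  between the last excluded paralog and the next retained SNP.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ExclusionRegions,
    GenotypeMatrix,
    HDplotStats,
    ReadCountTable,
)

__all__ = [
    "site_info_filter",
    "genotype_filter",
    "hdplot",
    "flag_paralog_sites",
    "paralog_window_filter",
    "INFO_THRESHOLDS",
]

# threshold, direction ("lt" fails when value < threshold, "gt" when >)
INFO_THRESHOLDS = {
    "QD": (0.25, "lt"),
    "QUAL": (20.0, "lt"),
    "SOR": (3.0, "gt"),
    "MQ": (30.0, "lt"),
    "MQRankSum": (-12.5, "lt"),
    "ReadPosRankSum": (-8.0, "lt"),
}


def site_info_filter(
    info: pd.DataFrame,
    thresholds: Optional[dict] = None,
    missing_passes: bool = True,
) -> np.ndarray:
    """Keep-mask over sites from caller INFO annotations.

    A site fails when any annotation violates its strict threshold
    (QD < 0.25, QUAL < 20, SOR > 3.0, MQ < 30, MQRankSum < -12.5,
    ReadPosRankSum < -8.0).  Values exactly at a threshold pass.  Missing
    annotations pass by default (callers omit the rank-sum statistics at
    sites without both genotype classes); set ``missing_passes=False`` to
    fail them instead.
    """
    if thresholds is None:
        thresholds = INFO_THRESHOLDS
    keep = np.ones(len(info), dtype=bool)
    for col, (thr, direction) in thresholds.items():
        if col not in info.columns:
            continue
        v = info[col].to_numpy(dtype=float)
        isna = np.isnan(v)
        bad = (v < thr) if direction == "lt" else (v > thr)
        bad &= ~isna
        if not missing_passes:
            bad |= isna
        keep &= ~bad
    return keep


def genotype_filter(
    gm: GenotypeMatrix,
    dp_min: int = 8,
    gq_min: int = 20,
    site_missing_max: float = 0.5,
) -> GenotypeMatrix:
    """Mask low-quality calls and drop sites with excess missingness.

    Calls with DP < ``dp_min`` or GQ < ``gq_min`` become missing (strict
    inequalities: DP = 8, GQ = 20 are retained); sites whose missing
    fraction then exceeds ``site_missing_max`` are dropped.  The same
    masking rule applies to monomorphic positions when accounting for the
    available genome, which callers report through ``L_total``.
    """
    geno = gm.genotypes.copy()
    fail = (gm.dp < dp_min) | (gm.gq < gq_min)
    geno[fail] = MISSING
    miss_frac = (geno == MISSING).mean(axis=0)
    keep = miss_frac <= site_missing_max
    out = GenotypeMatrix(
        genotypes=geno,
        dp=gm.dp,
        gq=gm.gq,
        positions=gm.positions,
        info=gm.info,
        site_class=gm.site_class,
        pop=gm.pop,
        L_total=gm.L_total,
        contig=gm.contig,
        l_by_class=gm.l_by_class,
    )
    return out.subset_sites(keep)


def hdplot(gm: GenotypeMatrix, reads: ReadCountTable) -> HDplotStats:
    """Per-site heterozygote excess H and read-ratio deviation D.

    H is the heterozygote fraction among non-missing calls.  D pools the
    allele-specific reads of all heterozygotes at the site and measures
    the deviation from the expected 1:1 ratio as a binomial z-score,
    D = (A - B) / sqrt(A + B).  Sites with no non-missing calls, or no
    heterozygote reads, get NaN and are never flagged.
    """
    if len(reads) == 0 and (gm.genotypes == 1).any():
        raise ValueError(
            "no allele-specific read counts available (empty read-count table); "
            "HDplot needs AD-style counts for heterozygous calls"
        )
    geno = gm.genotypes
    called = (geno != MISSING).sum(axis=0).astype(float)
    het = (geno == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(called > 0, het / called, np.nan)
    a, b = reads.site_read_sums(gm.n_sites)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, (a - b) / np.sqrt(tot), np.nan)
    return HDplotStats(h=h, d=d)


def flag_paralog_sites(
    stats: HDplotStats, h_max: float = 0.6, d_abs: float = 20.0
) -> np.ndarray:
    """Flag putative paralog-derived SNPs: H > ``h_max`` or |D| > ``d_abs``.

    Inequalities are strict; sites with undefined statistics are never
    flagged on that statistic.
    """
    h_bad = np.where(np.isnan(stats.h), False, stats.h > h_max)
    d_bad = np.where(np.isnan(stats.d), False, np.abs(stats.d) > d_abs)
    flagged = h_bad | d_bad
    stats.flagged = flagged
    return flagged


def paralog_window_filter(
    positions: np.ndarray,
    flags: np.ndarray,
    window: int = 250,
    frac: float = 0.10,
    contig: Optional[np.ndarray] = None,
) -> tuple:
    """Exclude SNPs inside windows enriched in paralog-derived SNPs.

    A symmetric ``window``-bp window is centred on every flagged SNP; if
    the window holds at least two SNPs and its paralog fraction exceeds
    ``frac``, every SNP inside is excluded.  Flagged SNPs are always
    excluded themselves; a lone flagged SNP is removed individually and
    never expands a region.  Exclusion-region limits extend to the
    midpoint between the outermost excluded SNP and the nearest retained
    SNP on each side.  Returns ``(excluded boolean mask, regions)`` with
    regions as 0-based half-open intervals.
    """
    positions = np.asarray(positions)
    flags = np.asarray(flags, dtype=bool)
    n = len(positions)
    if contig is None:
        contig = np.array(["chr1"] * n, dtype=object)
    excluded = flags.copy()
    window_hit = np.zeros(n, dtype=bool)  # excluded via an enriched window
    half = window / 2.0
    for ctg in pd.unique(contig):
        sel = np.nonzero(contig == ctg)[0]
        pos = positions[sel]
        flg = flags[sel]
        for idx in np.nonzero(flg)[0]:
            lo = np.searchsorted(pos, pos[idx] - half, side="left")
            hi = np.searchsorted(pos, pos[idx] + half, side="right")
            n_in = hi - lo
            if n_in >= 2 and flg[lo:hi].sum() / n_in > frac:
                window_hit[sel[lo:hi]] = True
    excluded |= window_hit

    regions = []
    for ctg in pd.unique(contig):
        sel = np.nonzero(contig == ctg)[0]
        pos = positions[sel]
        exc = excluded[sel]
        wh = window_hit[sel]
        i = 0
        m = len(sel)
        while i < m:
            if not exc[i]:
                i += 1
                continue
            j = i
            while j + 1 < m and exc[j + 1]:
                j += 1
            first, last = pos[i], pos[j]
            if wh[i : j + 1].any():
                # enriched region: extend limits to mid-distance
                start = (pos[i - 1] + first) / 2.0 if i > 0 else float(first)
                end = (last + pos[j + 1]) / 2.0 if j + 1 < m else float(last)
            else:
                start, end = float(first), float(last)
            # convert 1-based inclusive limits to 0-based half-open
            regions.append((ctg, int(np.floor(start)) - 1, int(np.ceil(end))))
            i = j + 1
    return excluded, ExclusionRegions(regions)
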