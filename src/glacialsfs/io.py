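"""Readers and writers for the pipeline's file formats.

Formats supported: VCF (FORMAT DP/GQ/AD plus the caller INFO fields used
by the site filters), folded and joint SFS in a fastsimcoal-style
``.obs`` text dialect and a TSV alternative, Ne-trajectory TSV,
stairway-style "final summary" tables (tolerant parser), BED exclusion
regions (0-based half-open; VCF positions are 1-based — conversions are
centralised here), and population coordinate tables.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ExclusionRegions,
    FoldedSFS,
    GenotypeMatrix,
    JointSFS,
    NeTrajectory,
    ReadCountTable,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "write_sfs_obs",
    "read_sfs_obs",
    "write_joint_sfs_obs",
    "read_joint_sfs_obs",
    "write_sfs_tsv",
    "read_sfs_tsv",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "read_stairway_summary",
    "write_bed",
    "read_coords_tsv",
    "write_fst_tsv",
    "read_fst_tsv",
]

INFO_FIELDS = ("QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path, reads: Optional[ReadCountTable] = None,
              sample_names: Optional[Sequence[str]] = None) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2 text file."""
    path = Path(path)
    n_ind = gm.n_ind
    if sample_names is None:
        sample_names = [f"ind{i + 1}" for i in range(n_ind)]
    ad = {}
    if reads is not None and len(reads):
        for row in reads.table.itertuples(index=False):
            ad[(row.individual, row.site)] = (int(row.reads_a), int(row.reads_b))
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read pos rank sum">',
        '##INFO=<ID=SCLASS,Number=1,Type=String,Description="Site class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    for ctg in pd.unique(gm.contig):
        length = int(gm.positions[gm.contig == ctg].max()) + 1000
        lines.append(f"##contig=<ID={ctg},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for s in range(gm.n_sites):
        info = gm.info.iloc[s]
        parts = [f"{f}={info[f]:.4f}" for f in INFO_FIELDS if f in info and not pd.isna(info[f])]
        parts.append(f"SCLASS={gm.site_class[s]}")
        qual = f"{info['QUAL']:.2f}" if "QUAL" in info and not pd.isna(info["QUAL"]) else "."
        cols = [
            str(gm.contig[s]), str(int(gm.positions[s])), ".", "A", "T", qual, "PASS",
            ";".join(parts), "GT:DP:GQ:AD",
        ]
        for i in range(n_ind):
            g = int(gm.genotypes[i, s])
            dp = int(gm.dp[i, s])
            gq = int(gm.gq[i, s])
            if (i, s) in ad:
                a, b = ad[(i, s)]
            elif g == 0:
                a, b = dp, 0
            elif g == 2:
                a, b = 0, dp
            else:
                a, b = dp // 2, dp - dp // 2
            cols.append(f"{gt_str[g]}:{dp}:{gq}:{a},{b}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path, pop_map: Optional[dict] = None, l_total: Optional[float] = None):
    """Read a VCF into a genotype matrix plus AD-derived read counts.

    Only biallelic SNV records are retained; multiallelic records are
    dropped and counted (``gm.n_multiallelic_dropped``).  1-based
    positions are preserved.  ``pop_map`` maps sample name to population
    id (default: one population).  Returns ``(GenotypeMatrix,
    ReadCountTable)``; the read-count table is empty when the VCF has no
    AD field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    n_ind = len(samples)
    geno_cols, dp_cols, gq_cols = [], [], []
    positions, contigs, classes, info_rows = [], [], [], []
    ad_rows = []
    n_multi = 0
    s_idx = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        g = np.full(n_ind, MISSING, dtype=np.int8)
        g[gt == 0] = 0
        g[gt == 1] = 1
        g[gt == 3] = 2
        geno_cols.append(g)
        dp = var.format("DP")
        gq = var.format("GQ")
        dp_cols.append(np.zeros(n_ind, int) if dp is None else np.maximum(dp[:, 0], 0))
        gq_cols.append(np.zeros(n_ind, int) if gq is None else np.maximum(gq[:, 0], 0))
        positions.append(var.POS)
        contigs.append(var.CHROM)
        classes.append(var.INFO.get("SCLASS", "other"))
        row = {f: var.INFO.get(f, np.nan) for f in INFO_FIELDS}
        row["QUAL"] = var.QUAL if var.QUAL is not None else np.nan
        info_rows.append(row)
        ad = var.format("AD")
        if ad is not None:
            for i in np.nonzero(gt == 1)[0]:
                a, b = int(ad[i, 0]), int(ad[i, 1])
                if a + b >= 1:
                    ad_rows.append((int(i), s_idx, a, b))
        s_idx += 1
    if s_idx == 0:
        raise ValueError(f"no biallelic records in {path}")
    geno = np.stack(geno_cols, axis=1)
    pop = np.array([pop_map.get(s, "pop1") if pop_map else "pop1" for s in samples], dtype=object)
    gm = GenotypeMatrix(
        genotypes=geno,
        dp=np.stack(dp_cols, axis=1),
        gq=np.stack(gq_cols, axis=1),
        positions=np.asarray(positions),
        info=pd.DataFrame(info_rows),
        site_class=np.asarray(classes, dtype=object),
        pop=pop,
        L_total=float(l_total) if l_total is not None else float(s_idx),
        contig=np.asarray(contigs, dtype=object),
    )
    gm.n_multiallelic_dropped = n_multi
    reads = ReadCountTable(
        pd.DataFrame(ad_rows, columns=list(ReadCountTable.COLUMNS))
    )
    return gm, reads


# ---------------------------------------------------------------------------
# SFS text dialects


def write_sfs_obs(sfs: FoldedSFS, path) -> None:
    """fastsimcoal-style folded SFS: '1 observations' header, then one row
    of counts indexed 0..n with entry 0 the monomorphic count."""
    row = np.zeros(sfs.n + 1)
    row[0] = sfs.n_mono
    row[1 : sfs.n // 2 + 1] = sfs.eta
    lines = ["1 observations", "\t".join(f"d0_{i}" for i in range(sfs.n + 1)),
             "\t".join(repr(float(v)) for v in row)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfs_obs(path) -> FoldedSFS:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or "observations" not in lines[0]:
        raise ValueError(f"corrupt .obs header in {path}")
    values = [float(v) for v in lines[-1].split()]
    n = len(values) - 1
    eta = np.asarray(values[1 : n // 2 + 1])
    tail = values[n // 2 + 1 :]
    if any(v != 0 for v in tail):
        raise ValueError("folded .obs has mass above n/2")
    return FoldedSFS(eta, n, float(sum(values)))


def write_joint_sfs_obs(jsfs: JointSFS, path) -> None:
    """Joint folded SFS, row-major: rows are pop1 counts 0..n1, columns
    pop2 counts 0..n2."""
    lines = ["1 observations"]
    lines.append("\t" + "\t".join(f"d1_{j}" for j in range(jsfs.n2 + 1)))
    for i in range(jsfs.n1 + 1):
        lines.append(f"d0_{i}\t" + "\t".join(repr(float(v)) for v in jsfs.counts[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_joint_sfs_obs(path) -> JointSFS:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if "observations" not in lines[0]:
        raise ValueError(f"corrupt joint .obs header in {path}")
    n2 = len(lines[1].split()) - 1
    rows = []
    for line in lines[2:]:
        parts = line.split()
        rows.append([float(v) for v in parts[1:]])
    counts = np.asarray(rows)
    if counts.shape[1] != n2 + 1:
        raise ValueError("joint .obs dimension mismatch")
    n1 = counts.shape[0] - 1
    return JointSFS(counts, n1, n2, float(counts.sum()))


def write_sfs_tsv(sfs: FoldedSFS, path) -> None:
    lines = [f"#n\t{sfs.n}", f"#L\t{repr(float(sfs.L))}", "minor_count\tsites"]
    lines.append(f"0\t{repr(float(sfs.n_mono))}")
    for i, v in enumerate(sfs.eta, start=1):
        lines.append(f"{i}\t{repr(float(v))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfs_tsv(path) -> FoldedSFS:
    n = L = None
    eta = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#n"):
            n = int(line.split("\t")[1])
        elif line.startswith("#L"):
            L = float(line.split("\t")[1])
        elif line and not line.startswith(("#", "minor_count")):
            i, v = line.split("\t")
            eta[int(i)] = float(v)
    if n is None or L is None:
        raise ValueError(f"missing #n/#L metadata in {path}")
    vec = np.array([eta.get(i, 0.0) for i in range(1, n // 2 + 1)])
    return FoldedSFS(vec, n, L)


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory_tsv(traj: NeTrajectory, path) -> None:
    lines = [
        f"#mu\t{float(traj.mu)!r}",
        f"#gen_time_years\t{float(traj.gen_time_years)!r}",
        "t_lo_years\tt_hi_years\tne_median\tne_lo\tne_hi",
    ]
    lo = traj.ne_lo if traj.ne_lo is not None else traj.ne
    hi = traj.ne_hi if traj.ne_hi is not None else traj.ne
    for a, b, m, l, h in zip(traj.t_lo, traj.t_hi, traj.ne, lo, hi):
        lines.append("\t".join(repr(float(v)) for v in (a, b, m, l, h)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_tsv(path) -> NeTrajectory:
    mu = math.nan
    gt = 1.0
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#mu"):
            mu = float(line.split("\t")[1])
        elif line.startswith("#gen_time_years"):
            gt = float(line.split("\t")[1])
        elif line and not line.startswith(("#", "t_lo")):
            rows.append([float(v) for v in line.split("\t")])
    arr = np.asarray(rows)
    return NeTrajectory(
        t_lo=arr[:, 0], t_hi=arr[:, 1], ne=arr[:, 2], mu=mu, gen_time_years=gt,
        ne_lo=arr[:, 3], ne_hi=arr[:, 4],
    )


def read_stairway_summary(path) -> NeTrajectory:
    """Tolerant parser for stairway-style 'final summary' tables.

    Requires columns named (case-insensitively) ``year`` and
    ``Ne_median``; percentile columns are picked up when present.
    Consecutive rows delimit steps; zero-length steps are merged.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    if "year" not in cols or "ne_median" not in cols:
        raise ValueError(f"summary file {path} lacks year/Ne_median columns")
    year = df[cols["year"]].to_numpy(dtype=float)
    ne = df[cols["ne_median"]].to_numpy(dtype=float)
    lo_col = next((cols[c] for c in cols if "2.5" in c and "ne" in c), None)
    hi_col = next((cols[c] for c in cols if "97.5" in c and "ne" in c), None)
    lo = df[lo_col].to_numpy(dtype=float) if lo_col else None
    hi = df[hi_col].to_numpy(dtype=float) if hi_col else None
    t_lo, t_hi, nes, los, his = [], [], [], [], []
    for i in range(len(year) - 1):
        if year[i + 1] <= year[i]:
            continue
        t_lo.append(year[i])
        t_hi.append(year[i + 1])
        nes.append(ne[i])
        if lo is not None:
            los.append(lo[i])
        if hi is not None:
            his.append(hi[i])
    mu = math.nan
    if "mutation_per_site" in cols:
        mu = float(df[cols["mutation_per_site"]].iloc[0])
    return NeTrajectory(
        t_lo=np.asarray(t_lo), t_hi=np.asarray(t_hi), ne=np.asarray(nes), mu=mu,
        ne_lo=np.asarray(los) if los else None,
        ne_hi=np.asarray(his) if his else None,
    )


# ---------------------------------------------------------------------------
# regions, coordinates, matrices


def write_bed(regions: ExclusionRegions, path) -> None:
    """Exclusion regions as BED (0-based half-open)."""
    lines = [f"{ctg}\t{int(s)}\t{int(e)}" for ctg, s, e in regions.regions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_coords_tsv(path) -> pd.DataFrame:
    """Population coordinates: columns pop, lat, lon[, elevation]."""
    df = pd.read_csv(path, sep="\t")
    missing = {"pop", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    return df


def write_fst_tsv(fst: pd.DataFrame, path) -> None:
    fst.to_csv(path, sep="\t", index_label="pop")


def read_fst_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pop")
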