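"""Core data containers shared across the pipeline.

The containers are deliberately thin: numpy arrays plus light validation.
All effective sizes are diploid effective population sizes (pairs of
haploid genomes), so the coalescence rate for ``k`` lineages is
``k(k-1)/(4*Ne)`` per generation and the population-scaled mutation rate
is ``theta = 4*Ne*mu``.  Times are in generations before present unless a
field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

SITE_CLASSES = ("4fold", "intron", "intergenic", "0fold", "other")


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant single-population demography.

    ``epochs`` is an ordered tuple of ``(ne, t_start)`` pairs: the diploid
    effective size in force from ``t_start`` generations before present
    until the start of the next epoch.  The first epoch starts at 0 and
    the last extends to infinity.
    """

    epochs: tuple

    def __post_init__(self):
        if len(self.epochs) == 0:
            raise ValueError("demography needs at least one epoch")
        ts = [t for _, t in self.epochs]
        nes = [n for n, _ in self.epochs]
        if ts[0] != 0:
            raise ValueError("first epoch must start at t=0")
        if any(t1 >= t2 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(n <= 0 for n in nes):
            raise ValueError("effective sizes must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def ne_at(self, t: float) -> float:
        """Effective size in force ``t`` generations before present."""
        ne = self.epochs[0][0]
        for n, t0 in self.epochs:
            if t0 <= t:
                ne = n
            else:
                break
        return ne

    def rescaled(self, c: float) -> "Demography":
        """Multiply every Ne and every epoch start time by ``c``.

        Under the coalescent scaling identity this leaves the expected SFS
        unchanged when the mutation rate is divided by ``c``.
        """
        return Demography(tuple((n * c, t * c) for n, t in self.epochs))


@dataclass(frozen=True)
class DivergenceModel:
    """Two-deme isolation-with-migration model.

    Looking backward in time: two demes of sizes ``npop1``/``npop2``
    exchange migrants until ``tdiv`` generations ago, when they merge into
    a single ancestral population of size ``ncur``.  If
    ``has_ancestral_change`` the ancestral size switches to ``nanc`` at
    ``tsep`` (> ``tdiv``).  ``n1m21``/``n2m12`` are effective migrant
    numbers (Ne x m); both zero when ``has_migration`` is false.
    """

    npop1: float
    npop2: float
    ncur: float
    tdiv: float
    nanc: float = 0.0
    tsep: float = 0.0
    n1m21: float = 0.0
    n2m12: float = 0.0
    has_migration: bool = False
    has_ancestral_change: bool = False

    def __post_init__(self):
        if min(self.npop1, self.npop2, self.ncur) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.tdiv < 0:
            raise ValueError("tdiv must be >= 0")
        if self.has_ancestral_change:
            if self.tsep <= self.tdiv:
                raise ValueError("tsep must exceed tdiv when the ancestral size changes")
            if self.nanc <= 0:
                raise ValueError("nanc must be positive")
        if self.has_migration:
            if self.n1m21 < 0 or self.n2m12 < 0:
                raise ValueError("migrant numbers must be >= 0")
        elif self.n1m21 != 0 or self.n2m12 != 0:
            raise ValueError("migrant numbers must be zero when has_migration is false")


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum of a single population.

    ``eta[i-1]`` counts sites with minor-allele count ``i`` (real-valued
    entries are allowed for expected spectra and projections); ``n`` is
    the haploid sample size and ``L`` the total number of surveyed sites
    including monomorphic ones.
    """

    eta: np.ndarray
    n: int
    L: float

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        if self.n < 2:
            raise ValueError("haploid sample size must be >= 2")
        if len(self.eta) != self.n // 2:
            raise ValueError(
                f"folded SFS for n={self.n} needs {self.n // 2} entries, got {len(self.eta)}"
            )
        if np.any(self.eta < -1e-9):
            raise ValueError("SFS entries must be non-negative")

    @property
    def segregating(self) -> float:
        return float(self.eta.sum())

    @property
    def n_mono(self) -> float:
        return float(self.L - self.eta.sum())

    def copy(self) -> "FoldedSFS":
        return FoldedSFS(self.eta.copy(), self.n, self.L)


@dataclass
class JointSFS:
    """Jointly folded two-population SFS.

    ``counts[i, j]`` is the number of sites whose minor configuration has
    ``i`` copies in population 1 (haploid size ``n1``) and ``j`` copies in
    population 2 (``n2``); cell (0, 0) holds the monomorphic count.
    Entries with total derived count above ``(n1+n2)/2`` are folded onto
    their complements.
    """

    counts: np.ndarray
    n1: int
    n2: int
    L: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("joint SFS shape must be (n1+1, n2+1)")

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def marginal(self, pop: int) -> FoldedSFS:
        """Fold one axis into a single-population spectrum (pooled sites)."""
        # derived counts along one axis of an already jointly folded matrix
        # cannot be disambiguated; marginalisation folds them again, which
        # is exact because folding is idempotent on minor counts.
        n = self.n1 if pop == 1 else self.n2
        axis = 1 if pop == 1 else 0
        marg = self.counts.sum(axis=axis)
        eta = np.zeros(n // 2)
        for d in range(1, n):
            f = min(d, n - d)
            if f >= 1:
                eta[f - 1] += marg[d]
        return FoldedSFS(eta, n, self.L)

    def pooled(self) -> FoldedSFS:
        """Fold the total minor-allele count over both populations."""
        n = self.n
        eta = np.zeros(n // 2)
        for i in range(self.n1 + 1):
            for j in range(self.n2 + 1):
                d = i + j
                if d == 0 or d == n:
                    continue
                eta[min(d, n - d) - 1] += self.counts[i, j]
        return FoldedSFS(eta, n, self.L)


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with per-call depth/quality annotations.

    genotypes : (n_ind, n_sites) int8 array of alt-allele dosages
        {0, 1, 2}; ``MISSING`` (-1) marks missing calls.
    dp, gq : per-call sequencing depth and genotype quality.
    contig, positions : per-site 1-based coordinates, strictly increasing
        within each contig.
    info : per-site table of caller annotations (QD, QUAL, SOR, MQ,
        MQRankSum, ReadPosRankSum).
    site_class : per-site functional label (see ``SITE_CLASSES``).
    pop : per-individual population identifier.
    L_total : total surveyed sites including monomorphic positions.
    l_by_class : optional per-class totals of surveyed sites; falls back
        to ``L_total`` when a class subset is requested without it.
    """

    genotypes: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    positions: np.ndarray
    info: pd.DataFrame
    site_class: np.ndarray
    pop: np.ndarray
    L_total: float
    contig: Optional[np.ndarray] = None
    l_by_class: Optional[dict] = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_sites = self.genotypes.shape
        if self.contig is None:
            self.contig = np.array(["chr1"] * n_sites, dtype=object)
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,missing}")
        if np.any(self.dp < 0) or np.any(self.gq < 0):
            raise ValueError("DP and GQ must be non-negative")
        for ctg in pd.unique(self.contig):
            pos = self.positions[self.contig == ctg]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions must be strictly increasing within {ctg}")

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def class_mask(self, classes: Iterable[str]) -> np.ndarray:
        classes = set(classes)
        unknown = classes - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site classes: {sorted(unknown)}")
        if not classes:
            raise ValueError("empty site-class selection")
        return np.isin(self.site_class, list(classes))

    def surveyed_sites(self, classes: Optional[Iterable[str]] = None) -> float:
        """Total surveyed sites (incl. monomorphic) for a class selection."""
        if classes is None:
            return float(self.L_total)
        classes = set(classes)
        if self.l_by_class is not None:
            return float(sum(self.l_by_class.get(c, 0) for c in classes))
        return float(self.L_total)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[:, mask],
            dp=self.dp[:, mask],
            gq=self.gq[:, mask],
            positions=self.positions[mask],
            info=self.info.loc[mask].reset_index(drop=True),
            site_class=self.site_class[mask],
            pop=self.pop,
            L_total=self.L_total,
            contig=self.contig[mask],
            l_by_class=self.l_by_class,
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[mask],
            dp=self.dp[mask],
            gq=self.gq[mask],
            positions=self.positions,
            info=self.info,
            site_class=self.site_class,
            pop=self.pop[mask],
            L_total=self.L_total,
            contig=self.contig,
            l_by_class=self.l_by_class,
        )


@dataclass
class ReadCountTable:
    """Allele-specific read counts for heterozygous calls.

    One row per (individual, site) heterozygote with ``reads_a`` and
    ``reads_b`` supporting the two alleles; every row has at least one
    read in total.
    """

    table: pd.DataFrame

    COLUMNS = ("individual", "site", "reads_a", "reads_b")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"read-count table missing columns: {sorted(missing)}")
        tot = self.table["reads_a"] + self.table["reads_b"]
        if len(self.table) and (tot < 1).any():
            raise ValueError("each recorded heterozygote needs >= 1 read")

    def __len__(self) -> int:
        return len(self.table)

    def site_read_sums(self, n_sites: int) -> tuple:
        """Per-site totals (A, B) of reads pooled over heterozygotes."""
        a = np.zeros(n_sites)
        b = np.zeros(n_sites)
        if len(self.table):
            g = self.table.groupby("site")[["reads_a", "reads_b"]].sum()
            a[g.index.to_numpy()] = g["reads_a"].to_numpy()
            b[g.index.to_numpy()] = g["reads_b"].to_numpy()
        return a, b


@dataclass
class NeTrajectory:
    """Step function of effective size over time.

    ``t_lo``/``t_hi`` bound each step (years before present, increasing
    toward the past); ``ne`` is the size on the step.  ``ne_lo``/``ne_hi``
    optionally carry bootstrap percentile bands.  ``mu`` and
    ``gen_time_years`` record the scaling used to convert the inference
    from coalescent units.
    """

    t_lo: np.ndarray
    t_hi: np.ndarray
    ne: np.ndarray
    mu: float = float("nan")
    gen_time_years: float = 1.0
    ne_lo: Optional[np.ndarray] = None
    ne_hi: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t_lo = np.asarray(self.t_lo, dtype=float)
        self.t_hi = np.asarray(self.t_hi, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if not (len(self.t_lo) == len(self.t_hi) == len(self.ne)):
            raise ValueError("step arrays must have equal length")
        if np.any(self.ne <= 0):
            raise ValueError("Ne must be positive")
        if np.any(self.t_hi <= self.t_lo):
            raise ValueError("each step needs t_hi > t_lo")
        if np.any(np.diff(self.t_lo) <= 0) or np.any(self.t_lo[1:] < self.t_hi[:-1] - 1e-9):
            raise ValueError("steps must be ordered and non-overlapping")

    @property
    def n_steps(self) -> int:
        return len(self.ne)

    def ne_at(self, t: float) -> float:
        """Ne of the step containing time ``t`` (clamped to the span)."""
        if t <= self.t_lo[0]:
            return float(self.ne[0])
        if t >= self.t_hi[-1]:
            return float(self.ne[-1])
        idx = int(np.searchsorted(self.t_lo, t, side="right")) - 1
        return float(self.ne[max(idx, 0)])


@dataclass
class HDplotStats:
    """Per-site HDplot statistics: heterozygote fraction H and pooled
    read-ratio deviation D (z-score); NaN where undefined."""

    h: np.ndarray
    d: np.ndarray
    flagged: np.ndarray = field(default=None)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        ok = np.isnan(self.h) | ((self.h >= 0) & (self.h <= 1))
        if not ok.all():
            raise ValueError("H must lie in [0, 1]")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.h), dtype=bool)


@dataclass
class ExclusionRegions:
    """Sorted, non-overlapping half-open genomic intervals."""

    regions: list  # of (contig, start, end), 0-based half-open

    def __post_init__(self):
        by_contig: dict = {}
        for ctg, s, e in self.regions:
            if e <= s:
                raise ValueError("region end must exceed start")
            by_contig.setdefault(ctg, []).append((s, e))
        for ctg, ivs in by_contig.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping regions on {ctg}")

    def __len__(self) -> int:
        return len(self.regions)

    def contains(self, contig: str, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(ctg == contig and s <= p < e for ctg, s, e in self.regions)


@dataclass
class SynchronyResult:
    """Outcome of the synchronous-decrease randomization test."""

    observed_max_species: int
    observed_longest_run: int
    null_95: tuple  # (95th pct of max-species null, 95th pct of longest-run null)
    n_perm: int
    window: int
    p_max_species: float
    p_longest_run: float
    significant_max_species: bool
    significant_longest_run: bool

    @property
    def significant(self) -> bool:
        """Primary decision: the longest synchronous run exceeds chance."""
        return self.significant_longest_run
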