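"""Synthetic-data generators for every stage of the pipeline.

This module produces the study conditions end to end: folded SFS samples
drawn from a single-population coalescent under piecewise-constant
demography, joint spectra from a two-deme isolation-with-migration
coalescent, diploid genotype matrices with controlled missingness,
read-count tables with injected collapsed-paralog loci, and sets of
step-function Ne trajectories with controllable shared-decrease windows.

The coalescent is the standard neutral one: ``k`` lineages coalesce at
rate ``k(k-1)/(4*Ne)`` per generation (diploid sizes), waiting times are
rescaled exponentials across epochs, and mutations fall on branches as a
Poisson process under the infinite-sites model.  Loci are independent
across replicates; spectra are folded throughout.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    Demography,
    DivergenceModel,
    FoldedSFS,
    GenotypeMatrix,
    JointSFS,
    NeTrajectory,
    ReadCountTable,
    SITE_CLASSES,
)

__all__ = [
    "glacial_cycle_demography",
    "simulate_coalescent_sfs",
    "simulate_two_deme_sfs",
    "simulate_genotype_matrix",
    "inject_paralogs",
    "simulate_trajectory_set",
]

# Glacial/interglacial event times (years before present): an expansion at
# 15 kya, a decline at 120 kya, then alternating events every 120 ky until
# a final decline at ~1.1 Mya -- ten instantaneous events, five cycles.
GLACIAL_EVENT_TIMES_YEARS = (15_000.0,) + tuple(120_000.0 * j for j in range(1, 10))


def glacial_cycle_demography(
    gen_time_years: float, ne_current: float, fold: float = 10.0
) -> Demography:
    """Ten-event glacial-cycle demography (five expansion/contraction cycles).

    Forward in time the population expands ``fold``-fold 15 kya, declined
    120 kya, and alternates every 120 ky back to a final decline ~1.1 Mya.
    Backward in time Ne therefore alternates between ``ne_current`` and
    ``ne_current/fold``, constant between instantaneous events.  Event
    times are converted to generations with ``gen_time_years``.
    """
    if gen_time_years <= 0 or ne_current <= 0:
        raise ValueError("gen_time_years and ne_current must be positive")
    if fold <= 1:
        raise ValueError("fold change must exceed 1")
    times_gen = [t / gen_time_years for t in GLACIAL_EVENT_TIMES_YEARS]
    epochs = [(ne_current, 0.0)]
    for i, t in enumerate(times_gen):
        # epoch i+1 starts at event i; sizes alternate low/high going back
        ne = ne_current / fold if i % 2 == 0 else ne_current
        epochs.append((ne, t))
    return Demography(tuple(epochs))


# ---------------------------------------------------------------------------
# single-population coalescent


def _sim_branches(dem: Demography, n: int, rng: np.random.Generator, leaves: bool = False):
    """Simulate one genealogy; return branches as (descendants, length).

    ``descendants`` is a leaf count, or a list of leaf indices when
    ``leaves`` is true.  Branch lengths are in generations.
    """
    epochs = dem.epochs
    n_epochs = len(epochs)
    if leaves:
        desc = [[i] for i in range(n)]
    else:
        desc = [1] * n
    birth = [0.0] * n
    branches = []
    t = 0.0
    ei = 0
    k = n
    while k > 1:
        ne = epochs[ei][0]
        t_end = epochs[ei + 1][1] if ei + 1 < n_epochs else math.inf
        rate = k * (k - 1) / (4.0 * ne)
        wait = rng.exponential(1.0 / rate)
        if t + wait < t_end:
            t += wait
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            branches.append((desc[i], t - birth[i]))
            branches.append((desc[j], t - birth[j]))
            if leaves:
                desc[i] = desc[i] + desc[j]
            else:
                desc[i] = desc[i] + desc[j]
            birth[i] = t
            desc[j] = desc[k - 1]
            birth[j] = birth[k - 1]
            desc.pop()
            birth.pop()
            k -= 1
        else:
            t = t_end
            ei += 1
    return branches


def simulate_coalescent_sfs(
    dem: Demography,
    n: int,
    L: float,
    mu: float,
    reps: int = 100,
    seed: Optional[int] = None,
    with_se: bool = False,
) -> FoldedSFS:
    """Monte Carlo folded SFS from ``reps`` independent loci.

    The ``L`` surveyed sites are split evenly across replicate loci; each
    locus draws one genealogy and Poisson mutation counts per branch with
    mean ``mu * (L/reps) * length``.  Entry expectations converge to the
    analytic expectation of the demography as ``reps`` grows.  When
    ``with_se`` the returned spectrum carries an ``eta_se`` attribute with
    Monte Carlo standard errors of the entry totals.
    """
    if n < 2:
        raise ValueError("need at least two haploid samples")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    nfold = n // 2
    eta = np.zeros(nfold)
    sumsq = np.zeros(nfold)
    l_rep = L / reps
    for _ in range(reps):
        rep_eta = np.zeros(nfold)
        for d, length in _sim_branches(dem, n, rng):
            nmut = rng.poisson(mu * l_rep * length)
            if nmut:
                rep_eta[min(d, n - d) - 1] += nmut
        eta += rep_eta
        sumsq += rep_eta**2
    sfs = FoldedSFS(eta, n, L)
    if with_se:
        var_rep = sumsq / reps - (eta / reps) ** 2
        sfs.eta_se = np.sqrt(np.maximum(var_rep, 0.0) * reps)
    return sfs


# ---------------------------------------------------------------------------
# two-deme structured coalescent


def _fold_joint(d1: int, d2: int, n1: int, n2: int):
    tot = d1 + d2
    n = n1 + n2
    if 2 * tot > n or (2 * tot == n and 2 * d1 > n1):
        return n1 - d1, n2 - d2
    return d1, d2


class EventBudgetExceeded(RuntimeError):
    """Raised when a structured-coalescent genealogy needs more events than
    the budget allows (pathological high-migration parameter corners)."""


def _sim_branches_two_deme(
    model: DivergenceModel, n1: int, n2: int, rng: np.random.Generator,
    max_events: int = 20_000,
):
    """One genealogy under the isolation-with-migration model.

    Returns branches as ((descendants in pop1, in pop2), length).  The
    effective-migrant parameters Nm translate into per-lineage backward
    migration rates ``Nm / (2 * N_deme)`` out of each deme.  Extreme
    migration/divergence corners whose genealogies would need more than
    ``max_events`` events (they are effectively panmictic) raise
    ``EventBudgetExceeded``.
    """
    m_out1 = model.n1m21 / (2.0 * model.npop1) if model.has_migration else 0.0
    m_out2 = model.n2m12 / (2.0 * model.npop2) if model.has_migration else 0.0
    # lineages per deme: lists of ((d1, d2), birth_time)
    demes = [
        [((1, 0), 0.0) for _ in range(n1)],
        [((0, 1), 0.0) for _ in range(n2)],
    ]
    branches = []
    t = 0.0

    def coalesce(pool, t):
        k = len(pool)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        (da, ta), (db, tb) = pool[i], pool[j]
        branches.append((da, t - ta))
        branches.append((db, t - tb))
        merged = ((da[0] + db[0], da[1] + db[1]), t)
        for idx in sorted((i, j), reverse=True):
            pool.pop(idx)
        pool.append(merged)

    # phase 1: two demes, until tdiv
    n_events = 0
    while len(demes[0]) + len(demes[1]) > 1 and t < model.tdiv:
        n_events += 1
        if n_events > max_events:
            raise EventBudgetExceeded(
                f"genealogy exceeded {max_events} events before tdiv"
            )
        k1, k2 = len(demes[0]), len(demes[1])
        rates = [
            k1 * (k1 - 1) / (4.0 * model.npop1),
            k2 * (k2 - 1) / (4.0 * model.npop2),
            k1 * m_out1,
            k2 * m_out2,
        ]
        total = sum(rates)
        if total <= 0:
            break
        wait = rng.exponential(1.0 / total)
        if t + wait >= model.tdiv:
            break
        t += wait
        u = rng.random() * total
        if u < rates[0]:
            coalesce(demes[0], t)
        elif u < rates[0] + rates[1]:
            coalesce(demes[1], t)
        elif u < rates[0] + rates[1] + rates[2]:
            i = int(rng.integers(k1))
            demes[1].append(demes[0].pop(i))
        else:
            i = int(rng.integers(k2))
            demes[0].append(demes[1].pop(i))

    # phase 2: merged ancestral population
    pool = demes[0] + demes[1]
    t = max(t, model.tdiv)
    bounds = []  # (ne, t_end)
    if model.has_ancestral_change:
        bounds = [(model.ncur, model.tsep), (model.nanc, math.inf)]
    else:
        bounds = [(model.ncur, math.inf)]
    bi = 0
    while bounds[bi][1] <= t:
        bi += 1
    while len(pool) > 1:
        ne, t_end = bounds[bi]
        k = len(pool)
        rate = k * (k - 1) / (4.0 * ne)
        wait = rng.exponential(1.0 / rate)
        if t + wait < t_end:
            t += wait
            coalesce(pool, t)
        else:
            t = t_end
            bi += 1
    return branches


def simulate_two_deme_sfs(
    model: DivergenceModel,
    n1: int,
    n2: int,
    L: float,
    mu: float,
    reps: int = 100,
    seed: Optional[int] = None,
) -> JointSFS:
    """Monte Carlo jointly folded two-population SFS."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two haploid samples per deme")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n1 + 1, n2 + 1))
    l_rep = L / reps
    for _ in range(reps):
        for (d1, d2), length in _sim_branches_two_deme(model, n1, n2, rng):
            nmut = rng.poisson(mu * l_rep * length)
            if nmut:
                i, j = _fold_joint(d1, d2, n1, n2)
                counts[i, j] += nmut
    counts[0, 0] = L - counts.sum()
    return JointSFS(counts, n1, n2, L)


# ---------------------------------------------------------------------------
# genotype matrices and paralog injection


def _synth_gq(dp: np.ndarray) -> np.ndarray:
    """Genotype quality synthesized monotone in depth (capped at 99)."""
    return np.minimum(99, np.round(10.0 * dp / 3.0)).astype(int)


def _passing_info(n_sites: int, rng: np.random.Generator) -> pd.DataFrame:
    """Caller INFO annotations drawn well inside the passing ranges."""
    return pd.DataFrame(
        {
            "QD": rng.uniform(10, 35, n_sites),
            "QUAL": rng.uniform(100, 2000, n_sites),
            "SOR": rng.uniform(0.3, 2.0, n_sites),
            "MQ": rng.uniform(45, 60, n_sites),
            "MQRankSum": rng.normal(0, 1.5, n_sites),
            "ReadPosRankSum": rng.normal(0, 1.5, n_sites),
        }
    )


_CLASS_PROBS = {"4fold": 0.25, "intron": 0.25, "intergenic": 0.25, "0fold": 0.15, "other": 0.10}


def simulate_genotype_matrix(
    dem: Demography,
    n_ind: int,
    L: float,
    mu: float,
    missing_rate: float = 0.0,
    dp_model: float = 30.0,
    seed: Optional[int] = None,
    pop_labels: Optional[Sequence[str]] = None,
    reps: int = 1,
) -> GenotypeMatrix:
    """Diploid genotype matrix from ``reps`` independent coalescent loci.

    The ``L`` surveyed positions are split evenly into ``reps`` loci,
    each drawing its own genealogy over ``2*n_ind`` leaves (targeted
    sequencing of many short fragments corresponds to ``reps`` in the
    hundreds).  Consecutive leaves pair into individuals, so per-site
    minor-allele counts equal those of the underlying haplotypes.  Depth
    is Poisson with mean ``dp_model`` (floored at 1), GQ is synthesized
    monotone in depth, and calls go missing independently at
    ``missing_rate``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_ind
    block = int(L) // reps
    sites = []  # leaf-index lists, one per segregating site
    positions = []
    for locus in range(reps):
        locus_sites = []
        for leaf_ids, length in _sim_branches(dem, n_hap, rng, leaves=True):
            nmut = rng.poisson(mu * block * length)
            locus_sites.extend([leaf_ids] * nmut)
        if len(locus_sites) > block:
            raise ValueError(
                f"simulated {len(locus_sites)} segregating sites on a {block}-bp "
                "locus; lower mu or raise L (infinite-sites placement needs S <= L)"
            )
        pos = np.sort(
            rng.choice(np.arange(1, block + 1), size=len(locus_sites), replace=False)
        )
        positions.extend(pos + locus * block)
        sites.extend(locus_sites)
    n_sites = len(sites)
    haplo = np.zeros((n_hap, n_sites), dtype=np.int8)
    for s, leaf_ids in enumerate(sites):
        haplo[leaf_ids, s] = 1
    geno = (haplo[0::2] + haplo[1::2]).astype(np.int8)
    positions = np.asarray(positions)
    dp = np.maximum(1, rng.poisson(dp_model, size=geno.shape))
    gq = _synth_gq(dp)
    miss = rng.random(geno.shape) < missing_rate
    geno[miss] = MISSING
    site_class = rng.choice(
        list(_CLASS_PROBS), size=n_sites, p=list(_CLASS_PROBS.values())
    ).astype(object)
    # surveyed-site totals per class, apportioned like the variant classes
    l_by_class = {c: p * L for c, p in _CLASS_PROBS.items()}
    if pop_labels is None:
        pop = np.array(["pop1"] * n_ind, dtype=object)
    else:
        if len(pop_labels) != n_ind:
            raise ValueError("pop_labels must have one entry per individual")
        pop = np.asarray(pop_labels, dtype=object)
    return GenotypeMatrix(
        genotypes=geno,
        dp=dp,
        gq=gq,
        positions=positions,
        info=_passing_info(n_sites, rng),
        site_class=site_class,
        pop=pop,
        L_total=float(L),
        l_by_class=l_by_class,
    )


def inject_paralogs(
    gm: GenotypeMatrix,
    prop: float,
    depth: float = 30.0,
    seed: Optional[int] = None,
    paralog_ratio: float = 0.25,
) -> tuple:
    """Turn a fraction of sites into collapsed-duplicate artifacts.

    Collapsed paralogs -- two loci mapping to one reference position --
    make nearly every individual look heterozygous, with pooled allele
    reads biased away from the 1:1 heterozygote expectation (one of the
    four collapsed chromosome copies carries the variant, so the minor
    allele draws ~``paralog_ratio`` of the reads).  Genuine heterozygotes
    get reads ~ Binomial(depth, 1/2).  Returns the modified matrix and a
    read-count table covering every heterozygous call.
    """
    if not 0 <= prop <= 1:
        raise ValueError("prop must be in [0, 1]")
    rng = np.random.default_rng(seed)
    geno = gm.genotypes.copy()
    dp = gm.dp.copy()
    n_ind, n_sites = geno.shape
    n_par = int(round(prop * n_sites))
    par_sites = np.sort(rng.choice(n_sites, size=n_par, replace=False)) if n_par else np.array([], dtype=int)
    par_mask = np.zeros(n_sites, dtype=bool)
    par_mask[par_sites] = True
    rows = []
    for s in range(n_sites):
        if par_mask[s]:
            for i in range(n_ind):
                if geno[i, s] == MISSING:
                    continue
                geno[i, s] = 1  # collapse forces apparent heterozygosity
                total = max(1, int(rng.poisson(2 * depth)))
                b = int(rng.binomial(total, paralog_ratio))
                rows.append((i, s, total - b, b))
                dp[i, s] = total
        else:
            for i in np.nonzero(geno[:, s] == 1)[0]:
                total = max(1, int(rng.poisson(depth)))
                a = int(rng.binomial(total, 0.5))
                rows.append((int(i), s, a, total - a))
    table = pd.DataFrame(rows, columns=list(ReadCountTable.COLUMNS))
    out = GenotypeMatrix(
        genotypes=geno,
        dp=dp,
        gq=_synth_gq(dp),
        positions=gm.positions,
        info=gm.info,
        site_class=gm.site_class,
        pop=gm.pop,
        L_total=gm.L_total,
        contig=gm.contig,
        l_by_class=gm.l_by_class,
    )
    out.paralog_mask = par_mask  # ground truth for calibration studies
    return out, ReadCountTable(table)


# ---------------------------------------------------------------------------
# Ne-trajectory sets for the synchronicity test


def simulate_trajectory_set(
    k: int,
    grid: Sequence[float],
    shared_decreases: Sequence[tuple] = (),
    noise: float = 0.1,
    seed: Optional[int] = None,
    base_ne: float = 1e5,
) -> list:
    """Random-walk log-Ne step functions with optional shared decreases.

    Each of the ``k`` trajectories is an independent Gaussian random walk
    in log Ne over the time grid (present to past).  Within every shared
    window ``(start, end)`` of grid indices all trajectories are forced
    to decrease monotonically toward the present (Ne grows with the
    index, which runs toward the past).
    """
    if k < 2:
        raise ValueError("need at least two trajectories")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    G = len(grid)
    windows = sorted(shared_decreases)
    for (s, e) in windows:
        if not (0 <= s < e < G):
            raise ValueError(f"window {(s, e)} outside grid of length {G}")
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        if s2 <= e1:
            raise ValueError("shared windows must not overlap")
    rng = np.random.default_rng(seed)
    # step boundaries around the grid points
    t_lo = grid.copy()
    t_hi = np.empty(G)
    t_hi[:-1] = grid[1:]
    t_hi[-1] = grid[-1] + (grid[-1] - grid[-2])
    out = []
    for _ in range(k):
        incr = rng.normal(0.0, noise, G - 1)
        for (s, e) in windows:
            forced = np.abs(rng.normal(0.0, noise, e - s)) + 0.1 * noise
            incr[s:e] = forced  # log-Ne rises with index -> decrease toward present
        log_ne = np.empty(G)
        log_ne[0] = math.log(base_ne) + rng.normal(0.0, noise)
        log_ne[1:] = log_ne[0] + np.cumsum(incr)
        out.append(NeTrajectory(t_lo, t_hi, np.exp(log_ne)))
    return out
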