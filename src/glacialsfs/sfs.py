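"""Folded site-frequency-spectrum construction, projection and summaries.

The central quantities are the folded SFS built from genotype calls with
missing data, its exact hypergeometric down-projection to a smaller
sample size, and the per-site nucleotide diversity

    pi = n / (L (n - 1)) * sum_sites (1 - sum_j p_j^2)

computed from folded minor-allele counts (p = i/n and 1 - p), which for
biallelic data equals the mean pairwise difference per site.  A
stochastic 1000-replicate resampling alternative to the deterministic
projection is provided for diversity estimation, along with the
normalized transform that renders the spectrum flat under the standard
neutral model.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from scipy.stats import hypergeom

from .core import MISSING, FoldedSFS, GenotypeMatrix

__all__ = [
    "build_folded_sfs",
    "project_sfs",
    "pi_from_sfs",
    "resampled_pi",
    "normalized_transform",
    "default_target_n",
]


def default_target_n(n_haploid: int) -> int:
    """Half the haploid call count, rounded down to even."""
    m = n_haploid // 2
    return m - (m % 2)


def _site_counts(gm: GenotypeMatrix, classes: Optional[Iterable[str]], max_missing: float):
    """Per retained variant site: (alt copies, called copies); plus counts
    of excluded and of monomorphic-within-sample sites."""
    if classes is None:
        mask = np.ones(gm.n_sites, dtype=bool)
    else:
        mask = gm.class_mask(classes)
    geno = gm.genotypes[:, mask]
    miss = geno == MISSING
    miss_frac = miss.mean(axis=0)
    keep = miss_frac <= max_missing
    n_excluded = int((~keep).sum())
    geno = geno[:, keep]
    called = 2 * (geno != MISSING).sum(axis=0)
    alt = np.where(geno == MISSING, 0, geno).sum(axis=0)
    return alt.astype(int), called.astype(int), n_excluded


def build_folded_sfs(
    gm: GenotypeMatrix,
    classes: Optional[Iterable[str]] = None,
    max_missing: float = 0.5,
    target_n: Optional[int] = None,
) -> FoldedSFS:
    """Folded SFS from a genotype matrix with missing data.

    Sites whose missing-call fraction exceeds ``max_missing`` are
    excluded.  Every remaining site is projected to ``target_n`` haploid
    copies by exact hypergeometric expectation (the deterministic
    counterpart of repeated down-sampling); mass projected onto count 0
    joins the monomorphic cell.  ``target_n`` defaults to half the
    haploid sample size rounded down to even.  Monomorphic surveyed sites
    of the selected classes are counted into ``L``.
    """
    n_hap = 2 * gm.n_ind
    if target_n is None:
        target_n = default_target_n(n_hap)
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    alt, called, n_excluded = _site_counts(gm, classes, max_missing)
    usable = called >= target_n
    if len(alt) and not usable.any() and (alt > 0).any():
        raise ValueError("target_n exceeds the available calls at every site")
    alt, called = alt[usable], called[usable]
    L = gm.surveyed_sites(classes) - n_excluded - int((~usable).sum())
    eta = np.zeros(target_n // 2)
    poly = (alt > 0) & (alt < called)
    for a, c in zip(alt[poly], called[poly]):
        dmin = max(0, target_n - (c - a))
        dmax = min(a, target_n)
        ds = np.arange(dmin, dmax + 1)
        pmf = hypergeom.pmf(ds, c, a, target_n)
        for d, p in zip(ds, pmf):
            f = min(d, target_n - d)
            if f >= 1:
                eta[f - 1] += p
    return FoldedSFS(eta, target_n, float(L))


def _folded_projection_matrix(n: int, m: int) -> np.ndarray:
    """P[j, i]: probability that a site with folded count i (of n) yields
    folded count j (of m) in a hypergeometric draw of m copies; j = 0
    collects the mass that becomes monomorphic."""
    P = np.zeros((m // 2 + 1, n // 2 + 1))
    for i in range(1, n // 2 + 1):
        ds = np.arange(0, min(i, m) + 1)
        pmf = hypergeom.pmf(ds, n, i, m)
        for d, p in zip(ds, pmf):
            P[min(d, m - d), i] += p
    return P


def project_sfs(sfs: FoldedSFS, m: int) -> FoldedSFS:
    """Exact hypergeometric down-projection of a folded SFS to size ``m``.

    Entry ``j`` of the output is the expectation over sites of drawing
    ``m`` of the ``n`` copies without replacement; expectations are exact
    (not resampled), ``L`` is preserved, and projected-to-monomorphic
    mass moves into the monomorphic cell.
    """
    if not 2 <= m <= sfs.n:
        raise ValueError(f"projection size must be in [2, {sfs.n}]")
    if m == sfs.n:
        return sfs.copy()
    P = _folded_projection_matrix(sfs.n, m)
    full = np.concatenate([[0.0], sfs.eta])
    out = P @ full
    return FoldedSFS(out[1:], m, sfs.L)


def pi_from_sfs(sfs: FoldedSFS) -> float:
    """Per-site nucleotide diversity from a folded spectrum.

    Sums the expected heterozygosity ``1 - p^2 - (1-p)^2`` over
    segregating sites with ``p = i/n``, scales by ``n/(n-1)`` and divides
    by the total site count ``L``.
    """
    if sfs.L <= 0:
        raise ValueError("total site count L must be positive")
    n = sfs.n
    i = np.arange(1, n // 2 + 1)
    w = 2.0 * i * (n - i) / (n * (n - 1))
    return float((sfs.eta * w).sum() / sfs.L)


def resampled_pi(
    gm: GenotypeMatrix,
    classes: Optional[Iterable[str]] = None,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    max_missing: float = 0.5,
    target_n: Optional[int] = None,
) -> float:
    """Diversity averaged over stochastic down-sampling replicates.

    Each replicate subsamples every site's called allele copies without
    replacement to ``target_n`` and evaluates the diversity estimator on
    the resulting folded spectrum; the mean over ``n_reps`` replicates is
    returned.  Its expectation equals the deterministic projection value.
    """
    n_hap = 2 * gm.n_ind
    if target_n is None:
        target_n = default_target_n(n_hap)
    alt, called, n_excluded = _site_counts(gm, classes, max_missing)
    usable = called >= target_n
    alt, called = alt[usable], called[usable]
    L = gm.surveyed_sites(classes) - n_excluded - int((~usable).sum())
    if L <= 0:
        raise ValueError("no surveyed sites left after filtering")
    poly = (alt > 0) & (alt < called)
    alt, called = alt[poly], called[poly]
    rng = np.random.default_rng(seed)
    if len(alt) == 0:
        return 0.0
    d = rng.hypergeometric(alt, called - alt, target_n, size=(n_reps, len(alt)))
    m = target_n
    het = 2.0 * d * (m - d) / (m * (m - 1))
    return float(het.sum(axis=1).mean() / L)


def normalized_transform(sfs: FoldedSFS) -> np.ndarray:
    """Scaled folded spectrum that is flat under the standard neutral model.

    phi_i = eta_i * i * (n - i) * (1 + [i == n - i]) / n, normalized to
    sum to one.  Under constant size E[eta_i] is proportional to
    n / (i (n - i) (1 + [i == n-i])), so the transform cancels the shape
    and departures (e.g., the rare-variant excess of growth) stand out.
    """
    n = sfs.n
    if sfs.eta.sum() <= 0:
        raise ValueError("cannot normalize an all-zero SFS")
    i = np.arange(1, n // 2 + 1)
    delta = (i == n - i).astype(float)
    phi = sfs.eta * i * (n - i) * (1.0 + delta) / n
    return phi / phi.sum()
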