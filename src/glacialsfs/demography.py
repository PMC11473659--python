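"""Composite-likelihood demographic inference from folded spectra.

The expected folded SFS under any piecewise-constant demography is
computed analytically: the expected time ``E[T_k]`` during which the
genealogy of ``n`` samples has ``k`` ancestral lineages follows from the
pure-death lineage-count process integrated epoch by epoch (closed-form
exponentials per epoch, via Tavare's ancestral-process probabilities),
and

    E[xi_i] = mu * L * sum_k k * E[T_k] * C(n-i-1, k-2) / C(n-1, k-1)

folded over minor counts, with the monomorphic expectation L - sum E[xi].

Model fitting maximises a Poisson composite likelihood over the folded
entries plus the monomorphic cell, with multistart Nelder-Mead over
log-scale parameters.  The module covers the single-population epoch
models (SNM / 2-epoch / 3-epoch) with AIC comparison and parametric
bootstrap, a seven-model divergence set whose two-deme expectations come
from Monte Carlo simulation with common random numbers, a stairway-style
flexible trajectory estimator (bootstrap-resampled AIC-selected epoch
fits), the glacial-cycle power study, and a mixed-population robustness
check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .core import Demography, DivergenceModel, FoldedSFS, JointSFS, NeTrajectory
from .simdata import (
    EventBudgetExceeded,
    _sim_branches_two_deme,
    _fold_joint,
    glacial_cycle_demography,
    simulate_coalescent_sfs,
)
from .sfs import build_folded_sfs, pi_from_sfs

__all__ = [
    "expected_sfs",
    "composite_loglik",
    "fit_epoch_model",
    "compare_models_aic",
    "bootstrap_ci",
    "fit_divergence_model",
    "fit_divergence_set",
    "compare_divergence_models",
    "stairway_like_fit",
    "count_reversals",
    "power_study",
    "mixed_population_check",
    "EpochFit",
    "DivergenceFit",
    "EPOCH_MODELS",
    "DIVERGENCE_MODELS",
]


# ---------------------------------------------------------------------------
# expected SFS under piecewise-constant demography


@lru_cache(maxsize=32)
def _tavare_coeffs(n: int) -> np.ndarray:
    """Coefficients c[k, j] of the ancestral lineage-count process:
    P(k lineages at scaled time tau | n at 0) = sum_j c[k,j] exp(-j(j-1)tau/2).

    Computed in exact rational arithmetic; the alternating sum limits the
    practical sample size to a few hundred before float cancellation bites.
    """
    C = np.zeros((n + 1, n + 1))
    for k in range(1, n + 1):
        for j in range(max(k, 2) if k == 1 else k, n + 1):
            sign = -1 if (j - k) % 2 else 1
            num = Fraction((2 * j - 1) * sign)
            rise_k = Fraction(1)
            for t in range(j - 1):
                rise_k *= k + t
            fall_n = Fraction(1)
            for t in range(j):
                fall_n *= n - t
            rise_n = Fraction(1)
            for t in range(j):
                rise_n *= n + t
            coeff = num * rise_k * fall_n / (
                Fraction(math.factorial(k)) * math.factorial(j - k) * rise_n
            )
            C[k, j] = float(coeff)
    return C


def _expected_tk(dem: Demography, n: int) -> np.ndarray:
    """E[T_k] (generations with exactly k ancestral lineages), k = 2..n."""
    C = _tavare_coeffs(n)
    js = np.arange(2, n + 1)
    lam = js * (js - 1) / 2.0
    # scaled-time offsets at epoch boundaries
    epochs = dem.epochs
    tk = np.zeros(n + 1)
    tau0 = 0.0
    for ei, (ne, t_start) in enumerate(epochs):
        if ei + 1 < len(epochs):
            dt = epochs[ei + 1][1] - t_start
            tau1 = tau0 + dt / (2.0 * ne)
        else:
            tau1 = math.inf
        e0 = np.exp(-lam * tau0)
        e1 = np.exp(-lam * tau1) if math.isfinite(tau1) else np.zeros_like(lam)
        integrals = (e0 - e1) / lam  # integral of exp(-lam tau) over the epoch
        for k in range(2, n + 1):
            tk[k] += 2.0 * ne * float(np.dot(C[k, 2:], integrals))
        tau0 = tau1
    return tk


@lru_cache(maxsize=32)
def _branch_weights(n: int) -> np.ndarray:
    """W[i, k] = k * C(n-i-1, k-2) / C(n-1, k-1): expected share of the
    k-lineage time carried by branches with i descendants."""
    W = np.zeros((n, n + 1))
    for i in range(1, n):
        for k in range(2, n + 1):
            num = math.comb(n - i - 1, k - 2)
            den = math.comb(n - 1, k - 1)
            W[i, k] = k * num / den
    return W


def expected_sfs(dem: Demography, n: int, mu: float, L: float) -> FoldedSFS:
    """Analytic expected folded SFS under a piecewise-constant demography.

    Exact for any epoch structure; reduces to Watterson's
    ``E[xi_i] = theta L / i`` under constant size.  Practical sample
    sizes are limited by cancellation in the ancestral-process sum
    (documented limit n <= 1000, and well-conditioned for n up to ~100).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    tk = _expected_tk(dem, n)
    W = _branch_weights(n)
    xi = mu * L * (W[:, 2:] @ tk[2:])  # xi[i], i = 1..n-1 at index i
    eta = np.zeros(n // 2)
    for i in range(1, n // 2 + 1):
        eta[i - 1] = xi[i] + (xi[n - i] if i != n - i else 0.0)
    return FoldedSFS(eta, n, L)


# ---------------------------------------------------------------------------
# composite likelihood


def composite_loglik(obs: FoldedSFS, exp: FoldedSFS) -> float:
    """Poisson composite log-likelihood of an observed folded SFS.

    Treats every folded entry and the monomorphic cell as independent
    Poisson counts with the expected spectrum as mean:
    ``sum [o ln e - e - ln o!]``.  Returns -inf when a cell with observed
    mass has zero (or negative) expectation.
    """
    if obs.n != exp.n:
        raise ValueError("sample sizes differ between observed and expected SFS")
    o = np.concatenate([[obs.n_mono], obs.eta])
    e = np.concatenate([[exp.n_mono], exp.eta])
    if np.any(e <= 0):
        if np.any((e <= 0) & (o > 0)):
            return -math.inf
        o = o[e > 0]
        e = e[e > 0]
    return float(np.sum(o * np.log(e) - e - gammaln(o + 1)))


# ---------------------------------------------------------------------------
# multistart optimisation over log-scale parameters


def _multistart(objective, log_bounds, n_starts, rng, maxiter=400, extra_x0=()):
    """Multistart Nelder-Mead in log10-parameter space within a box.

    ``extra_x0`` adds deterministic starting points (e.g. warm starts
    from a nested model) to the random log-uniform ones."""
    lo = np.log10([b[0] for b in log_bounds])
    hi = np.log10([b[1] for b in log_bounds])

    def penalised(x):
        if np.any(x < lo) or np.any(x > hi):
            return 1e12 + float(np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0)))
        val = objective(10.0**x)
        return val if math.isfinite(val) else 1e12  # -inf loglik: invalid region

    best = None
    converged = False
    x0s = [rng.uniform(lo, hi) for _ in range(n_starts)]
    x0s += [np.clip(np.asarray(x), lo, hi) for x in extra_x0]
    for x0 in x0s:
        res = minimize(
            penalised, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    params = np.clip(10.0**best.x, [b[0] for b in log_bounds], [b[1] for b in log_bounds])
    return params, -float(best.fun), converged


# ---------------------------------------------------------------------------
# epoch models


EPOCH_MODELS = {
    "SNM": ("NCUR",),
    "epoch2": ("NCUR", "NANC", "TBOT"),
    "epoch3": ("NCUR", "NBOT", "NANC", "TBOT", "TENDBOT"),
}


@dataclass
class EpochFit:
    """Best multistart fit of a single-population epoch model."""

    model_name: str
    params: dict
    loglik: float
    aic: float
    n_starts: int
    converged: bool
    data_fingerprint: tuple = ()

    @property
    def k(self) -> int:
        return len(self.params)


def _epoch_demography(model_name: str, values: Sequence[float]) -> Demography:
    if model_name == "SNM":
        (ncur,) = values
        return Demography(((ncur, 0.0),))
    if model_name == "epoch2":
        ncur, nanc, tbot = values
        return Demography(((ncur, 0.0), (nanc, tbot)))
    if model_name == "epoch3":
        # internally the second change time is TBOT + a positive increment,
        # which enforces TENDBOT > TBOT
        ncur, nbot, nanc, tbot, dt = values
        return Demography(((ncur, 0.0), (nbot, tbot), (nanc, tbot + dt)))
    raise ValueError(f"unknown epoch model {model_name!r}")


def _fingerprint(obs: FoldedSFS) -> tuple:
    return (obs.n, round(float(obs.L), 6), round(float(obs.eta.sum()), 6))


def fit_epoch_model(
    obs: FoldedSFS,
    model: str,
    mu: float,
    n_starts: int = 100,
    bounds: tuple = (10.0, 1e7),
    seed: Optional[int] = None,
    maxiter: int = 400,
) -> EpochFit:
    """Maximum composite-likelihood fit of SNM / 2-epoch / 3-epoch models.

    Parameters (sizes and event times) take log-uniform starts within
    ``bounds`` (default prior range 10..1e7) and are optimised on the log
    scale with Nelder-Mead; the best of ``n_starts`` runs is returned.
    """
    if model not in EPOCH_MODELS:
        raise ValueError(f"model must be one of {sorted(EPOCH_MODELS)}")
    names = EPOCH_MODELS[model]
    rng = np.random.default_rng(seed)
    log_bounds = [bounds] * len(names)

    def objective(values):
        dem = _epoch_demography(model, values)
        exp = expected_sfs(dem, obs.n, mu, obs.L)
        return -composite_loglik(obs, exp)

    params, loglik, converged = _multistart(objective, log_bounds, n_starts, rng, maxiter)
    values = dict(zip(names, params))
    if model == "epoch3":
        values["TENDBOT"] = values["TBOT"] + values["TENDBOT"]  # increment -> absolute
    k = len(names)
    return EpochFit(
        model_name=model,
        params=values,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_starts=n_starts,
        converged=converged,
        data_fingerprint=_fingerprint(obs),
    )


def compare_models_aic(fits: Sequence) -> pd.DataFrame:
    """Rank fits of the same dataset by AIC (ascending, with delta AIC)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {f.data_fingerprint for f in fits if f.data_fingerprint}
    if len(fps) > 1:
        raise ValueError("fits come from different datasets")
    rows = [
        {"model": f.model_name, "k": f.k, "loglik": f.loglik, "aic": f.aic}
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def bootstrap_ci(
    best: EpochFit,
    obs: FoldedSFS,
    mu: float,
    n_boot: int = 100,
    n_starts: int = 100,
    level: float = 0.95,
    seed: Optional[int] = None,
    maxiter: int = 400,
) -> dict:
    """Parametric-bootstrap confidence intervals for an epoch fit.

    Simulates ``n_boot`` Poisson spectra at the fitted expectation,
    refits each with the same model and settings, and takes empirical
    percentile intervals; failed refits are dropped and counted.
    """
    if not best.converged:
        raise ValueError("cannot bootstrap an unconverged fit")
    names = EPOCH_MODELS[best.model_name]
    values = [best.params[n] for n in names]
    if best.model_name == "epoch3":
        values[4] = best.params["TENDBOT"] - best.params["TBOT"]
    dem = _epoch_demography(best.model_name, values)
    exp = expected_sfs(dem, obs.n, mu, obs.L)
    rng = np.random.default_rng(seed)
    samples = {n: [] for n in best.params}
    n_failed = 0
    for _ in range(n_boot):
        eta_b = rng.poisson(exp.eta)
        obs_b = FoldedSFS(eta_b.astype(float), obs.n, obs.L)
        try:
            fit_b = fit_epoch_model(
                obs_b, best.model_name, mu,
                n_starts=n_starts, seed=int(rng.integers(2**31)), maxiter=maxiter,
            )
        except Exception:
            n_failed += 1
            continue
        for n, v in fit_b.params.items():
            samples[n].append(v)
    alpha = (1 - level) / 2
    out = {
        n: (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
        for n, v in samples.items()
    }
    out["_n_failed"] = n_failed
    return out


# ---------------------------------------------------------------------------
# divergence models (two demes)


DIVERGENCE_MODELS = {
    # name -> (parameter names, has_migration, has_ancestral_change)
    "div_strict": (("NPOP1", "NPOP2", "NCUR", "TDIV"), False, False),
    "div_mig": (("NPOP1", "NPOP2", "NCUR", "TDIV", "N1M21", "N2M12"), True, False),
    "div_anc": (("NPOP1", "NPOP2", "NCUR", "NANC", "TDIV", "TSEP"), False, True),
    "div_mig_anc": (
        ("NPOP1", "NPOP2", "NCUR", "NANC", "TDIV", "TSEP", "N1M21", "N2M12"),
        True,
        True,
    ),
}

PANMICTIC_MODELS = ("SNM", "epoch2", "epoch3")
ALL_DIVERGENCE_SET = PANMICTIC_MODELS + tuple(DIVERGENCE_MODELS)


@dataclass
class DivergenceFit:
    model_name: str
    params: dict
    loglik: float
    aic: float
    n_starts: int
    converged: bool
    data_fingerprint: tuple = ()

    @property
    def k(self) -> int:
        return len(self.params)


def _divergence_model(name: str, values: Sequence[float]) -> DivergenceModel:
    names, has_mig, has_anc = DIVERGENCE_MODELS[name]
    p = dict(zip(names, values))
    return DivergenceModel(
        npop1=p["NPOP1"],
        npop2=p["NPOP2"],
        ncur=p["NCUR"],
        tdiv=p["TDIV"],
        nanc=p.get("NANC", 0.0),
        tsep=p["TDIV"] + p["TSEP"] if has_anc else 0.0,  # TSEP fitted as increment
        n1m21=p.get("N1M21", 0.0),
        n2m12=p.get("N2M12", 0.0),
        has_migration=has_mig,
        has_ancestral_change=has_anc,
    )


def _expected_joint(model: DivergenceModel, n1, n2, mu, L, reps, seed) -> np.ndarray:
    """Monte Carlo expected joint spectrum (counts), common random numbers:
    the same seed is reused at every optimiser evaluation so the
    stochastic objective is a fixed function of the parameters.  A tight
    per-genealogy event budget rejects near-panmictic migration corners
    whose genealogies would be pathologically expensive."""
    from ._twodeme_fast import two_deme_branch_lengths

    m1 = model.n1m21 / (2.0 * model.npop1) if model.has_migration else 0.0
    m2 = model.n2m12 / (2.0 * model.npop2) if model.has_migration else 0.0
    raw, ok = two_deme_branch_lengths(
        n1, n2, model.npop1, model.npop2, model.ncur,
        model.nanc if model.has_ancestral_change else model.ncur,
        model.tdiv, model.tsep, model.has_ancestral_change,
        m1, m2, reps, seed, 500,
    )
    if not ok:
        raise EventBudgetExceeded("two-deme genealogy event budget exceeded")
    lengths = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if raw[i, j]:
                fi, fj = _fold_joint(i, j, n1, n2)
                lengths[fi, fj] += raw[i, j]
    exp = mu * (L / reps) * lengths
    exp[0, 0] = max(L - exp.sum(), 1e-8)
    return exp


def fit_divergence_model(
    jsfs: JointSFS,
    model_id: str,
    mu: float,
    bounds: tuple = (10.0, 1e9),
    mig_bounds: tuple = (1e-4, 1e4),
    n_starts: int = 100,
    seed: Optional[int] = None,
    mc_reps: int = 200,
    maxiter: int = 200,
    epoch_bounds: tuple = (10.0, 1e7),
    n_scan: int = 200,
    extra_starts: Sequence[dict] = (),
) -> DivergenceFit:
    """Composite-likelihood fit of one of the seven divergence-set models.

    The four two-deme models fit the jointly folded spectrum with Monte
    Carlo expectations (common random numbers across evaluations); the
    three panmictic reference models (SNM / 2-epoch / 3-epoch) fit the
    pooled spectrum of all samples.  Size and time parameters use
    log-uniform priors in ``bounds`` (default 10..1e9), effective-migrant
    parameters in ``mig_bounds`` (default 1e-4..1e4).  A randomized
    ``n_scan``-point coarse scan of the prior box seeds ``n_starts``
    Nelder-Mead refinements at full Monte Carlo resolution.
    """
    if jsfs.counts[1:, 1:].sum() + jsfs.counts[0, 1:].sum() + jsfs.counts[1:, 0].sum() == 0:
        raise ValueError("degenerate joint SFS: no polymorphic sites")
    if model_id in PANMICTIC_MODELS:
        pooled = jsfs.pooled()
        fit = fit_epoch_model(
            pooled, model_id, mu,
            n_starts=n_starts, bounds=epoch_bounds, seed=seed, maxiter=maxiter,
        )
        return DivergenceFit(
            model_name=model_id,
            params=fit.params,
            loglik=fit.loglik,
            aic=fit.aic,
            n_starts=n_starts,
            converged=fit.converged,
            data_fingerprint=(jsfs.n1, jsfs.n2, round(float(jsfs.L), 6)),
        )
    if model_id not in DIVERGENCE_MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    names, has_mig, _ = DIVERGENCE_MODELS[model_id]
    log_bounds = [mig_bounds if n.startswith("N1M") or n.startswith("N2M") else bounds
                  for n in names]
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31))
    obs = jsfs.counts.ravel()
    log_fact = gammaln(obs + 1).sum()

    def make_objective(reps):
        def objective(values):
            model = _divergence_model(model_id, values)
            try:
                exp = _expected_joint(model, jsfs.n1, jsfs.n2, mu, jsfs.L, reps, crn_seed)
            except EventBudgetExceeded:
                return math.inf  # effectively-panmictic corner; covered elsewhere
            e = np.maximum(exp.ravel(), 1e-10)
            return -(float(np.sum(obs * np.log(e) - e)) - log_fact)

        return objective

    objective = make_objective(mc_reps)
    # stage 1: cheap randomized scan of the prior box to seed the local
    # optimizer (the stochastic surface has many basins)
    lo = np.log10([b[0] for b in log_bounds])
    hi = np.log10([b[1] for b in log_bounds])
    scan_obj = make_objective(max(20, mc_reps // 3))
    scan_x = rng.uniform(lo, hi, size=(n_scan, len(names)))
    scan_f = np.array([scan_obj(10.0**x) for x in scan_x])
    order = np.argsort(scan_f)
    starts = [scan_x[i] for i in order[: max(1, n_starts)]]
    for extra in extra_starts:
        # warm starts, e.g. a nested model's solution with near-zero migration
        vals = np.array([extra.get(n, math.sqrt(b[0] * b[1]))
                         for n, b in zip(names, log_bounds)])
        starts.append(np.clip(np.log10(vals), lo, hi))
    # stage 2: Nelder-Mead refinement at full Monte Carlo resolution,
    # then a short polish on a smoother (higher-reps) surface, and a final
    # likelihood evaluation at high resolution so AIC comparisons across
    # models are not dominated by Monte Carlo noise
    def boxed(obj):
        def f(x):
            if np.any(x < lo) or np.any(x > hi):
                return 1e12 + float(np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0)))
            return min(obj(10.0**x), 1e12)

        return f

    best = None
    converged = False
    for x0 in starts:
        # a wide initial simplex (±0.7 decade per coordinate) lets the
        # search traverse parameter ridges despite Monte Carlo roughness
        simplex = np.vstack([x0] + [x0 + 0.7 * e for e in np.eye(len(x0))])
        simplex = np.clip(simplex, lo, hi - 1e-6)
        res = minimize(
            boxed(objective), x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4,
                     "initial_simplex": simplex},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    polish = minimize(
        boxed(make_objective(5 * mc_reps)), best.x, method="Nelder-Mead",
        options={"maxiter": max(30, maxiter // 3), "xatol": 1e-4, "fatol": 1e-4},
    )
    x_final = polish.x if polish.fun < 1e11 else best.x
    # the reported solution is the best of the refined point and the
    # supplied warm starts under one high-resolution evaluation; for
    # nested warm starts this guarantees the richer model never scores
    # below the solution it was seeded from
    final_obj = boxed(make_objective(10 * mc_reps))
    cands = [x_final] + starts[len(order[: max(1, n_starts)]):]
    vals = [final_obj(np.asarray(x)) for x in cands]
    x_best = cands[int(np.argmin(vals))]
    params = np.clip(10.0**np.asarray(x_best), [b[0] for b in log_bounds], [b[1] for b in log_bounds])
    loglik = -float(min(vals))
    values = dict(zip(names, params))
    if "TSEP" in values:
        values["TSEP"] = values["TDIV"] + values["TSEP"]
    k = len(names)
    return DivergenceFit(
        model_name=model_id,
        params=values,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_starts=n_starts,
        converged=converged,
        data_fingerprint=(jsfs.n1, jsfs.n2, round(float(jsfs.L), 6)),
    )


def fit_divergence_set(
    jsfs: JointSFS,
    model_ids: Sequence[str] = ("div_strict", "div_mig"),
    mu: float = 1e-8,
    seed: Optional[int] = None,
    **kwargs,
) -> dict:
    """Fit several divergence-set models with nested warm starts.

    Models are fitted in the given order; each two-deme fit passes its
    solution on as an extra start for every later (richer) two-deme
    model, with absent parameters (e.g. migration) started near the
    bottom of their prior.  This exploits the nesting of the model
    family: the migration models contain the strict-divergence ones in
    the limit of vanishing migrant numbers.
    """
    fits = {}
    # moment anchors: marginal Watterson sizes per deme, used to seed the
    # migration-drift-equilibrium regime (an old split with gene flow)
    def watterson_n(sfs_marginal):
        a_n = float(np.sum(1.0 / np.arange(1, sfs_marginal.n)))
        return max(sfs_marginal.segregating / (sfs_marginal.L * a_n) / (4.0 * mu), 10.0)

    n1_hat = watterson_n(jsfs.marginal(1))
    n2_hat = watterson_n(jsfs.marginal(2))
    n_bar = math.sqrt(n1_hat * n2_hat)
    warm: list = []
    for mid in model_ids:
        extra = []
        if mid in ("div_mig", "div_mig_anc"):
            extra += [
                {
                    "NPOP1": n1_hat, "NPOP2": n2_hat, "NCUR": n_bar,
                    "TDIV": 100.0 * n_bar, "N1M21": nm, "N2M12": nm,
                    "NANC": n_bar, "TSEP": 100.0 * n_bar,
                }
                for nm in (0.3, 3.0, 30.0)
            ]
        for w in warm:
            variants = [{"N1M21": 1e-3, "N2M12": 1e-3}]
            if mid in ("div_mig", "div_mig_anc") and "N1M21" not in w:
                variants += [
                    {"N1M21": nm, "N2M12": nm, "TDIV": 100.0 * n_bar}
                    for nm in (0.3, 3.0, 30.0)
                ]
            for v in variants:
                e = dict(w)
                e.update({k: val for k, val in v.items() if k not in w})
                e.update({k: val for k, val in v.items() if k.startswith("N1M") or k.startswith("N2M") or k == "TDIV"})
                if mid in ("div_anc", "div_mig_anc"):
                    e.setdefault("NANC", e.get("NCUR", 1e4))
                    e.setdefault("TSEP", e.get("TDIV", 1e4))
                extra.append(e)
        fit = fit_divergence_model(
            jsfs, mid, mu, seed=seed, extra_starts=extra, **kwargs
        )
        fits[mid] = fit
        if mid in DIVERGENCE_MODELS:
            w = dict(fit.params)
            if "TSEP" in w:  # stored as absolute; warm starts use increments
                w["TSEP"] = max(w["TSEP"] - w["TDIV"], 10.0)
            warm.append(w)
    return fits


def compare_divergence_models(fits: Sequence[DivergenceFit]) -> pd.DataFrame:
    """AIC table over divergence-set fits of the same joint spectrum."""
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits come from different datasets")
    rows = [
        {"model": f.model_name, "k": f.k, "loglik": f.loglik, "aic": f.aic}
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


# ---------------------------------------------------------------------------
# stairway-style flexible trajectories


def default_breakpoints(n: int) -> tuple:
    """Stairway-style breakpoint counts: n/4, n/2, 3n/4, n-2."""
    return (max(2, n // 4), n // 2, 3 * n // 4, n - 2)


def _free_epoch_fit(obs, mu, n_epochs, rng, n_starts, bounds, time_bounds, maxiter,
                    warm: Optional[Demography] = None):
    """Fit a piecewise-constant model with ``n_epochs`` sizes and free
    change times (times parameterised as positive increments).

    ``warm`` optionally supplies a fitted model with one epoch fewer;
    its solution, with the terminal epoch split in two, seeds an extra
    local search (the model family is nested, so the richer fit should
    never be worse)."""
    k_sizes = n_epochs
    k_times = n_epochs - 1
    log_bounds = [bounds] * k_sizes + [time_bounds] * k_times

    def build(values):
        sizes = values[:k_sizes]
        incr = values[k_sizes:]
        times = np.concatenate([[0.0], np.cumsum(incr)])
        return Demography(tuple(zip(sizes, times)))

    def objective(values):
        exp = expected_sfs(build(values), obs.n, mu, obs.L)
        return -composite_loglik(obs, exp)

    extra_x = []
    if warm is not None and warm.n_epochs == n_epochs - 1:
        sizes = [n for n, _ in warm.epochs] + [warm.epochs[-1][0]]
        times = [t for _, t in warm.epochs]
        t_last = max(times[-1], time_bounds[0] * 2)
        incr = list(np.diff(times)) + [t_last]  # split the terminal epoch
        vec = np.clip(sizes, *bounds).tolist() + np.clip(incr, *time_bounds).tolist()
        extra_x.append(np.log10(vec))
    params, loglik, _ = _multistart(
        objective, log_bounds, n_starts, rng, maxiter=maxiter, extra_x0=extra_x
    )
    k = k_sizes + k_times
    return build(params), loglik, 2 * k - 2 * loglik


def stairway_like_fit(
    obs: FoldedSFS,
    mu: float,
    gen_time_years: float = 1.0,
    breakpoints: Optional[Sequence[int]] = None,
    train_frac: float = 0.67,
    n_boot: int = 200,
    seed: Optional[int] = None,
    n_starts: int = 4,
    maxiter: int = 250,
    ne_bounds: tuple = (10.0, 1e7),
    grid_size: int = 48,
) -> NeTrajectory:
    """Model-flexible Ne trajectory from bootstrap-resampled epoch fits.

    Each of ``n_boot`` replicates multinomially resamples
    ``train_frac * L`` sites from the observed spectrum (monomorphic cell
    included), fits piecewise-constant models with 2 up to
    ``len(breakpoints) + 1`` epochs and free change times, and keeps the
    AIC-best model.  The trajectory is the per-time median Ne across
    replicates on a log-spaced time grid, with 2.5/97.5 percentile bands,
    scaled to years via ``gen_time_years``.
    """
    if obs.n < 8:
        raise ValueError("need n >= 8 for a flexible trajectory")
    if obs.segregating < 10 * obs.n:
        raise ValueError(
            f"insufficient segregating sites ({obs.segregating:.0f} < {10 * obs.n})"
        )
    if breakpoints is None:
        breakpoints = default_breakpoints(obs.n)
    n_models = len(breakpoints) + 1  # epoch counts 2..n_models
    rng = np.random.default_rng(seed)
    p = np.concatenate([[obs.n_mono], obs.eta])
    p = np.maximum(p, 0)
    p = p / p.sum()
    total = int(round(train_frac * obs.L))
    # report only over the genealogical depth the data inform: the grid is
    # anchored on the Watterson size (TMRCA scale ~ 4N generations)
    a_n = np.sum(1.0 / np.arange(1, obs.n))
    n_watterson = obs.segregating / (obs.L * a_n) / (4.0 * mu)
    t_min = max(1.0, 0.002 * 4.0 * n_watterson)
    t_max = 8.0 * 4.0 * n_watterson
    grid = np.logspace(np.log10(t_min), np.log10(t_max), grid_size)  # generations
    time_bounds = (10.0, 1e7)
    ne_curves = np.empty((n_boot, grid_size))
    for b in range(n_boot):
        draw = rng.multinomial(total, p)
        obs_b = FoldedSFS(draw[1:].astype(float), obs.n, float(total))
        best = None
        prev = None
        for n_epochs in range(2, n_models + 1):
            dem, loglik, aic = _free_epoch_fit(
                obs_b, mu, n_epochs, rng, n_starts, ne_bounds, time_bounds, maxiter,
                warm=prev,
            )
            prev = dem
            if best is None or aic < best[1]:
                best = (dem, aic)
        dem = best[0]
        ne_curves[b] = [dem.ne_at(t) for t in grid]
    med = np.median(ne_curves, axis=0)
    lo = np.quantile(ne_curves, 0.025, axis=0)
    hi = np.quantile(ne_curves, 0.975, axis=0)
    t_lo = grid * gen_time_years
    t_hi = np.empty_like(t_lo)
    t_hi[:-1] = t_lo[1:]
    t_hi[-1] = t_lo[-1] * (t_lo[-1] / t_lo[-2])
    return NeTrajectory(
        t_lo=t_lo, t_hi=t_hi, ne=med, mu=mu, gen_time_years=gen_time_years,
        ne_lo=lo, ne_hi=hi,
    )


def count_reversals(
    ne: np.ndarray, min_rel_change: float = 0.10, t: Optional[np.ndarray] = None,
    t_max: Optional[float] = None,
) -> int:
    """Number of direction changes in an Ne series, ignoring wiggles whose
    relative amplitude stays below ``min_rel_change`` (zigzag rule).
    Optionally restricted to steps with ``t < t_max``."""
    ne = np.asarray(ne, dtype=float)
    if t_max is not None:
        if t is None:
            raise ValueError("t_max needs the matching time axis")
        ne = ne[np.asarray(t) < t_max]
    if len(ne) < 3:
        return 0
    reversals = 0
    direction = 0
    extremum = ne[0]
    for v in ne[1:]:
        if direction == 0:
            if abs(v / extremum - 1) >= min_rel_change:
                direction = 1 if v > extremum else -1
                extremum = v
            else:
                extremum = max(extremum, v) if v > extremum else extremum
        elif direction > 0:
            if v > extremum:
                extremum = v
            elif (extremum - v) / extremum >= min_rel_change:
                reversals += 1
                direction = -1
                extremum = v
        else:
            if v < extremum:
                extremum = v
            elif (v - extremum) / extremum >= min_rel_change:
                reversals += 1
                direction = 1
                extremum = v
    return reversals


# the most recent full glacial-interglacial cycle spans the 15 kya
# interglacial expansion back to the previous interglacial (~240 kya)
LAST_CYCLE_YEARS = 240_000.0


def power_study(
    scenarios: Sequence[dict],
    seed: Optional[int] = None,
    n: int = 20,
    sim_reps: int = 2000,
    **stairway_kwargs,
) -> pd.DataFrame:
    """Glacial-cycle power study over a scenario grid.

    Each scenario dict supplies ``gen_time`` (years/generation), ``L``
    (surveyed bp), ``mu`` and ``ne_current``.  Per cell the ten-event
    glacial demography is built, a folded SFS of ``n = 20`` haploid
    genomes is simulated, the flexible trajectory is fitted, and the
    table reports the diversity of the simulated spectrum plus reversal
    counts over the whole trajectory and within the last glacial cycle.
    """
    rng = np.random.default_rng(seed)
    rows = []
    trajectories = []
    for sc in scenarios:
        dem = glacial_cycle_demography(sc["gen_time"], sc["ne_current"])
        s = int(rng.integers(2**31))
        obs = simulate_coalescent_sfs(dem, n, sc["L"], sc["mu"], reps=sim_reps, seed=s)
        traj = stairway_like_fit(
            obs, sc["mu"], gen_time_years=sc["gen_time"],
            seed=int(rng.integers(2**31)), **stairway_kwargs,
        )
        t_mid = (traj.t_lo + traj.t_hi) / 2
        rows.append(
            {
                **sc,
                "pi": pi_from_sfs(obs),
                "segregating": obs.segregating,
                "reversals_total": count_reversals(traj.ne),
                "reversals_last_cycle": count_reversals(
                    traj.ne, t=t_mid, t_max=LAST_CYCLE_YEARS
                ),
                "ne_recent": traj.ne[0],
                "ne_ancient": traj.ne[-1],
            }
        )
        trajectories.append(traj)
    out = pd.DataFrame(rows)
    out.attrs["trajectories"] = trajectories
    return out


def mixed_population_check(
    gm,
    mu: float,
    gen_time_years: float = 1.0,
    seed: Optional[int] = None,
    classes: Optional[Sequence[str]] = None,
    **stairway_kwargs,
) -> dict:
    """Pooled-vs-separate trajectory robustness check.

    Builds spectra for the two populations pooled and for each population
    separately, fits the flexible trajectory to all three, and reports
    the maximum absolute log-ratio between the pooled trajectory and each
    separate one over the common time grid.
    """
    pops = list(pd.unique(gm.pop))
    if len(pops) != 2:
        raise ValueError("expected exactly two population labels")
    rng = np.random.default_rng(seed)
    out = {"trajectories": {}}
    sfs_pooled = build_folded_sfs(gm, classes=classes)
    out["trajectories"]["pooled"] = stairway_like_fit(
        sfs_pooled, mu, gen_time_years, seed=int(rng.integers(2**31)), **stairway_kwargs
    )
    for p in pops:
        sub = gm.subset_individuals(gm.pop == p)
        sfs_p = build_folded_sfs(sub, classes=classes)
        out["trajectories"][p] = stairway_like_fit(
            sfs_p, mu, gen_time_years, seed=int(rng.integers(2**31)), **stairway_kwargs
        )
    # compare on the overlap of the spans, sampled on a common log grid
    trajs = out["trajectories"]
    t0 = max(t.t_lo[0] for t in trajs.values())
    t1 = min(t.t_hi[-1] for t in trajs.values())
    divergence = float("nan")
    if t1 > t0:
        times = np.logspace(np.log10(t0), np.log10(t1), 25)
        pooled_vals = np.array([trajs["pooled"].ne_at(t) for t in times])
        divergence = 0.0
        for p in pops:
            vals = np.array([trajs[p].ne_at(t) for t in times])
            divergence = max(divergence, float(np.max(np.abs(np.log(pooled_vals / vals)))))
    out["max_log_ratio"] = divergence
    return out
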