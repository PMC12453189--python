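"""Posterior sampling and diagnostics for the persistence model.

The default engine is an adaptive random-walk Metropolis-within-Gibbs sampler
over the nine scalar parameters (three ecoregion intercepts, three persistence
slopes, detection intercept/trend/effort slope) against the *marginalized*
likelihood of :mod:`cjspersist.likelihood` — the latent extirpation year is
summed out analytically, so no state augmentation is needed and the target is
exact.  Proposal scales adapt toward ~0.37 acceptance during burn-in and are
frozen afterwards.

A second, latent-state-augmented sampler (Gibbs on the extirpation year,
Metropolis on the parameters given the imputed states) is provided purely as
an internal cross-check: the two samplers target the same posterior and their
draws must be statistically indistinguishable.

Diagnostics: split-chain Brooks-Gelman-Rubin statistics, and posterior
predictive checks comparing the mean number of detected populations in
chosen year windows between replicated and observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .likelihood import (
    ModelData,
    Params,
    _detection_tables,
    _pop_loglik,
    invlogit,
)


@dataclass
class ModelSpec:
    """Chain protocol and priors.

    Defaults mirror the study protocol: three chains of 100,000 iterations,
    the first 50,000 discarded, every third of the remainder retained.
    Priors are independent Normal(0, sd=10) on every logit/linear-scale
    parameter ("uninformative" on the probability scale).
    """

    year_range: tuple[int, int] = (1950, 2024)
    t_ref: float | None = None  # default: midpoint year
    chains: int = 3
    iterations: int = 100_000
    burn_in: int = 50_000
    thin: int = 3
    prior_sd: float = 10.0
    seed: int = 0
    max_persist_draws: int = 4000  # per chain, for per-population quantiles

    def __post_init__(self) -> None:
        if self.year_range[1] <= self.year_range[0]:
            raise ValueError("year_range end must exceed start")
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        if self.thin < 1 or self.burn_in >= self.iterations:
            raise ValueError("invalid burn-in/thinning")


@dataclass
class PosteriorDraws:
    """Retained samples plus per-population persistence posteriors."""

    thetas: np.ndarray  # (chains, n_keep, P)
    param_names: list[str]
    ecoregion_names: tuple[str, ...]
    persist_mean: np.ndarray  # (N,) posterior mean of P(alive in final year)
    persist_draws: np.ndarray  # (n_stored_total, N)
    acceptance: np.ndarray  # (chains, P)
    spec: ModelSpec
    pop_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.thetas.shape[0] * self.thetas.shape[1]

    def flat(self) -> np.ndarray:
        return self.thetas.reshape(-1, self.thetas.shape[2])

    def persistence_table(self) -> pd.DataFrame:
        qs = np.percentile(self.persist_draws, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "pop_id": self.pop_ids or [f"pop{i:04d}" for i in range(len(self.persist_mean))],
                "persistence_mean": self.persist_mean,
                "persistence_sd": self.persist_draws.std(axis=0),
                "persistence_q2.5": qs[0],
                "persistence_q97.5": qs[1],
            }
        )


# ------------------------------------------------------------- chain kernel

@njit(cache=True)
def _phi_fill(idx, theta, R, eco, hwv, phi):
    for kk in range(idx.size):
        i = idx[kk]
        eta = theta[eco[i]] + theta[R] * hwv[i, 0] + theta[R + 1] * hwv[i, 1] + theta[R + 2] * hwv[i, 2]
        if eta >= 0.0:
            phi[i] = 1.0 / (1.0 + np.exp(-eta))
        else:
            ex = np.exp(eta)
            phi[i] = ex / (1.0 + ex)


@njit(cache=True)
def _run_chain(
    y, L, code, code_dt, code_e, eco, hwv, R,
    eco_order, eco_off,
    theta0, prior_sd, n_iter, burn, thin, persist_stride, seed,
):
    np.random.seed(seed)
    N, T = y.shape
    P = theta0.size
    K = code_dt.size
    all_idx = np.arange(N)

    theta = theta0.copy()
    lp = np.empty(K); l1p = np.empty(K); omp = np.empty(K)
    lp2 = np.empty(K); l1p2 = np.empty(K); omp2 = np.empty(K)
    _detection_tables(theta[R + 3], theta[R + 4], theta[R + 5], code_dt, code_e, lp, l1p, omp)
    phi = np.empty(N); phi2 = np.empty(N)
    ll = np.empty(N); ll2 = np.empty(N)
    persist = np.empty(N); persist2 = np.empty(N)
    _phi_fill(all_idx, theta, R, eco, hwv, phi)
    _pop_loglik(all_idx, phi, y, L, code, lp, l1p, omp, ll, persist)

    log_step = np.full(P, np.log(0.2))
    acc = np.zeros(P)
    n_prop = np.zeros(P)

    n_keep = (n_iter - burn + thin - 1) // thin
    out = np.empty((n_keep, P))
    n_pstore = (n_keep + persist_stride - 1) // persist_stride
    pstore = np.empty((n_pstore, N))
    psum = np.zeros(N)
    kept = 0
    stored = 0

    for it in range(n_iter):
        for j in range(P):
            old = theta[j]
            step = np.exp(log_step[j])
            new = old + step * np.random.normal()
            if j < R:
                idx = eco_order[eco_off[j]:eco_off[j + 1]]
            else:
                idx = all_idx
            delta = (old * old - new * new) / (2.0 * prior_sd * prior_sd)
            theta[j] = new
            if j < R + 3:
                _phi_fill(idx, theta, R, eco, hwv, phi2)
                _pop_loglik(idx, phi2, y, L, code, lp, l1p, omp, ll2, persist2)
                use_det2 = False
            else:
                _detection_tables(theta[R + 3], theta[R + 4], theta[R + 5], code_dt, code_e, lp2, l1p2, omp2)
                _pop_loglik(idx, phi, y, L, code, lp2, l1p2, omp2, ll2, persist2)
                use_det2 = True
            for kk in range(idx.size):
                i = idx[kk]
                delta += ll2[i] - ll[i]
            a = np.exp(delta) if delta < 0.0 else 1.0
            if np.random.random() < a:
                for kk in range(idx.size):
                    i = idx[kk]
                    ll[i] = ll2[i]
                    persist[i] = persist2[i]
                    if not use_det2:
                        phi[i] = phi2[i]
                if use_det2:
                    for k in range(K):
                        lp[k] = lp2[k]; l1p[k] = l1p2[k]; omp[k] = omp2[k]
                acc[j] += 1.0
            else:
                theta[j] = old
            n_prop[j] += 1.0
            if it < burn:
                gamma = 2.0 / (1.0 + it) ** 0.6
                log_step[j] += gamma * (a - 0.37)
                if log_step[j] < -12.0:
                    log_step[j] = -12.0
                elif log_step[j] > 6.0:
                    log_step[j] = 6.0
        if it >= burn and (it - burn) % thin == 0:
            for j in range(P):
                out[kept, j] = theta[j]
            psum += persist
            if kept % persist_stride == 0 and stored < n_pstore:
                for i in range(N):
                    pstore[stored, i] = persist[i]
                stored += 1
            kept += 1

    rates = acc / np.maximum(n_prop, 1.0)
    return out[:kept], pstore[:stored], psum / max(kept, 1), rates


def run_mcmc(
    spec: ModelSpec,
    data: ModelData,
    pop_ids: list[str] | None = None,
    init_sd: float = 1.0,
    max_init_retries: int = 20,
) -> PosteriorDraws:
    """Sample the posterior with the marginalized Metropolis-within-Gibbs sampler.

    Chains start from independent N(0, ``init_sd``) draws (re-drawn, up to
    ``max_init_retries`` times, if the likelihood is non-finite there).  Fully
    deterministic given ``spec.seed``.
    """
    R = len(data.ecoregion_names)
    P = R + 6
    order = np.argsort(data.eco, kind="stable").astype(np.int64)
    off = np.zeros(R + 1, dtype=np.int64)
    for r in range(R):
        off[r + 1] = off[r] + int((data.eco == r).sum())

    ss = np.random.SeedSequence(spec.seed)
    chain_states = ss.generate_state(2 * spec.chains) % (2**31 - 1)
    persist_stride = max(
        1, ((spec.iterations - spec.burn_in + spec.thin - 1) // spec.thin) // spec.max_persist_draws
    )

    thetas = []
    pstores = []
    pmeans = []
    rates = []
    for c in range(spec.chains):
        rng = np.random.default_rng(chain_states[2 * c])
        for attempt in range(max_init_retries):
            theta0 = rng.normal(0.0, init_sd, size=P)
            from .likelihood import total_loglik

            params0 = Params.from_vector(theta0, data.ecoregion_names)
            if total_loglik(params0, data) > -1e299:
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initialization")
        out, pst, pm, rate = _run_chain(
            data.y, data.L, data.code, data.code_dt, data.code_e, data.eco, data.hwv,
            R, order, off, theta0, spec.prior_sd,
            spec.iterations, spec.burn_in, spec.thin, persist_stride,
            int(chain_states[2 * c + 1]),
        )
        thetas.append(out)
        pstores.append(pst)
        pmeans.append(pm)
        rates.append(rate)

    return PosteriorDraws(
        thetas=np.stack(thetas),
        param_names=Params.names(data.ecoregion_names),
        ecoregion_names=data.ecoregion_names,
        persist_mean=np.mean(pmeans, axis=0),
        persist_draws=np.concatenate(pstores, axis=0),
        acceptance=np.stack(rates),
        spec=spec,
        pop_ids=list(pop_ids) if pop_ids is not None else [],
    )


# ----------------------------------------------- latent-state-augmented MCMC

@njit(cache=True)
def _run_chain_augmented(
    y, L, code, code_dt, code_e, eco, hwv, R,
    theta0, prior_sd, n_iter, burn, thin, seed,
):
    """Cross-check sampler: Gibbs on the extirpation year, Metropolis on params.

    Targets the identical posterior as :func:`_run_chain`; complete-data
    likelihood given tau is phi^(tau-2) (1-phi)^[tau<=T] times the detection
    Bernoullis over the alive years.
    """
    np.random.seed(seed)
    N, T = y.shape
    P = theta0.size
    K = code_dt.size

    theta = theta0.copy()
    lp = np.empty(K); l1p = np.empty(K); omp = np.empty(K)
    lp2 = np.empty(K); l1p2 = np.empty(K); omp2 = np.empty(K)
    _detection_tables(theta[R + 3], theta[R + 4], theta[R + 5], code_dt, code_e, lp, l1p, omp)
    phi = np.empty(N)
    _phi_fill(np.arange(N), theta, R, eco, hwv, phi)
    tau = np.empty(N, dtype=np.int64)
    for i in range(N):
        tau[i] = T + 1  # start everyone alive

    log_step = np.full(P, np.log(0.2))
    n_keep = (n_iter - burn + thin - 1) // thin
    out = np.empty((n_keep, P))
    kept = 0
    w = np.empty(T + 2)

    for it in range(n_iter):
        # --- Gibbs update of extirpation years
        for i in range(N):
            Li = L[i]
            ph = phi[i]
            pw = ph ** (Li - 1)
            q = 1.0
            tot = 0.0
            for t2 in range(Li + 1, T + 2):
                if t2 <= T:
                    w[t2] = pw * (1.0 - ph) * q
                    q *= omp[code[i, t2 - 1]]
                    pw *= ph
                else:
                    w[t2] = pw * q
                tot += w[t2]
            u = np.random.random() * tot
            csum = 0.0
            pick = T + 1
            for t2 in range(Li + 1, T + 2):
                csum += w[t2]
                if u <= csum:
                    pick = t2
                    break
            tau[i] = pick

        # --- Metropolis updates of the parameters given tau
        for j in range(P):
            old = theta[j]
            new = old + np.exp(log_step[j]) * np.random.normal()
            delta = (old * old - new * new) / (2.0 * prior_sd * prior_sd)
            theta[j] = new
            if j < R + 3:
                for i in range(N):
                    if j < R and eco[i] != j:
                        continue
                    eta = theta[eco[i]] + theta[R] * hwv[i, 0] + theta[R + 1] * hwv[i, 1] + theta[R + 2] * hwv[i, 2]
                    phn = 1.0 / (1.0 + np.exp(-eta)) if eta >= 0.0 else np.exp(eta) / (1.0 + np.exp(eta))
                    pho = phi[i]
                    ti = tau[i]
                    dn = (ti - 2) * np.log(phn) + (np.log(1.0 - phn) if ti <= T else 0.0)
                    do = (ti - 2) * np.log(pho) + (np.log(1.0 - pho) if ti <= T else 0.0)
                    delta += dn - do
            else:
                _detection_tables(theta[R + 3], theta[R + 4], theta[R + 5], code_dt, code_e, lp2, l1p2, omp2)
                for i in range(N):
                    for t in range(tau[i] - 1):
                        c = code[i, t]
                        if y[i, t] == 1:
                            delta += lp2[c] - lp[c]
                        else:
                            delta += l1p2[c] - l1p[c]
            a = np.exp(delta) if delta < 0.0 else 1.0
            if np.random.random() < a:
                if j < R + 3:
                    _phi_fill(np.arange(N), theta, R, eco, hwv, phi)
                else:
                    for k in range(K):
                        lp[k] = lp2[k]; l1p[k] = l1p2[k]; omp[k] = omp2[k]
            else:
                theta[j] = old
            if it < burn:
                gamma = 2.0 / (1.0 + it) ** 0.6
                log_step[j] += gamma * (a - 0.37)
                if log_step[j] < -12.0:
                    log_step[j] = -12.0
                elif log_step[j] > 6.0:
                    log_step[j] = 6.0

        if it >= burn and (it - burn) % thin == 0:
            for j in range(P):
                out[kept, j] = theta[j]
            kept += 1
    return out[:kept]


def run_mcmc_augmented(spec: ModelSpec, data: ModelData) -> np.ndarray:
    """Run the latent-state-augmented sampler; returns (chains, n_keep, P)."""
    R = len(data.ecoregion_names)
    ss = np.random.SeedSequence(spec.seed + 7)
    states = ss.generate_state(2 * spec.chains) % (2**31 - 1)
    outs = []
    for c in range(spec.chains):
        rng = np.random.default_rng(states[2 * c])
        theta0 = rng.normal(0.0, 1.0, size=R + 6)
        outs.append(
            _run_chain_augmented(
                data.y, data.L, data.code, data.code_dt, data.code_e, data.eco, data.hwv,
                R, theta0, spec.prior_sd, spec.iterations, spec.burn_in, spec.thin,
                int(states[2 * c + 1]),
            )
        )
    return np.stack(outs)


# ---------------------------------------------------------------- diagnostics

def gelman_rubin(chains: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-chain potential scale reduction factor (Brooks-Gelman-Rubin).

    ``chains`` has shape (m, n) or (m, n, P).  Each chain is split in half,
    then R-hat = sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the half-chain means.  Returns
    ``(rhat, degenerate)``; a parameter with zero within-chain variance is
    flagged degenerate (R-hat set to inf unless the chains also agree exactly,
    in which case it is NaN).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    m, n, P = x.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains with >= 10 samples each")
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)  # (2m, half, P)
    means = splits.mean(axis=1)  # (2m, P)
    variances = splits.var(axis=1, ddof=1)  # (2m, P)
    W = variances.mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    degenerate = W <= 0
    rhat = np.empty(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (half - 1) / half * W + B_over_n
        rhat = np.sqrt(var_plus / W)
    rhat[degenerate & (B_over_n > 0)] = np.inf
    rhat[degenerate & (B_over_n <= 0)] = np.nan
    if chains.ndim == 2:
        return rhat[0], degenerate[0]
    return rhat, degenerate


@njit(cache=True)
def _ppc_stats(thetas, R, eco, hwv, code, code_dt, code_e, win_lo, win_hi, T, seed):
    np.random.seed(seed)
    D = thetas.shape[0]
    N = eco.size
    W = win_lo.size
    K = code_dt.size
    lp = np.empty(K); l1p = np.empty(K); omp = np.empty(K)
    stats = np.zeros((D, W))
    counts = np.zeros(T)
    for d in range(D):
        _detection_tables(thetas[d, R + 3], thetas[d, R + 4], thetas[d, R + 5], code_dt, code_e, lp, l1p, omp)
        for t in range(T):
            counts[t] = 0.0
        for i in range(N):
            eta = thetas[d, eco[i]] + thetas[d, R] * hwv[i, 0] + thetas[d, R + 1] * hwv[i, 1] + thetas[d, R + 2] * hwv[i, 2]
            ph = 1.0 / (1.0 + np.exp(-eta)) if eta >= 0.0 else np.exp(eta) / (1.0 + np.exp(eta))
            alive = True
            for t in range(T):
                if t > 0 and alive:
                    alive = np.random.random() < ph
                if alive:
                    p = 1.0 - omp[code[i, t]]
                    if np.random.random() < p:
                        counts[t] += 1.0
        for wdx in range(W):
            s = 0.0
            for t in range(win_lo[wdx], win_hi[wdx] + 1):
                s += counts[t]
            stats[d, wdx] = s / (win_hi[wdx] - win_lo[wdx] + 1)
    return stats


def posterior_predictive_check(
    draws: PosteriorDraws | np.ndarray,
    data: ModelData,
    windows: tuple[tuple[int, int], ...] = ((1970, 1974), (2000, 2004), (2020, 2024)),
    n_draws: int = 500,
    seed: int = 12345,
) -> pd.DataFrame:
    """Bayesian p-values for the mean number of detected populations per window.

    For each retained draw the model simulates a full replicate state/detection
    history with the observed effort; the statistic is, per year window, the
    mean over window years of the count of populations with at least one
    detection.  The p-value is the fraction of draws whose simulated statistic
    is >= the observed one.
    """
    flat = draws.flat() if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if len(flat) > n_draws:
        sel = np.linspace(0, len(flat) - 1, n_draws).astype(int)
        flat = flat[sel]
    R = len(data.ecoregion_names)
    y0 = int(data.years[0])
    win_lo = np.array([a - y0 for a, _ in windows], dtype=np.int64)
    win_hi = np.array([b - y0 for _, b in windows], dtype=np.int64)
    if (win_lo < 0).any() or (win_hi >= data.n_years).any():
        raise ValueError("PPC window outside the modeled year range")
    stats = _ppc_stats(
        np.ascontiguousarray(flat), R, data.eco, data.hwv, data.code,
        data.code_dt, data.code_e, win_lo, win_hi, data.n_years, seed,
    )
    rows = []
    for widx, (a, b) in enumerate(windows):
        obs = data.y[:, a - y0 : b - y0 + 1].sum(axis=0).mean()
        sim = stats[:, widx]
        rows.append(
            {
                "window": f"{a}-{b}",
                "observed": float(obs),
                "simulated_mean": float(sim.mean()),
                "p_value": float((sim >= obs).mean()),
            }
        )
    return pd.DataFrame(rows)


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior means and central 95% credible intervals per parameter.

    Ecoregion intercepts and the detection intercept are additionally reported
    back-transformed through the inverse logit (per-draw, then summarized):
    ``mu_ecoregion`` is mean annual persistence at zero covariates and
    ``mu_mean`` the detection probability at the reference year under zero
    scaled effort.  A coefficient whose interval excludes 0 is flagged
    "important".
    """
    flat = draws.flat()
    R = len(draws.ecoregion_names)
    rows = []

    def _row(name, samples, transformed=False):
        lo, hi = np.percentile(samples, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(samples.mean()),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "important": bool(lo > 0 or hi < 0) if not transformed else np.nan,
            }
        )

    for j, name in enumerate(draws.param_names):
        _row(name, flat[:, j])
    for r, name in enumerate(draws.ecoregion_names):
        _row(f"mu_ecoregion[{name}]", invlogit(flat[:, r]), transformed=True)
    _row("mu_mean", invlogit(flat[:, R + 3]), transformed=True)
    return pd.DataFrame(rows)
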