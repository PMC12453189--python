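"""Marginalized likelihood of the modified Cormack-Jolly-Seber persistence model.

Each population i carries a latent alive/extirpated state z[i, t] over the
modeled years t = 1..T.  The state starts alive (every population is assumed
present in the first modeled year), survives year-to-year with a constant
population-specific annual persistence probability

    phi_i = logit^-1(alpha_{r(i)} + b_HS * h_i + b_rain * w_i + b_imp * v_i)

and extirpation is absorbing.  While alive, the population is detected in
year t with probability

    p[i, t] = logit^-1(gamma0 + b_trend * (t - t_ref) + b_effort * e[i, t]);

a dead population is never detected.  Rather than sampling z, the likelihood
marginalizes the extirpation year tau (the first dead year, tau in
{L_i + 1, ..., T + 1}, where L_i is the last detection year and tau = T + 1
means the population survived the whole span):

    L_i = sum_tau phi_i^(tau-2) * (1 - phi_i)^[tau <= T]
              * prod_{t < tau} p[i,t]^y[i,t] (1 - p[i,t])^(1 - y[i,t])

The probability the population persists in the final year given the data and
parameters is the tau = T + 1 term divided by L_i.  Populations detected only
before the first modeled year enter with an all-zero history and L_i = 1
(year-one presence assumed, year-one non-detection observed).

Detection cells sharing a (year, scaled-effort) value are collapsed into a
code table so a chain iteration touches each distinct logistic value once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .histories import DetectionMatrix, EffortMatrix


def invlogit(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass
class Params:
    """Model parameters on their sampling (logit/linear) scales.

    ``alpha`` holds one logit-scale persistence intercept per ecoregion, in
    the order of ``ecoregion_names``.  The back-transformed ``invlogit(alpha_r)``
    is the mean annual persistence of an average-zero-covariate population in
    ecoregion r; ``invlogit(gamma0)`` is the detection probability at the
    reference year with zero scaled effort.
    """

    alpha: np.ndarray
    beta_hs: float
    beta_rain: float
    beta_imp: float
    gamma0: float
    beta_trend: float
    beta_effort: float
    ecoregion_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if not self.ecoregion_names:
            self.ecoregion_names = tuple(f"eco{i}" for i in range(len(self.alpha)))

    @property
    def n_ecoregions(self) -> int:
        return len(self.alpha)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.alpha, [self.beta_hs, self.beta_rain, self.beta_imp, self.gamma0, self.beta_trend, self.beta_effort]]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, ecoregion_names: tuple[str, ...]) -> "Params":
        R = len(ecoregion_names)
        vec = np.asarray(vec, dtype=float)
        return cls(vec[:R], *vec[R : R + 6], ecoregion_names=ecoregion_names)

    @staticmethod
    def names(ecoregion_names: tuple[str, ...]) -> list[str]:
        return [f"alpha[{n}]" for n in ecoregion_names] + [
            "beta_hs", "beta_rain", "beta_imp", "gamma0", "beta_trend", "beta_effort",
        ]


@dataclass
class ModelData:
    """Aligned arrays the sampler consumes.

    ``L`` is the 1-based index of each population's last detection year,
    floored at 1 (never-detected populations contribute a year-one
    non-detection).  ``code[i, t]`` indexes the distinct (year, effort) pairs
    whose logistic detection values are tabulated once per proposal.
    """

    y: np.ndarray  # (N, T) int8
    e: np.ndarray  # (N, T) float, scaled effort
    L: np.ndarray  # (N,) int64, in [1, T]
    eco: np.ndarray  # (N,) int64 ecoregion index
    hwv: np.ndarray  # (N, 3) covariates
    years: np.ndarray  # (T,)
    t_ref: float
    ecoregion_names: tuple[str, ...]
    code: np.ndarray = field(init=False)
    code_dt: np.ndarray = field(init=False)
    code_e: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.ascontiguousarray(self.y, dtype=np.int8)
        self.e = np.ascontiguousarray(self.e, dtype=float)
        self.L = np.asarray(self.L, dtype=np.int64)
        self.eco = np.asarray(self.eco, dtype=np.int64)
        self.hwv = np.ascontiguousarray(self.hwv, dtype=float)
        N, T = self.y.shape
        if np.any((self.L < 1) | (self.L > T)):
            raise ValueError("last-detection index must lie in [1, T]")
        dt = (self.years - self.t_ref).astype(float)
        pairs = np.column_stack([np.tile(dt, N), self.e.ravel()])
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        self.code = np.ascontiguousarray(inv.reshape(N, T), dtype=np.int64)
        self.code_dt = np.ascontiguousarray(uniq[:, 0])
        self.code_e = np.ascontiguousarray(uniq[:, 1])

    @property
    def n_populations(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.y.shape[1]

    @classmethod
    def from_matrices(
        cls,
        det: DetectionMatrix,
        eff: EffortMatrix,
        ecoregion_labels,
        hwv: np.ndarray,
        t_ref: float | None = None,
    ) -> "ModelData":
        if det.y.shape != eff.e.shape or list(det.pop_ids) != list(eff.pop_ids):
            raise ValueError("detection and effort matrices are not aligned")
        names = tuple(dict.fromkeys(ecoregion_labels))
        idx = {n: i for i, n in enumerate(names)}
        eco = np.array([idx[l] for l in ecoregion_labels], dtype=np.int64)
        L = np.maximum(det.last_index(), 1)
        t_ref = float(t_ref if t_ref is not None else (det.years[0] + det.years[-1]) // 2)
        return cls(det.y, eff.e, L, eco, np.asarray(hwv, dtype=float), det.years, t_ref, names)

    def phi(self, params: Params) -> np.ndarray:
        """Annual persistence probability per population."""
        eta = (
            params.alpha[self.eco]
            + params.beta_hs * self.hwv[:, 0]
            + params.beta_rain * self.hwv[:, 1]
            + params.beta_imp * self.hwv[:, 2]
        )
        return invlogit(eta)


# ----------------------------------------------------------------- kernels

@njit(cache=True)
def _detection_tables(gamma0, beta_trend, beta_effort, code_dt, code_e, lp, l1p, omp):
    """Fill log p, log(1-p), and 1-p for every distinct (year, effort) cell."""
    for k in range(code_dt.size):
        eta = gamma0 + beta_trend * code_dt[k] + beta_effort * code_e[k]
        if eta >= 0.0:
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            ex = np.exp(eta)
            p = ex / (1.0 + ex)
        lp[k] = np.log(p) if p > 0.0 else -1e300
        l1p[k] = np.log1p(-p) if p < 1.0 else -1e300
        omp[k] = 1.0 - p


@njit(cache=True)
def _pop_loglik(idx, phi, y, L, code, lp, l1p, omp, out_ll, out_persist):
    """Marginal log-likelihood and final-year persistence for populations in idx."""
    T = y.shape[1]
    for kk in range(idx.size):
        i = idx[kk]
        Li = L[i]
        Cl = 0.0
        for t in range(Li):
            c = code[i, t]
            Cl += lp[c] if y[i, t] == 1 else l1p[c]
        ph = phi[i]
        pw = ph ** (Li - 1)
        acc = 0.0
        q = 1.0
        last = 0.0
        for tau in range(Li + 1, T + 2):
            if tau <= T:
                acc += pw * (1.0 - ph) * q
                q *= omp[code[i, tau - 1]]
                pw *= ph
            else:
                last = pw * q
                acc += last
        if acc > 0.0:
            out_ll[i] = Cl + np.log(acc)
            out_persist[i] = last / acc
        else:
            out_ll[i] = -1e300
            out_persist[i] = 0.0


def _eval_all(params: Params, data: ModelData) -> tuple[np.ndarray, np.ndarray]:
    """Per-population log-likelihood and persistence-given-params."""
    K = data.code_dt.size
    lp = np.empty(K)
    l1p = np.empty(K)
    omp = np.empty(K)
    _detection_tables(params.gamma0, params.beta_trend, params.beta_effort, data.code_dt, data.code_e, lp, l1p, omp)
    phi = data.phi(params)
    N = data.n_populations
    ll = np.empty(N)
    persist = np.empty(N)
    _pop_loglik(np.arange(N, dtype=np.int64), phi, data.y, data.L, data.code, lp, l1p, omp, ll, persist)
    return ll, persist


def population_loglik(y_i, e_i, L_i, params: Params, years, eco_i: int = 0, hwv_i=(0.0, 0.0, 0.0), t_ref=None) -> float:
    """Marginal log-likelihood of one population's detection history.

    Convenience single-population wrapper around the vectorized kernel; the
    model-fitting path uses :class:`ModelData` directly.
    """
    data = ModelData(
        np.asarray(y_i, dtype=np.int8)[None, :],
        np.asarray(e_i, dtype=float)[None, :],
        np.array([max(int(L_i), 1)]),
        np.array([eco_i]),
        np.asarray(hwv_i, dtype=float)[None, :],
        np.asarray(years),
        float(t_ref if t_ref is not None else years[0]),
        params.ecoregion_names,
    )
    ll, _ = _eval_all(params, data)
    return float(ll[0])


def persistence_posterior_given_params(y_i, e_i, L_i, params: Params, years, eco_i: int = 0, hwv_i=(0.0, 0.0, 0.0), t_ref=None) -> float:
    """P(alive in the final year | history, parameters) for one population."""
    data = ModelData(
        np.asarray(y_i, dtype=np.int8)[None, :],
        np.asarray(e_i, dtype=float)[None, :],
        np.array([max(int(L_i), 1)]),
        np.array([eco_i]),
        np.asarray(hwv_i, dtype=float)[None, :],
        np.asarray(years),
        float(t_ref if t_ref is not None else years[0]),
        params.ecoregion_names,
    )
    _, persist = _eval_all(params, data)
    return float(persist[0])


def total_loglik(params: Params, data: ModelData) -> float:
    ll, _ = _eval_all(params, data)
    return float(ll.sum())


def annual_persistence(params: Params, data: ModelData) -> np.ndarray:
    """phi_i for every population (public name for the persistence predictor)."""
    return data.phi(params)


def detection_prob(params: Params, t, e, t_ref: float) -> np.ndarray:
    """p = logit^-1(gamma0 + b_trend (t - t_ref) + b_effort e)."""
    t = np.asarray(t, dtype=float)
    return invlogit(params.gamma0 + params.beta_trend * (t - t_ref) + params.beta_effort * np.asarray(e, dtype=float))
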