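"""Random-coefficient (mixed) logit estimated by simulated maximum likelihood.

Model.  Patient i derives utility from surgeon-hospital alternative (j, k)

    U_ijkt = Q_ijkt' beta_i + X_ijk' gamma + FE_k + eps_ijkt,

where the coefficients on the quality-information indicators and distance are
random across patients, beta_i ~ N(mu, diag(sigma^2)), the hospital-attribute
coefficients gamma, surgeon fixed effects FE and any attribute-by-year-trend
interactions are fixed, and eps is i.i.d. type-1 extreme value.  Conditional
on beta_i the choice probability is the multinomial logit (softmax) over the
patient's choice set; the unconditional probability integrates the softmax
over the normal mixing density.  The integral is approximated by averaging
over R draws per patient (Halton by default), and the resulting simulated
log-likelihood is maximized by quasi-Newton (BFGS) with an analytic score.

Identification notes.  The likelihood depends on sigma only through sigma*z,
so the sign of each sigma is unidentified; estimates are reported as |sigma|.
Standard errors come from the inverse of a finite-difference Hessian of the
analytic gradient.

The module also provides two deliberately independent oracles: an exact
conditional logit (``fit_conditional_logit``, also the warm start) and a
tensor-product Gauss-Hermite quadrature of the same mixture integral
(``gh_loglik``) for problems with at most two random attributes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import ndtri, softmax as _sp_softmax

from .choice_sets import HOSPITAL_ATTRS, RANDOM_ATTRS
from .quarters import year_trend

logger = logging.getLogger(__name__)

_HALTON_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)
_HALTON_BURN = 100
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ModelSpec:
    """What enters the utility, and how.

    ``random_attrs`` get N(mu, sigma^2) coefficients; ``fixed_attrs`` get
    nonrandom coefficients; ``fe_key`` names the column whose levels receive
    alternative-specific constants (one reference level pinned to 0);
    ``interactions`` lists attributes interacted with a linear year trend
    (fixed coefficients, trend = floor((quarter - trend_origin)/4)).
    """

    random_attrs: tuple[str, ...] = RANDOM_ATTRS
    fixed_attrs: tuple[str, ...] = HOSPITAL_ATTRS
    fe_key: str | None = "surgeon_id"
    reference: str | None = None
    interactions: tuple[str, ...] = ()
    trend_origin: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.random_attrs) & set(self.fixed_attrs)
        if overlap:
            raise ValueError(f"attributes in both blocks: {sorted(overlap)}")


class EstimationData:
    """Long-format dataset compiled to the arrays the likelihood needs.

    Rows are sorted by patient; ``starts`` delimits each patient's block for
    segmented reductions, ``chosen_rows`` indexes the realized alternative.
    """

    def __init__(self, df: pd.DataFrame, spec: ModelSpec | None = None):
        spec = spec or ModelSpec()
        need = {"patient_id", "chosen", *spec.random_attrs, *spec.fixed_attrs}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        df = df.sort_values("patient_id", kind="stable").reset_index(drop=True)
        per = df.groupby("patient_id", sort=True)["chosen"].sum()
        if (per != 1).any():
            raise ValueError("each patient must have exactly one chosen alternative")

        self.spec = spec
        codes, uniques = pd.factorize(df["patient_id"], sort=True)
        self.patient_ids = np.asarray(uniques)
        self.rep = codes.astype(np.int64)
        self.n_patients = len(uniques)
        self.n_rows = len(df)
        sizes = np.bincount(codes, minlength=self.n_patients)
        self.sizes = sizes
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
        self.chosen_rows = np.flatnonzero(df["chosen"].to_numpy() == 1)

        self.X_rand = np.ascontiguousarray(df[list(spec.random_attrs)].to_numpy(float))
        fixed_cols: list[np.ndarray] = []
        fixed_names: list[str] = []
        for a in spec.fixed_attrs:
            fixed_cols.append(df[a].to_numpy(float))
            fixed_names.append(a)
        if spec.interactions:
            if "quarter" not in df.columns:
                raise ValueError("interactions require a quarter column")
            trend = year_trend(df["quarter"].to_numpy(np.int64), spec.trend_origin).astype(float)
            for a in spec.interactions:
                fixed_cols.append(df[a].to_numpy(float) * trend)
                fixed_names.append(f"ix:{a}")
        if spec.fe_key is not None:
            levels = sorted(df[spec.fe_key].unique())
            ref = spec.reference if spec.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {spec.fe_key}")
            for lev in levels:
                if lev == ref:
                    continue
                fixed_cols.append((df[spec.fe_key] == lev).to_numpy(float))
                fixed_names.append(f"fe:{lev}")
            self.fe_reference = ref
        else:
            self.fe_reference = None
        self.X_fixed = (
            np.ascontiguousarray(np.column_stack(fixed_cols))
            if fixed_cols
            else np.zeros((self.n_rows, 0))
        )
        self.fixed_names = fixed_names
        self.rand_names = list(spec.random_attrs)
        self.param_names = (
            [f"mu:{a}" for a in spec.random_attrs]
            + [f"sd:{a}" for a in spec.random_attrs]
            + fixed_names
        )
        if not np.isfinite(self.X_rand).all() or not np.isfinite(self.X_fixed).all():
            raise ValueError("non-finite covariates")
        # quarter of each patient (used by post-estimation counterfactuals)
        if "quarter" in df.columns:
            self.patient_quarter = df["quarter"].to_numpy(np.int64)[self.chosen_rows]
        else:
            self.patient_quarter = np.zeros(self.n_patients, dtype=np.int64)
        self.frame = df

    @property
    def n_rand(self) -> int:
        return len(self.rand_names)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def n_params(self) -> int:
        return 2 * self.n_rand + self.n_fixed

    def pack(
        self,
        mu: Mapping[str, float] | None = None,
        sigma: Mapping[str, float] | None = None,
        fixed: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """Assemble a parameter vector in the canonical [mu, sigma, fixed] order."""
        theta = np.zeros(self.n_params)
        for i, a in enumerate(self.rand_names):
            theta[i] = (mu or {}).get(a, 0.0)
            theta[self.n_rand + i] = (sigma or {}).get(a, 0.0)
        for j, nm in enumerate(self.fixed_names):
            theta[2 * self.n_rand + j] = (fixed or {}).get(nm, 0.0)
        return theta


@dataclass
class DrawSet:
    """Standard-normal draws for the mixture integral, one block per patient.

    Halton draws use distinct primes per random attribute with a burn-in and
    are deterministic (the seed is kept only for API symmetry); pseudo draws
    come from a seeded PCG64 generator.
    """

    method: str
    n_draws: int
    seed: int
    z: np.ndarray  # (n_patients, n_draws, n_attrs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.z.shape


def _radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    idx = indices.astype(np.int64).copy()
    out = np.zeros(len(idx))
    f = 1.0 / base
    while idx.any():
        out += f * (idx % base)
        idx //= base
        f /= base
    return out


def make_draws(
    n_patients: int,
    n_attrs: int,
    n_draws: int,
    method: str = "halton",
    seed: int = 0,
) -> DrawSet:
    if n_attrs > len(_HALTON_PRIMES):
        raise ValueError("too many random attributes for the configured primes")
    if method == "pseudo":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_patients, n_draws, n_attrs))
    elif method == "halton":
        total = n_patients * n_draws
        idx = np.arange(_HALTON_BURN, _HALTON_BURN + total)
        u = np.column_stack(
            [_radical_inverse(idx, p) for p in _HALTON_PRIMES[:n_attrs]]
        )
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        z = ndtri(u).reshape(n_patients, n_draws, n_attrs)
    else:
        raise ValueError(f"unknown draw method {method!r}")
    return DrawSet(method=method, n_draws=n_draws, seed=seed, z=z)


# ---------------------------------------------------------------------------
# Likelihood

def conditional_choice_prob(utilities: Sequence[float]) -> np.ndarray:
    """Multinomial-logit probabilities over one choice set (stabilized softmax)."""
    u = np.asarray(utilities, dtype=float)
    if u.size == 0:
        raise ValueError("empty choice set")
    if not np.isfinite(u).all():
        raise ValueError("utilities must be finite")
    e = np.exp(u - u.max())
    return e / e.sum()


class _Workspace:
    """Draw-dependent precomputations shared across likelihood evaluations:
    XZ[k, row*R + r] = x_rand[row, k] * z[patient(row), r, k], stored flat so
    that building utilities is a single matrix product sigma @ XZ."""

    def __init__(self, data: EstimationData, draws: DrawSet):
        if draws.z.shape[0] != data.n_patients or draws.z.shape[2] != data.n_rand:
            raise ValueError("draw set does not match the data's patients/attributes")
        self.data = data
        self.draws = draws
        n, R, K = data.n_rows, draws.n_draws, data.n_rand
        XZ = np.empty((K, n * R))
        for k in range(K):
            XZ[k] = (data.X_rand[:, k, None] * draws.z[data.rep, :, k]).ravel()
        self.XZ = XZ


def _sll_core(theta: np.ndarray, ws: _Workspace, want_grad: bool):
    data, draws = ws.data, ws.draws
    K, F, R = data.n_rand, data.n_fixed, draws.n_draws
    mu, sg, gam = theta[:K], theta[K : 2 * K], theta[2 * K :]
    base = data.X_rand @ mu
    if F:
        base = base + data.X_fixed @ gam

    U = (sg @ ws.XZ).reshape(data.n_rows, R)
    U += base[:, None]
    m = np.maximum.reduceat(U, data.starts, axis=0)
    np.subtract(U, m[data.rep], out=U)
    np.exp(U, out=U)  # U now holds exp(u - m)
    denom = np.add.reduceat(U, data.starts, axis=0)
    Pch = U[data.chosen_rows] / denom  # (P, R)
    S = Pch.mean(axis=1)
    floored = S < _PROB_FLOOR
    if floored.any():
        logger.warning("probability underflow floored for %d patients", int(floored.sum()))
    Sf = np.maximum(S, _PROB_FLOOR)
    ll = float(np.log(Sf).sum())
    if not want_grad:
        return ll, None

    w = Pch / (R * Sf[:, None])
    w[floored] = 0.0
    wd = w / denom
    W = U
    W *= wd[data.rep]  # reuse the buffer: W[row, r] = prob * w
    rowm = -W.sum(axis=1)
    wsum = w.sum(axis=1)
    rowm[data.chosen_rows] += wsum
    g = np.empty(data.n_params)
    g[:K] = data.X_rand.T @ rowm
    if F:
        g[2 * K :] = data.X_fixed.T @ rowm
    term2 = ws.XZ @ W.ravel()  # (K,)
    term1 = np.array(
        [
            float((w * draws.z[:, :, k]).sum(axis=1) @ data.X_rand[data.chosen_rows, k])
            for k in range(K)
        ]
    )
    g[K : 2 * K] = term1 - term2
    return ll, g


def _sll_scores(theta: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Per-patient score vectors of the simulated log-likelihood (P x K).

    Used for the BHHH (outer-product-of-gradients) information estimate:
    at the MLE, sum_p s_p s_p' consistently estimates the information matrix
    at a fraction of the cost of a finite-difference Hessian.
    """
    data, draws = ws.data, ws.draws
    K, F, R = data.n_rand, data.n_fixed, draws.n_draws
    mu, sg, gam = theta[:K], theta[K : 2 * K], theta[2 * K :]
    base = data.X_rand @ mu
    if F:
        base = base + data.X_fixed @ gam
    U = (sg @ ws.XZ).reshape(data.n_rows, R)
    U += base[:, None]
    m = np.maximum.reduceat(U, data.starts, axis=0)
    np.subtract(U, m[data.rep], out=U)
    np.exp(U, out=U)
    denom = np.add.reduceat(U, data.starts, axis=0)
    Pch = U[data.chosen_rows] / denom
    S = Pch.mean(axis=1)
    Sf = np.maximum(S, _PROB_FLOOR)
    w = Pch / (R * Sf[:, None])
    w[S < _PROB_FLOOR] = 0.0
    W = U
    W *= (w / denom)[data.rep]
    rowm = -W.sum(axis=1)
    wsum = w.sum(axis=1)
    rowm[data.chosen_rows] += wsum

    scores = np.empty((data.n_patients, data.n_params))
    scores[:, :K] = np.add.reduceat(data.X_rand * rowm[:, None], data.starts, axis=0)
    if F:
        scores[:, 2 * K :] = np.add.reduceat(
            data.X_fixed * rowm[:, None], data.starts, axis=0
        )
    Wflat = W.ravel()
    for k in range(K):
        a = (w * draws.z[:, :, k]).sum(axis=1)
        row_term = (Wflat * ws.XZ[k]).reshape(data.n_rows, R).sum(axis=1)
        scores[:, K + k] = a * data.X_rand[data.chosen_rows, k] - np.add.reduceat(
            row_term, data.starts
        )
    return scores


def simulated_loglik(
    theta: np.ndarray,
    data: EstimationData,
    draws: DrawSet,
    return_grad: bool = False,
    _ws: _Workspace | None = None,
):
    """Simulated log-likelihood sum_i log((1/R) sum_r P_i(chosen | mu + sigma*z_ir)).

    ``theta`` is packed [mu..., sigma..., fixed...] following
    ``data.param_names``.  With all sigma = 0 this equals the plain
    conditional-logit log-likelihood for any draw set.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (data.n_params,):
        raise ValueError(f"expected {data.n_params} parameters, got {theta.shape}")
    ws = _ws if _ws is not None else _Workspace(data, draws)
    ll, g = _sll_core(theta, ws, return_grad)
    return (ll, g) if return_grad else ll


def gh_loglik(theta: np.ndarray, data: EstimationData, n_nodes: int = 64) -> float:
    """Gauss-Hermite quadrature of the mixture log-likelihood (oracle).

    Tensor-product rule, so only models with at most two random attributes
    are accepted.  Implemented independently of the simulation path: explicit
    per-patient loop with scipy's softmax.
    """
    K = data.n_rand
    if K > 2:
        raise ValueError("quadrature oracle supports at most 2 random attributes")
    theta = np.asarray(theta, dtype=float)
    mu, sg, gam = theta[:K], theta[K : 2 * K], theta[2 * K :]
    x, wq = np.polynomial.hermite.hermgauss(n_nodes)
    z1 = np.sqrt(2.0) * x
    w1 = wq / np.sqrt(np.pi)
    if K == 1:
        nodes = z1[:, None]
        weights = w1
    else:
        za, zb = np.meshgrid(z1, z1, indexing="ij")
        nodes = np.column_stack([za.ravel(), zb.ravel()])
        weights = np.outer(w1, w1).ravel()
    betas = mu[None, :] + sg[None, :] * nodes  # (n_nodes_total, K)
    fixed_part = data.X_fixed @ gam if data.n_fixed else np.zeros(data.n_rows)
    ll = 0.0
    for p in range(data.n_patients):
        lo = data.starts[p]
        hi = lo + data.sizes[p]
        U = data.X_rand[lo:hi] @ betas.T + fixed_part[lo:hi, None]
        P = _sp_softmax(U, axis=0)
        chosen_local = data.chosen_rows[p] - lo
        ll += np.log(max(float(weights @ P[chosen_local]), _PROB_FLOOR))
    return float(ll)


# ---------------------------------------------------------------------------
# Results container

@dataclass
class FitResult:
    """Point estimates, standard errors and diagnostics of one fit.

    ``params``/``se`` are indexed by ``mu:<attr>``, ``sd:<attr>`` (reported
    as |sigma|) and the fixed-coefficient names (hospital attributes,
    ``ix:<attr>`` interactions, ``fe:<surgeon>`` fixed effects).
    """

    params: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    loglik: float
    converged: bool
    n_obs: int
    n_patients: int
    spec: ModelSpec
    options: dict = field(default_factory=dict)
    message: str = ""

    def mu(self, attr: str) -> float:
        return float(self.params[f"mu:{attr}"])

    def sd(self, attr: str) -> float:
        return float(self.params[f"sd:{attr}"])

    def fixed(self, name: str) -> float:
        return float(self.params[name])

    def summary_table(self) -> str:
        """Mean (SE) / SD (SE) table over the random attributes, mirroring the
        conventional presentation of mixed-logit estimates."""
        lines = [f"{'Variable':<22}{'Mean (SE)':>20}{'SD (SE)':>20}"]
        for a in self.spec.random_attrs:
            mean = f"{self.mu(a):.3f} ({self.se[f'mu:{a}']:.3f})"
            sd_key = f"sd:{a}"
            if sd_key in self.params.index:
                sd = f"{self.sd(a):.3f} ({self.se[sd_key]:.3f})"
            else:
                sd = "-"
            lines.append(f"{a:<22}{mean:>20}{sd:>20}")
        lines.append(f"log-likelihood: {self.loglik:.4f}   "
                     f"n_obs: {self.n_obs}   patients: {self.n_patients}   "
                     f"converged: {self.converged}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_patients": int(self.n_patients),
            "message": self.message,
            "options": self.options,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Conditional logit (exact MLE; warm start and degenerate-case oracle)

def _clogit_ll_grad_hess(beta, X, data: EstimationData, want_hess=True):
    eta = X @ beta
    m = np.maximum.reduceat(eta, data.starts)
    e = np.exp(eta - m[data.rep])
    denom = np.add.reduceat(e, data.starts)
    probs = e / denom[data.rep]
    ll = float(np.log(np.maximum(probs[data.chosen_rows], _PROB_FLOOR)).sum())
    resid = np.zeros(data.n_rows)
    resid[data.chosen_rows] = 1.0
    resid -= probs
    g = X.T @ resid
    if not want_hess:
        return ll, g, None
    PX = X * probs[:, None]
    xbar = np.add.reduceat(PX, data.starts, axis=0)  # (P, K)
    H = X.T @ PX - xbar.T @ xbar  # observed information (negative Hessian of ll)
    return ll, g, H


def fit_conditional_logit(
    data: EstimationData | pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FitResult:
    """Exact ML conditional logit with all coefficients fixed.

    Coefficient names reuse the ``mu:<attr>`` convention for the attributes
    the mixed model treats as random, so the result doubles as a warm start.
    Collinear covariates and perfectly separating covariates are rejected
    with the offending columns named.
    """
    if isinstance(data, pd.DataFrame):
        data = EstimationData(data, spec)
    X = np.hstack([data.X_rand, data.X_fixed])
    names = [f"mu:{a}" for a in data.rand_names] + data.fixed_names
    K = X.shape[1]

    # Identification: columns must vary within choice sets and be independent.
    means = np.add.reduceat(X, data.starts, axis=0) / data.sizes[:, None]
    Xc = X - means[data.rep]
    scale = np.sqrt((Xc**2).mean(axis=0))
    if (scale < 1e-12).any():
        bad = [names[j] for j in np.flatnonzero(scale < 1e-12)]
        raise ValueError(f"covariates constant within every choice set: {bad}")
    sv = scipy.linalg.svdvals(Xc / scale)
    if sv[-1] < 1e-8 * sv[0]:
        _, _, piv = scipy.linalg.qr(Xc / scale, pivoting=True, mode="economic")
        r = int((sv > 1e-8 * sv[0]).sum())
        bad = [names[j] for j in sorted(piv[r:])]
        raise ValueError(f"collinear covariates: {bad}")

    Xs = X / scale
    beta = np.zeros(K)
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, g, H = _clogit_ll_grad_hess(beta, Xs, data)
        try:
            step = scipy.linalg.solve(H + 1e-10 * np.eye(K), g, assume_a="pos")
        except scipy.linalg.LinAlgError:
            step = scipy.linalg.lstsq(H, g)[0]
        t = 1.0
        while t > 1e-8:
            ll_new = _clogit_ll_grad_hess(beta + t * step, Xs, data, want_hess=False)[0]
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        if np.abs(beta).max() > 50.0:
            j = int(np.abs(beta).argmax())
            raise ValueError(
                f"non-identified fit (possible perfect separation) on {names[j]!r}"
            )
        if abs(ll_new - ll_prev) < tol * (1.0 + abs(ll_new)) and np.abs(g).max() < 1e-5:
            ll_prev = ll_new
            break
        ll_prev = ll_new
    ll, g, H = _clogit_ll_grad_hess(beta, Xs, data)
    # A likelihood at (essentially) zero means some covariate predicts the
    # choice perfectly; the MLE does not exist.
    if ll > -1e-4 or np.abs(beta).max() > 30.0:
        j = int(np.abs(beta).argmax())
        raise ValueError(
            f"non-identified fit (possible perfect separation) on {names[j]!r}"
        )
    vcov_s = scipy.linalg.pinvh(H)
    beta_nat = beta / scale
    vcov = vcov_s / np.outer(scale, scale)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    converged = bool(np.abs(g).max() < 1e-4)
    return FitResult(
        params=pd.Series(beta_nat, index=names),
        se=pd.Series(se, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=ll,
        converged=converged,
        n_obs=data.n_rows,
        n_patients=data.n_patients,
        spec=data.spec,
        options={"model": "conditional_logit", "tol": tol},
    )


# ---------------------------------------------------------------------------
# Simulated maximum likelihood

def _numerical_hessian(grad_fn, theta, scheme="central", step=1e-4):
    n = len(theta)
    H = np.zeros((n, n))
    if scheme == "forward":
        g0 = grad_fn(theta)
        for j in range(n):
            h = step * (1.0 + abs(theta[j]))
            tp = theta.copy()
            tp[j] += h
            H[:, j] = (grad_fn(tp) - g0) / h
    elif scheme == "central":
        for j in range(n):
            h = step * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    else:
        raise ValueError(f"unknown Hessian scheme {scheme!r}")
    return 0.5 * (H + H.T)


def fit(
    data: EstimationData | pd.DataFrame,
    spec: ModelSpec | None = None,
    draws: int = 1000,
    method: str = "halton",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    start: np.ndarray | None = None,
    start_sigma: float = 0.1,
    compute_se: bool = True,
    hessian_scheme: str = "central",
) -> FitResult:
    """Maximize the simulated log-likelihood.

    ``tol`` is a per-patient gradient tolerance (the BFGS gtol is
    tol * n_patients), so the stopping rule scales sensibly with sample size.
    The warm start is the exact conditional logit; sigma parameters start at
    ``start_sigma`` and are unconstrained during optimization, with |sigma|
    reported.  Non-convergence returns a result flagged converged=False
    rather than raising.

    ``hessian_scheme`` selects the covariance estimator: 'central'/'forward'
    finite differences of the analytic gradient (observed information), or
    'bhhh' for the outer product of per-patient scores.
    """
    if isinstance(data, pd.DataFrame):
        data = EstimationData(data, spec)
    K, F = data.n_rand, data.n_fixed

    if start is None:
        warm = fit_conditional_logit(data)
        theta0 = np.zeros(data.n_params)
        theta0[:K] = warm.params.iloc[:K].to_numpy()
        theta0[K : 2 * K] = start_sigma
        if F:
            theta0[2 * K :] = warm.params.iloc[K:].to_numpy()
    else:
        theta0 = np.asarray(start, dtype=float)
        if theta0.shape != (data.n_params,):
            raise ValueError("start vector has the wrong length")

    ds = make_draws(data.n_patients, K, draws, method=method, seed=seed)
    ws = _Workspace(data, ds)

    # Precondition: scale each parameter by the RMS of its design column so
    # BFGS sees O(1) curvature in every direction.
    col_rms = np.sqrt((data.X_rand**2).mean(axis=0))
    col_rms = np.maximum(col_rms, 1e-8)
    if F:
        fix_rms = np.maximum(np.sqrt((data.X_fixed**2).mean(axis=0)), 1e-8)
        c = np.concatenate([1.0 / col_rms, 1.0 / col_rms, 1.0 / fix_rms])
    else:
        c = np.concatenate([1.0 / col_rms, 1.0 / col_rms])

    def negll(y):
        ll, g = _sll_core(y * c, ws, want_grad=True)
        return -ll, -(g * c)

    res = scipy.optimize.minimize(
        negll,
        theta0 / c,
        jac=True,
        method="BFGS",
        options={"gtol": tol * data.n_patients, "maxiter": max_iter},
    )
    theta_hat = res.x * c
    ll_hat = -float(res.fun)
    converged = bool(res.success) or np.abs(res.jac / c).max() < 10 * tol * data.n_patients

    names = data.param_names
    if compute_se:
        if hessian_scheme == "bhhh":
            s = _sll_scores(theta_hat, ws)
            H = s.T @ s
        else:
            def grad_nat(th):
                return _sll_core(th, ws, want_grad=True)[1]

            H = -_numerical_hessian(grad_nat, theta_hat, scheme=hessian_scheme)
        try:
            vcov_m = scipy.linalg.inv(H)
        except scipy.linalg.LinAlgError:
            vcov_m = scipy.linalg.pinvh(H)
            logger.warning("singular Hessian; using pseudo-inverse covariance")
        # Report |sigma|: flip the sign of negative sigma rows in both the
        # estimate and the covariance (delta method with d|s|/ds = sign(s)).
        signs = np.ones(data.n_params)
        sg = theta_hat[K : 2 * K]
        signs[K : 2 * K] = np.where(sg < 0, -1.0, 1.0)
        theta_rep = theta_hat * signs
        vcov_m = vcov_m * np.outer(signs, signs)
        se = np.sqrt(np.clip(np.diag(vcov_m), 0.0, None))
        vcov = pd.DataFrame(vcov_m, index=names, columns=names)
    else:
        theta_rep = theta_hat.copy()
        theta_rep[K : 2 * K] = np.abs(theta_rep[K : 2 * K])
        se = np.full(data.n_params, np.nan)
        vcov = pd.DataFrame(np.full((data.n_params,) * 2, np.nan), index=names, columns=names)

    return FitResult(
        params=pd.Series(theta_rep, index=names),
        se=pd.Series(se, index=names),
        vcov=vcov,
        loglik=ll_hat,
        converged=converged,
        n_obs=data.n_rows,
        n_patients=data.n_patients,
        spec=data.spec,
        options={
            "draws": draws,
            "method": method,
            "seed": seed,
            "tol": tol,
            "max_iter": max_iter,
        },
        message=str(res.message),
    )
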