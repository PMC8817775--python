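"""Conditional-logit and mixed-logit (random-parameters logit) estimators.

The mixed logit lets each respondent carry their own preference weights,
beta_i = mu + sigma * z_i with independent normal heterogeneity per
dummy-coded attribute level; the alternative-specific constant is fixed.
Estimation maximizes the simulated log-likelihood

    SLL(mu, sigma) = sum_n ln[ (1/R) sum_r prod_t P_nt(chosen | beta_nr) ]

over quasi-random (Halton) normal draws z_nr, with the opt-out utility
normalized to zero.  The conditional logit is the sigma = 0 special case and
supplies starting values.  Both estimators follow the scikit-learn protocol
(``fit`` on a long-format dataset, fitted attributes with trailing
underscores) and compose with sklearn tooling via ``get_params``/``set_params``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from .dataset import ChoiceDataset
from .design import ASC_COLUMN
from .halton import HaltonConfig, normal_draws
from .scheme import study_scheme

__all__ = [
    "ModelSpec",
    "PanelData",
    "MixlResult",
    "simulated_loglik",
    "conditional_loglik",
    "ConditionalLogit",
    "MixedLogit",
    "fit_conditional_logit",
    "fit_mixl",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class ModelSpec:
    """Which columns enter as fixed vs normally-mixed random coefficients."""

    fixed: tuple[str, ...] = (ASC_COLUMN,)
    random: tuple[str, ...] = ("c_chw", "c_expert", "l_home", "s_phcall", "s_tvouch")

    def __post_init__(self) -> None:
        overlap = set(self.fixed) & set(self.random)
        if overlap:
            raise ValueError(f"columns assigned to both fixed and random: {sorted(overlap)}")


class EstimationError(RuntimeError):
    pass


@dataclass
class PanelData:
    """Rectangular long-format data as arrays: X (N, T, A, P), chosen (N, T)."""

    X: np.ndarray
    chosen: np.ndarray
    param_names: list[str]
    respondent_ids: np.ndarray

    @property
    def n_respondents(self) -> int:
        return self.X.shape[0]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0] * self.X.shape[1] * self.X.shape[2]

    @classmethod
    def from_dataset(
        cls, dataset: ChoiceDataset, columns: Sequence[str]
    ) -> "PanelData":
        df = dataset.df.sort_values(
            ["respondent_id", "task_id", "alt_id"], kind="stable"
        )
        rids = df["respondent_id"].unique()
        counts = df.groupby("respondent_id", sort=False).size()
        if counts.nunique() != 1:
            raise ValueError("respondents have unequal row counts (non-rectangular panel)")
        alt_counts = df.groupby(["respondent_id", "task_id"], sort=False).size()
        if alt_counts.nunique() != 1:
            raise ValueError("tasks have unequal alternative counts (non-rectangular panel)")
        a = int(alt_counts.iloc[0])
        t = int(counts.iloc[0]) // a
        n = len(rids)
        X = df[list(columns)].to_numpy(dtype=float).reshape(n, t, a, len(columns))
        chosen = df["chosen"].to_numpy(dtype=int).reshape(n, t, a).argmax(axis=2)
        return cls(X=X, chosen=chosen, param_names=list(columns), respondent_ids=rids)

    def degenerate_columns(self) -> list[str]:
        """Columns with no variation across alternatives within any task."""
        spread = self.X.max(axis=2) - self.X.min(axis=2)  # (N, T, P)
        dead = spread.reshape(-1, self.X.shape[3]).max(axis=0) == 0
        return [c for c, d in zip(self.param_names, dead) if d]


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _chosen_x(panel: PanelData) -> np.ndarray:
    """Sum over tasks of the chosen alternative's attributes, (N, P)."""
    idx = panel.chosen[:, :, None, None]
    xc = np.take_along_axis(panel.X, idx, axis=2)[:, :, 0, :]
    return xc.sum(axis=1)


def conditional_loglik(
    beta: np.ndarray, panel: PanelData, order: int = 2
) -> tuple:
    """Conditional-logit log-likelihood, gradient and (optionally) Hessian."""
    beta = np.asarray(beta, float)
    V = panel.X @ beta  # (N, T, A)
    m = V.max(axis=2, keepdims=True)
    e = np.exp(V - m)
    denom = e.sum(axis=2)
    lse = np.log(denom) + m[:, :, 0]
    vch = np.take_along_axis(V, panel.chosen[:, :, None], axis=2)[:, :, 0]
    ll = float((vch - lse).sum())
    if order == 0:
        return (ll,)
    p = e / denom[:, :, None]  # (N, T, A)
    xbar = np.einsum("nta,ntap->ntp", p, panel.X)
    grad = _chosen_x(panel) .sum(axis=0) - xbar.sum(axis=(0, 1))
    if order == 1:
        return ll, grad
    xc = panel.X - xbar[:, :, None, :]
    hess = -np.einsum("nta,ntap,ntaq->pq", p, xc, xc)
    return ll, grad, hess


def _sll_core(
    mu: np.ndarray,
    sigma: np.ndarray,
    panel: PanelData,
    z: np.ndarray,
    random_idx: np.ndarray,
    with_grad: bool = True,
):
    """Simulated log-likelihood (and score) with log-sum-exp stabilization.

    mu has one entry per panel column; sigma one per random column (aligned
    with random_idx into the panel columns); z has shape (N, R, n_random).
    Returns (sll, grad) with grad ordered [d/dmu, d/dsigma].
    """
    n, t, a, p_dim = panel.X.shape
    r = z.shape[1]
    beta = np.broadcast_to(mu, (n, r, p_dim)).copy()
    beta[:, :, random_idx] += sigma * z
    U = np.einsum("ntap,nrp->nrta", panel.X, beta, optimize=True)
    m = U.max(axis=3, keepdims=True)
    eU = np.exp(U - m)
    denom = eU.sum(axis=3)
    lse = np.log(denom) + m[:, :, :, 0]
    vch = np.take_along_axis(
        U, panel.chosen[:, None, :, None], axis=3
    )[:, :, :, 0]
    lnL = (vch - lse).sum(axis=2)  # (N, R)
    amax = lnL.max(axis=1, keepdims=True)
    wu = np.exp(lnL - amax)
    s = wu.sum(axis=1)
    sll = float((np.log(s) + amax[:, 0] - np.log(r)).sum())
    if not with_grad:
        return sll, None
    prob = eU / denom[:, :, :, None]  # (N, R, T, A)
    xbar = np.einsum("nrta,ntap->nrp", prob, panel.X, optimize=True)
    score = _chosen_x(panel)[:, None, :] - xbar  # (N, R, P)
    w = wu / s[:, None]
    g_mu = np.einsum("nr,nrp->p", w, score)
    g_sigma = np.einsum("nr,nrk,nrk->k", w, score[:, :, random_idx], z)
    return sll, np.concatenate([g_mu, g_sigma])


def simulated_loglik(
    mu: np.ndarray,
    sigma: np.ndarray,
    data: "ChoiceDataset | PanelData",
    draws: np.ndarray,
    columns: Sequence[str] | None = None,
) -> float:
    """Panel mixed-logit simulated log-likelihood at (mu, sigma).

    ``mu`` is aligned with ``columns`` (default: asc + the scheme's indicator
    columns); ``sigma`` may be full-length (entries for fixed columns must be
    0) or match the number of random columns implied by ``draws``'s last
    dimension, which are taken to be the trailing columns.
    """
    if isinstance(data, PanelData):
        panel = data
    else:
        columns = list(columns or [ASC_COLUMN] + data.scheme.columns)
        panel = PanelData.from_dataset(data, columns)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if not (np.isfinite(mu).all() and np.isfinite(sigma).all()):
        raise ValueError("non-finite parameters")
    n_random = draws.shape[2]
    p_dim = panel.X.shape[3]
    if sigma.shape == (p_dim,):
        if np.any(sigma[: p_dim - n_random] != 0):
            raise ValueError("sigma entries for fixed coefficients must be 0")
        sigma = sigma[p_dim - n_random :]
    elif sigma.shape != (n_random,):
        raise ValueError(f"sigma must have length {n_random} or {p_dim}")
    random_idx = np.arange(p_dim - n_random, p_dim)
    sll, _ = _sll_core(mu, sigma, panel, draws, random_idx, with_grad=False)
    return sll


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class MixlResult:
    """Estimates in the layout of a mixed-logit results table.

    ``table`` has one row per parameter: name, kind ("mean" or "sd"),
    estimate, se, z, p, ci_low, ci_high.  SD rows are reported in absolute
    value and tested against zero (no heterogeneity).
    """

    table: pd.DataFrame
    loglik: float
    n_obs: int
    converged: bool
    n_draws: int | None = None
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "parameters": self.table.to_dict(orient="records"),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_draws": self.n_draws,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixlResult":
        return cls(
            table=pd.DataFrame(d["parameters"]),
            loglik=d["loglik"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            n_draws=d.get("n_draws"),
            message=d.get("message", ""),
        )

    def means(self) -> pd.Series:
        t = self.table[self.table["kind"] == "mean"]
        return pd.Series(t["estimate"].to_numpy(), index=t["name"].to_numpy())

    def sds(self) -> pd.Series:
        t = self.table[self.table["kind"] == "sd"]
        return pd.Series(t["estimate"].to_numpy(), index=t["name"].to_numpy())


def _param_rows(names, kinds, est, se) -> pd.DataFrame:
    se = np.asarray(se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2 * ndtr(-np.abs(z))
    return pd.DataFrame(
        {
            "name": names,
            "kind": kinds,
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "ci_low": est - _Z975 * se,
            "ci_high": est + _Z975 * se,
        }
    )


def _as_dataset(X) -> ChoiceDataset:
    if isinstance(X, ChoiceDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return ChoiceDataset.from_frame(X)
    raise TypeError("X must be a ChoiceDataset or a long-format DataFrame")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class ConditionalLogit(BaseEstimator):
    """Fixed-coefficient multinomial choice model (McFadden conditional logit).

    Newton–Raphson maximum likelihood with analytic gradient and Hessian;
    standard errors from the inverse observed information.  Serves both as a
    model in its own right and as the starting point of :class:`MixedLogit`.

    Parameters
    ----------
    columns : explicit model columns, default asc + the scheme's indicators.
    tol : sup-norm gradient tolerance (per respondent) for convergence.
    max_iter : Newton iteration budget.
    """

    def __init__(self, columns=None, tol=1e-8, max_iter=100):
        self.columns = columns
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        dataset = _as_dataset(X)
        columns = list(self.columns or [ASC_COLUMN] + dataset.scheme.columns)
        panel = PanelData.from_dataset(dataset, columns)
        dead = panel.degenerate_columns()
        if dead:
            warnings.warn(
                f"dropping columns constant within every task: {dead}", stacklevel=2
            )
            columns = [c for c in columns if c not in dead]
            panel = PanelData.from_dataset(dataset, columns)
        n = panel.n_respondents

        beta = np.zeros(len(columns))
        converged, message = False, ""
        ll = -np.inf
        for _ in range(self.max_iter):
            ll, grad, hess = conditional_loglik(beta, panel)
            if np.abs(grad).max() / n < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                message = "singular Hessian (separation or collinear columns)"
                break
            # halve until the likelihood does not decrease
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                if conditional_loglik(cand, panel, order=0)[0] >= ll - 1e-12:
                    break
                scale /= 2
            beta = beta + scale * step
        if converged and np.abs(beta).max() > 10:
            converged = False
            message = "diverging coefficients: an indicator may perfectly predict choice"
        if not converged and not message:
            message = "gradient tolerance not reached within iteration budget"

        ll, grad, hess = conditional_loglik(beta, panel)
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((len(beta),) * 2, np.nan)
            se = np.full(len(beta), np.nan)
            message = message or "singular Hessian: standard errors unavailable"

        self.panel_ = panel
        self.columns_ = columns
        self.coef_ = pd.Series(beta, index=columns)
        self.se_ = pd.Series(se, index=columns)
        self.cov_ = cov
        self.loglik_ = ll
        self.converged_ = converged
        self.n_obs_ = panel.n_obs
        self.result_ = MixlResult(
            table=_param_rows(columns, ["mean"] * len(columns), beta, se),
            loglik=ll,
            n_obs=panel.n_obs,
            converged=converged,
            n_draws=None,
            message=message,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Choice probabilities (N, T, A) at the fitted coefficients."""
        dataset = _as_dataset(X)
        panel = PanelData.from_dataset(dataset, self.columns_)
        V = panel.X @ self.coef_.to_numpy()
        e = np.exp(V - V.max(axis=2, keepdims=True))
        return e / e.sum(axis=2, keepdims=True)


class MixedLogit(BaseEstimator):
    """Random-parameters logit by maximum simulated likelihood.

    Normally-mixed coefficients for the attribute indicators and a fixed
    alternative-specific constant, integrated with per-respondent blocks of
    Halton normal draws.  The optimizer is L-BFGS-B on the per-respondent
    average simulated log-likelihood with the analytic score; standard
    errors come from the inverse numeric Hessian at the optimum.  SD
    estimates are reported in absolute value (the likelihood is symmetric
    in each sigma's sign).

    Parameters
    ----------
    spec : ModelSpec assigning columns to fixed/random (default: study layout).
    n_draws : Halton draws per respondent (study convention: 1000).
    burn_in : leading Halton elements discarded.
    start_sigma : starting value for every heterogeneity SD.
    gtol : sup-norm tolerance on the per-respondent average gradient.
    max_iter : optimizer iteration budget.
    compute_se : skip the numeric Hessian when False (e.g. in simulations).
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        n_draws: int = 1000,
        burn_in: int = 10,
        primes: tuple = None,
        start_sigma: float = 0.1,
        gtol: float = 1e-5,
        max_iter: int = 500,
        compute_se: bool = True,
    ):
        self.spec = spec
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.primes = primes
        self.start_sigma = start_sigma
        self.gtol = gtol
        self.max_iter = max_iter
        self.compute_se = compute_se

    def _halton_config(self) -> HaltonConfig:
        kw = {"n_draws": self.n_draws, "burn_in": self.burn_in}
        if self.primes is not None:
            kw["primes"] = tuple(self.primes)
        return HaltonConfig(**kw)

    def fit(self, X, y=None, draws: np.ndarray | None = None):
        """Fit on a long-format dataset.

        ``draws`` overrides the Halton normal draws with an explicit
        (N, R, n_random) array (used for diagnostics such as the
        zero-draw collapse onto the conditional logit).
        """
        dataset = _as_dataset(X)
        spec = self.spec or ModelSpec(
            fixed=(ASC_COLUMN,), random=tuple(dataset.scheme.columns)
        )
        columns = list(spec.fixed) + list(spec.random)
        missing = [c for c in columns if c not in dataset.df.columns]
        if missing:
            raise ValueError(f"dataset is missing model columns: {missing}")
        panel = PanelData.from_dataset(dataset, columns)
        dead = panel.degenerate_columns()
        if dead:
            warnings.warn(
                f"dropping columns constant within every task: {dead}", stacklevel=2
            )
            spec = ModelSpec(
                fixed=tuple(c for c in spec.fixed if c not in dead),
                random=tuple(c for c in spec.random if c not in dead),
            )
            columns = list(spec.fixed) + list(spec.random)
            panel = PanelData.from_dataset(dataset, columns)
        n, _, _, p_dim = panel.X.shape
        n_random = len(spec.random)
        random_idx = np.arange(p_dim - n_random, p_dim)

        if draws is None:
            z = normal_draws(self._halton_config(), n, n_random)
        else:
            z = np.asarray(draws, float)
            if z.shape[0] != n or z.shape[2] != n_random:
                raise ValueError(
                    f"draws must have shape (n_respondents={n}, R, {n_random})"
                )
        r = z.shape[1]

        start = ConditionalLogit(columns=columns).fit(dataset)
        theta0 = np.concatenate(
            [start.coef_.to_numpy(), np.full(n_random, self.start_sigma)]
        )

        def objective(theta):
            mu, sigma = theta[:p_dim], theta[p_dim:]
            sll, grad = _sll_core(mu, sigma, panel, z, random_idx)
            return -sll / n, -grad / n

        f0 = objective(theta0)[0]
        res = optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-11, "gtol": self.gtol},
        )
        theta = res.x
        gmax = float(np.abs(res.jac).max())
        converged = bool(res.success or gmax < 10 * self.gtol)
        message = "" if converged else f"optimizer: {res.message} (max |grad|/N = {gmax:.2e})"
        if res.fun > f0 + 1e-10:  # L-BFGS-B never worsens; belt and braces
            theta, message = theta0, message or "no improvement over starting values"
            converged = False

        mu, sigma_raw = theta[:p_dim], theta[p_dim:]
        sigma = np.abs(sigma_raw)
        sll = -objective(theta)[0] * n

        se = np.full(len(theta), np.nan)
        cov = np.full((len(theta),) * 2, np.nan)
        if self.compute_se:
            hess = self._numeric_hessian(objective, theta) * n
            try:
                cov = np.linalg.inv(hess)
                diag = np.diag(cov)
                if (diag <= 0).any():
                    raise np.linalg.LinAlgError("non-positive variance")
                se = np.sqrt(diag)
            except np.linalg.LinAlgError:
                message = (message + "; " if message else "") + (
                    "singular or indefinite Hessian: standard errors unavailable"
                )

        names = columns + [f"sd_{c}" for c in spec.random]
        kinds = ["mean"] * p_dim + ["sd"] * n_random
        estimates = np.concatenate([mu, sigma])
        self.spec_ = spec
        self.columns_ = columns
        self.mu_ = pd.Series(mu, index=columns)
        self.sigma_ = pd.Series(sigma, index=list(spec.random))
        self.se_mu_ = pd.Series(se[:p_dim], index=columns)
        self.se_sigma_ = pd.Series(se[p_dim:], index=list(spec.random))
        self.cov_ = cov
        self.loglik_ = sll
        self.start_loglik_ = -f0 * n
        self.cl_result_ = start.result_
        self.converged_ = converged
        self.n_obs_ = panel.n_obs
        self.n_draws_ = r
        self.result_ = MixlResult(
            table=_param_rows(names, kinds, estimates, se),
            loglik=sll,
            n_obs=panel.n_obs,
            converged=converged,
            n_draws=r,
            message=message,
        )
        return self

    @staticmethod
    def _numeric_hessian(objective, theta, h: float = 1e-4) -> np.ndarray:
        """Central differences of the analytic gradient of the average SLL."""
        k = len(theta)
        hess = np.zeros((k, k))
        for i in range(k):
            step = h * max(1.0, abs(theta[i]))
            e = np.zeros(k)
            e[i] = step
            gp = objective(theta + e)[1]
            gm = objective(theta - e)[1]
            hess[i] = (gp - gm) / (2 * step)
        return (hess + hess.T) / 2


def fit_conditional_logit(dataset, **kwargs) -> MixlResult:
    """Functional wrapper over :class:`ConditionalLogit`."""
    return ConditionalLogit(**kwargs).fit(dataset).result_


def fit_mixl(
    dataset,
    spec: ModelSpec | None = None,
    config: HaltonConfig | None = None,
    **kwargs,
) -> MixlResult:
    """Functional wrapper over :class:`MixedLogit`."""
    if config is not None:
        kwargs.setdefault("n_draws", config.n_draws)
        kwargs.setdefault("burn_in", config.burn_in)
        kwargs.setdefault("primes", config.primes)
    return MixedLogit(spec=spec, **kwargs).fit(dataset).result_
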