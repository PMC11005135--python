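"""Weighted logistic mixed models with random intercepts.

Fits each candidate specification by maximising a Laplace approximation
to the weighted marginal likelihood: for trial variance components the
fixed effects and random intercepts are jointly maximised by penalised
Newton iterations, and the log-determinant correction for the integrated
random effects is added.  Survey weights are treated as frequency
weights after rescaling to stratum sample size.

Cell-level predictions plug in posterior-mode (empirical-Bayes)
intercepts for observed groups; unobserved groups contribute zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import expit

from . import design
from .design import CELL_FACTORS, ModelSpec

__all__ = [
    "FittedModel",
    "rescale_weights",
    "fit",
    "predict_cells",
    "select_model",
]

logger = logging.getLogger(__name__)

_MU_EPS = 1e-10
_LOGVAR_FLOOR = -16.0  # exp(-16) ~ 1e-7: variance effectively at the zero boundary


def rescale_weights(records: pd.DataFrame) -> pd.DataFrame:
    """Rescale survey weights to sample size within each (domain, wave).

    Relative weights are preserved; within every stratum the rescaled
    weights sum to the stratum's respondent count.
    """
    if (records["weight"] <= 0).any():
        bad = records.index[records["weight"] <= 0][0]
        raise ValueError(f"nonpositive weight in record {bad}")
    out = records.copy()
    grp = out.groupby(["domain", "wave"])["weight"]
    out["weight"] = out["weight"] * grp.transform("size") / grp.transform("sum")
    return out


@dataclass
class FittedModel:
    """A fitted mixed model plus fit statistics."""

    spec: ModelSpec
    beta: pd.Series
    beta_se: pd.Series
    variance_components: dict[str, float]
    random_effects: dict[str, pd.Series]
    loglik: float
    aic: float
    bic: float
    converged: bool
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.id,
            "beta": self.beta.to_dict(),
            "beta_se": self.beta_se.to_dict(),
            "variance_components": self.variance_components,
            "random_effects": {
                term: {str(k): v for k, v in u.items()}
                for term, u in self.random_effects.items()
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _bernoulli_ll(y: np.ndarray, w: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


@dataclass
class _Prepared:
    """Arrays shared by repeated fits on resampled rows of one dataset."""

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    names: list[str]
    terms: list[tuple[str, np.ndarray, list]]  # (term, codes, labels)
    spec: ModelSpec


def prepare(records: pd.DataFrame, spec: ModelSpec) -> _Prepared:
    """Validate and assemble the arrays needed by the optimiser."""
    if records["domain"].nunique() < 2:
        raise ValueError("need >= 2 domains: domain variance is not identifiable")
    X, names, groups = design.design_matrix(records, spec)
    _check_rank(X, names)
    y = records["outcome"].to_numpy(dtype=float)
    if spec.use_weights:
        w = records["weight"].to_numpy(dtype=float)
        if (w <= 0).any():
            bad = records.index[records["weight"] <= 0][0]
            raise ValueError(f"nonpositive weight in record {bad}")
    else:
        w = np.ones(len(records))
    terms = [(t, groups[t][0], groups[t][1]) for t in spec.random_intercepts]
    return _Prepared(X=X, y=y, w=w, names=names, terms=terms, spec=spec)


def _pirls(
    M: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    pen: np.ndarray,
    z0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Penalised Newton iterations for the joint (beta, u) mode.

    ``pen`` is the diagonal of the penalty matrix (0 for fixed-effect
    positions, 1/sigma^2 for random intercepts).  Returns the mode, the
    negative Hessian there, the penalised log-likelihood, and a
    convergence flag.
    """
    z = z0.copy()

    def pll(zv: np.ndarray) -> float:
        return _bernoulli_ll(y, w, M @ zv) - 0.5 * float(zv @ (pen * zv))

    ll = pll(z)
    H = np.empty((M.shape[1], M.shape[1]))
    ok = False
    for _ in range(max_iter):
        eta = M @ z
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        g = M.T @ (w * (y - mu)) - pen * z
        omega = w * mu * (1 - mu)
        H = (M.T * omega) @ M
        H[np.diag_indices_from(H)] += pen
        try:
            cf = scipy.linalg.cho_factor(H)
            step = scipy.linalg.cho_solve(cf, g)
        except scipy.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(len(H)), g)
        # step-halving keeps the penalised objective non-decreasing
        scale = 1.0
        for _ in range(30):
            z_new = z + scale * step
            ll_new = pll(z_new)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        z, ll_prev, ll = z_new, ll, ll_new
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            ok = True
            break
    return z, H, ll, ok


def _fit_prepared(
    prep: _Prepared,
    fix_variances: Mapping[str, float] | None = None,
    theta0: Mapping[str, float] | None = None,
    outer_tol: float = 1e-6,
    outer_maxiter: int = 200,
) -> FittedModel:
    """Optimise the Laplace objective over the free variance components."""
    X, y, w, names, terms, spec = (
        prep.X, prep.y, prep.w, prep.names, prep.terms, prep.spec,
    )
    p = X.shape[1]
    fix_variances = dict(fix_variances or {})
    for t in fix_variances:
        if t not in spec.random_intercepts:
            raise ValueError(f"fix_variances names unknown term {t!r}")

    # terms pinned at exactly zero variance drop out of the joint mode
    active = [
        (t, codes, labels)
        for t, codes, labels in terms
        if fix_variances.get(t, None) != 0.0
    ]
    q_sizes = [len(labels) for _, _, labels in active]
    q = int(sum(q_sizes))
    blocks = [X]
    for (_, codes, labels), qt in zip(active, q_sizes):
        Z = np.zeros((len(y), qt))
        Z[np.arange(len(y)), codes] = 1.0
        blocks.append(Z)
    M = np.hstack(blocks) if len(blocks) > 1 else X

    free = [
        i for i, (t, _, _) in enumerate(active) if t not in fix_variances
    ]
    fixed_logvar = {
        i: np.log(fix_variances[t])
        for i, (t, _, _) in enumerate(active)
        if t in fix_variances
    }

    z_cache = np.zeros(p + q)
    if len(y):
        ybar = min(max(np.average(y, weights=w), 1e-3), 1 - 1e-3)
        z_cache[0] = np.log(ybar / (1 - ybar))
    state: dict = {}

    def laplace_negloglik(theta_free: np.ndarray) -> float:
        logvar = np.empty(len(active))
        for j, i in enumerate(free):
            logvar[i] = theta_free[j]
        for i, lv in fixed_logvar.items():
            logvar[i] = lv
        pen = np.zeros(p + q)
        off = p
        for i, qt in enumerate(q_sizes):
            pen[off: off + qt] = np.exp(-logvar[i])
            off += qt
        z, H, pll, ok = _pirls(M, y, w, pen, z_cache)
        z_cache[:] = z
        ll = pll
        if q:
            off = p
            for i, qt in enumerate(q_sizes):
                ll -= 0.5 * qt * logvar[i]
                off += qt
            sign, logdet = np.linalg.slogdet(H[p:, p:])
            ll -= 0.5 * logdet
        state.update(z=z.copy(), H=H, loglik=ll, inner_ok=ok, logvar=logvar.copy())
        return -ll

    outer_ok = True
    if free:
        start = np.full(len(free), np.log(0.1))
        if theta0:
            for j, i in enumerate(free):
                t = active[i][0]
                if t in theta0:
                    start[j] = theta0[t]
        f0 = laplace_negloglik(start)
        res = scipy.optimize.minimize(
            laplace_negloglik,
            start,
            method="Nelder-Mead",
            options={
                # outer_tol is relative to the log-likelihood magnitude
                "fatol": outer_tol * (1.0 + abs(f0)),
                "xatol": 1e-3,
                "maxiter": outer_maxiter * max(1, len(free)),
            },
        )
        laplace_negloglik(res.x)
        outer_ok = bool(res.success)
    else:
        laplace_negloglik(np.empty(0))

    z = state["z"]
    H = state["H"]
    loglik = state["loglik"]
    converged = bool(state["inner_ok"] and outer_ok)
    if not converged:
        logger.warning(
            "fit of %s did not converge (inner_ok=%s outer_ok=%s)",
            spec.id, state["inner_ok"], outer_ok,
        )

    try:
        cov = scipy.linalg.cho_solve(scipy.linalg.cho_factor(H), np.eye(len(H)))
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except scipy.linalg.LinAlgError:
        se = np.full(p, np.nan)

    variance_components: dict[str, float] = {}
    for i, (t, _, _) in enumerate(active):
        variance_components[t] = float(np.exp(state["logvar"][i]))
    for t, v in (fix_variances or {}).items():
        if v == 0.0:
            variance_components[t] = 0.0

    random_effects: dict[str, pd.Series] = {}
    off = p
    for (t, _, labels), qt in zip(active, q_sizes):
        random_effects[t] = pd.Series(z[off: off + qt], index=labels, name=t)
        off += qt
    for t in spec.random_intercepts:
        if t not in random_effects:
            _, _, labels = next(tt for tt in terms if tt[0] == t)
            random_effects[t] = pd.Series(0.0, index=labels, name=t)

    n_params = design.count_parameters(spec)
    n_eff = len(y)
    return FittedModel(
        spec=spec,
        beta=pd.Series(z[:p], index=names, name="beta"),
        beta_se=pd.Series(se, index=names, name="se"),
        variance_components=variance_components,
        random_effects=random_effects,
        loglik=float(loglik),
        aic=float(-2 * loglik + 2 * n_params),
        bic=float(-2 * loglik + n_params * np.log(n_eff)),
        converged=converged,
        n_obs=n_eff,
    )


def fit(
    records: pd.DataFrame,
    spec: ModelSpec,
    fix_variances: Mapping[str, float] | None = None,
) -> FittedModel:
    """Fit one specification to respondent records.

    ``records`` must carry domain, wave, the four cell factors, a
    ``lf_partic_c`` column, ``weight`` and the binary ``outcome``.
    Variance components listed in ``fix_variances`` are pinned instead of
    estimated (zero pins reduce the model to weighted fixed-effects
    logistic regression for those terms).
    """
    prep = prepare(records, spec)
    return _fit_prepared(prep, fix_variances=fix_variances)


def prediction_grid(
    domains: Sequence, waves: Sequence, labor_force: pd.DataFrame
) -> pd.DataFrame:
    """Full (domain, wave, cell) grid with centred labor-force values."""
    cells = design.cell_frame()
    lf = labor_force.set_index(["domain", "wave"])["lf_partic_c"]
    frames = []
    for d in domains:
        for t in waves:
            if (d, t) not in lf.index:
                raise ValueError(
                    f"labor-force value missing for domain={d} wave={t}"
                )
            block = cells.copy()
            block.insert(0, "domain", d)
            block.insert(1, "wave", t)
            block["lf_partic_c"] = lf.loc[(d, t)]
            frames.append(block)
    return pd.concat(frames, ignore_index=True)


def predict_cells(
    model: FittedModel,
    labor_force: pd.DataFrame,
    domains: Sequence | None = None,
    waves: Sequence | None = None,
) -> pd.DataFrame:
    """Predicted outcome probability for every (domain, wave, cell).

    ``labor_force`` must carry ``domain``, ``wave`` and ``lf_partic_c``.
    Returns 72 * n_domains * n_waves rows with a ``pi_hat`` column.
    """
    if domains is None:
        domains = sorted(labor_force["domain"].unique())
    if waves is None:
        waves = sorted(labor_force["wave"].unique())
    grid = prediction_grid(domains, waves, labor_force)
    X, names, _ = design.design_matrix(grid, model.spec)
    if list(names) != list(model.beta.index):
        raise ValueError("prediction design columns do not match fitted model")
    eta = X @ model.beta.to_numpy()
    for term, u in model.random_effects.items():
        lookup = dict(u.items())
        if term == "domain":
            keys = grid["domain"]
        elif term == "wave":
            keys = grid["wave"]
        else:
            keys = pd.Series(
                list(zip(grid["domain"], grid["race_eth"])), index=grid.index
            )
        eta += keys.map(lookup).fillna(0.0).to_numpy()
    out = grid[["domain", "wave", *CELL_FACTORS]].copy()
    out["pi_hat"] = expit(eta)
    return out


def select_model(fits: Sequence[FittedModel]) -> FittedModel:
    """Smallest AIC among converged fits; ties by BIC, then parameters."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise RuntimeError("no converged fits to select from")
    return min(
        converged,
        key=lambda f: (f.aic, f.bic, design.count_parameters(f.spec)),
    )
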