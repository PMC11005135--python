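"""Post-stratification frame construction.

For every (domain, wave, cell): a direct survey estimate of smoking
prevalence with a Kish effective-sample-size binomial variance, a
model-smoothed estimate from a weighted logistic regression with the
four two-way interactions (domain:race, sex:age, sex:race, age:race), a
variance-weighted composite of the two, small-cell fallback rules, and
multiplication by the cell's adult population.  The resulting smoker
totals are raked by iterative proportional fitting so that, within each
domain-wave, each single-factor margin matches the direct survey total.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.special import expit

from . import design
from .design import CELL_FACTORS, FACTOR_LEVELS

__all__ = [
    "direct_estimates",
    "model_estimates",
    "composite",
    "apply_fallback",
    "smoker_totals",
    "rake",
    "survey_margins",
    "build_frame",
]

logger = logging.getLogger(__name__)

IPF_TOL = 1e-8
IPF_MAX_SWEEPS = 1000
#: fixed factor update order for determinism
IPF_ORDER = ("sex", "age_group", "race_eth", "ses")

MIN_CELL_N = 5


def _full_grid(domains: Sequence, waves: Sequence) -> pd.MultiIndex:
    cells = design.build_cells()
    tuples = [
        (d, t, *c) for d in sorted(domains) for t in sorted(waves) for c in cells
    ]
    return pd.MultiIndex.from_tuples(
        tuples, names=["domain", "wave", *CELL_FACTORS]
    )


def direct_estimates(smoking: pd.DataFrame) -> pd.DataFrame:
    """Weighted direct smoking prevalence per (domain, wave, cell).

    Returns columns ``n_direct`` (respondent count), ``p_direct``
    (weighted proportion; NaN for empty cells) and ``v_direct`` using the
    binomial variance p(1-p)/n_eff with the Kish effective sample size
    n_eff = (sum w)^2 / sum w^2.
    """
    df = smoking.copy()
    df["_wy"] = df["weight"] * df["smoker"]
    df["_w2"] = df["weight"] ** 2
    g = df.groupby(["domain", "wave", *CELL_FACTORS], sort=True)
    agg = g.agg(
        n_direct=("smoker", "size"),
        _sw=("weight", "sum"),
        _sw2=("_w2", "sum"),
        _swy=("_wy", "sum"),
    )
    idx = _full_grid(smoking["domain"].unique(), smoking["wave"].unique())
    agg = agg.reindex(idx)
    agg["n_direct"] = agg["n_direct"].fillna(0).astype(int)
    p = agg["_swy"] / agg["_sw"]
    n_eff = agg["_sw"] ** 2 / agg["_sw2"]
    agg["p_direct"] = p
    agg["v_direct"] = p * (1 - p) / n_eff
    return agg[["n_direct", "p_direct", "v_direct"]].reset_index()


def _smoking_design(df: pd.DataFrame, domains: Sequence) -> tuple[np.ndarray, list[str]]:
    """Design for the frame-smoothing logistic model.

    Main effects for domain, sex, age, race and SES plus the domain:race,
    sex:age, sex:race and age:race two-way interactions.
    """
    domains = sorted(domains)
    ref_dom = domains[0]
    dom_arr = df["domain"].to_numpy()
    dom_cols = [(dom_arr == d).astype(float) for d in domains if d != ref_dom]
    dom_names = [f"domain[{d}]" for d in domains if d != ref_dom]

    def dummies(factor: str) -> tuple[list[np.ndarray], list[str]]:
        levels = FACTOR_LEVELS[factor]
        ref = design.REFERENCE_LEVELS[factor]
        arr = df[factor].to_numpy()
        cols = [(arr == lv).astype(float) for lv in levels if lv != ref]
        names = [f"{factor}[{lv}]" for lv in levels if lv != ref]
        return cols, names

    sex_c, sex_n = dummies("sex")
    age_c, age_n = dummies("age_group")
    race_c, race_n = dummies("race_eth")
    ses_c, ses_n = dummies("ses")

    cols = [np.ones(len(df))] + dom_cols + sex_c + age_c + race_c + ses_c
    names = ["intercept"] + dom_names + sex_n + age_n + race_n + ses_n

    def interact(c1, n1, c2, n2):
        for a, na in zip(c1, n1):
            for b, nb in zip(c2, n2):
                cols.append(a * b)
                names.append(f"{na}:{nb}")

    interact(dom_cols, dom_names, race_c, race_n)
    interact(sex_c, sex_n, age_c, age_n)
    interact(sex_c, sex_n, race_c, race_n)
    interact(age_c, age_n, race_c, race_n)
    return np.column_stack(cols), names


def model_estimates(smoking: pd.DataFrame) -> pd.DataFrame:
    """Model-smoothed smoking prevalence per (domain, wave, cell).

    A weighted fixed-effects logistic regression is fit separately for
    each wave; cell predictions carry a delta-method variance from the
    coefficient covariance.  Returns columns ``p_model``, ``v_model``.
    """
    domains = sorted(smoking["domain"].unique())
    out = []
    for wave, block in smoking.groupby("wave", sort=True):
        X, names = _smoking_design(block, domains)
        _, rr, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rr))
        tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            aliased = sorted(names[j] for j in piv[rank:])
            raise ValueError(
                f"smoothing model rank deficient in wave {wave}; "
                f"aliased terms: {aliased}"
            )
        model = sm.GLM(
            block["smoker"].to_numpy(dtype=float),
            X,
            family=sm.families.Binomial(),
            var_weights=block["weight"].to_numpy(dtype=float),
        )
        res = model.fit()
        cov = np.asarray(res.cov_params())
        cells = design.cell_frame()
        grid = pd.concat(
            [cells.assign(domain=d) for d in domains], ignore_index=True
        )
        Xg, _ = _smoking_design(grid, domains)
        eta = Xg @ res.params
        mu = expit(eta)
        gprime = (mu * (1 - mu))[:, None] * Xg
        var = np.einsum("ij,jk,ik->i", gprime, cov, gprime)
        part = grid[["domain", *CELL_FACTORS]].copy()
        part.insert(1, "wave", wave)
        part["p_model"] = mu
        part["v_model"] = var
        out.append(part)
    return pd.concat(out, ignore_index=True)


def composite(
    p_direct: float, v_direct: float, p_model: float, v_model: float
) -> tuple[float, float]:
    """Variance-weighted blend of direct and model estimates.

    Returns ``(a, theta)`` with ``a = v_model / (v_model + v_direct)``
    and ``theta = a * p_direct + (1 - a) * p_model``: the direct
    estimate gets more weight when the model estimate is the noisier of
    the two.
    """
    if v_direct < 0 or v_model < 0:
        raise ValueError("variances must be nonnegative")
    if v_direct == 0 and v_model == 0:
        raise ValueError("composite undefined when both variances are zero")
    a = v_model / (v_model + v_direct)
    return a, a * p_direct + (1 - a) * p_model


def apply_fallback(
    n_direct: int, p_direct: float, theta: float, p_model: float
) -> tuple[float, str]:
    """Choose the composite or the model estimate for one cell.

    The model estimate is used when the direct estimate is unstable:
    cell sample size < 5, direct prevalence exactly 0 or 1, or estimated
    smoker count (n * p) below one.
    """
    use_model = (
        n_direct < MIN_CELL_N
        or not np.isfinite(p_direct)
        or p_direct == 0.0
        or p_direct == 1.0
        or n_direct * p_direct < 1.0
    )
    if use_model:
        return p_model, "model"
    return theta, "composite"


def smoker_totals(frame: pd.DataFrame, population: pd.DataFrame) -> pd.Series:
    """Pre-raking smoker totals: chosen prevalence times cell population."""
    keys = ["domain", "wave", *CELL_FACTORS]
    pop = population.set_index(keys)["population"]
    idx = pd.MultiIndex.from_frame(frame[keys])
    missing = idx.difference(pop.index)
    if len(missing):
        raise ValueError(f"population missing for cell {tuple(missing[0])}")
    return frame["chosen_p"].to_numpy() * pop.reindex(idx).to_numpy()


def rake(
    seed: np.ndarray,
    margins: Sequence[np.ndarray],
    tol: float = IPF_TOL,
    max_sweeps: int = IPF_MAX_SWEEPS,
    factor_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Iterative proportional fitting of an n-way nonnegative table.

    ``margins[k]`` gives the target totals along axis ``k``.  Axes are
    updated in order each sweep until every margin matches within
    relative tolerance ``tol``.
    """
    table = np.asarray(seed, dtype=float).copy()
    if (table < 0).any():
        raise ValueError("seed table must be nonnegative")
    if len(margins) != table.ndim:
        raise ValueError("one margin vector required per table axis")
    names = list(factor_names or [f"axis{k}" for k in range(table.ndim)])
    margins = [np.asarray(m, dtype=float) for m in margins]
    for k, m in enumerate(margins):
        if len(m) != table.shape[k]:
            raise ValueError(f"margin length mismatch on {names[k]}")
        cur = table.sum(axis=tuple(a for a in range(table.ndim) if a != k))
        bad = (m > 0) & (cur == 0)
        if bad.any():
            lv = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"zero seed mass in {names[k]} level {lv} with positive margin"
            )

    def max_rel_err() -> float:
        err = 0.0
        for k, m in enumerate(margins):
            cur = table.sum(axis=tuple(a for a in range(table.ndim) if a != k))
            denom = np.where(m > 0, m, 1.0)
            err = max(err, float(np.max(np.abs(cur - m) / denom)))
        return err

    for _ in range(max_sweeps):
        for k, m in enumerate(margins):
            axes = tuple(a for a in range(table.ndim) if a != k)
            cur = table.sum(axis=axes)
            scale = np.divide(m, cur, out=np.zeros_like(m), where=cur > 0)
            shape = [1] * table.ndim
            shape[k] = table.shape[k]
            table *= scale.reshape(shape)
        if max_rel_err() < tol:
            return table
    raise RuntimeError(
        f"IPF did not converge in {max_sweeps} sweeps; "
        f"final max relative margin error {max_rel_err():.3e}"
    )


def survey_margins(smoking: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Direct smoker totals per factor level at population scale.

    Survey weights are calibrated within each (domain, wave) so they sum
    to the total adult population of that domain-wave; the margin for a
    level is then the calibrated weighted count of respondents who smoke
    in that level.  All four factor margins share an identical total by
    construction.  Long format: domain, wave, factor, level, total.
    """
    pop_dw = population.groupby(["domain", "wave"])["population"].sum()
    rows = []
    for (d, t), block in smoking.groupby(["domain", "wave"], sort=True):
        if (d, t) not in pop_dw.index:
            raise ValueError(f"population missing for domain={d} wave={t}")
        scale = pop_dw.loc[(d, t)] / block["weight"].sum()
        wy = block["weight"] * block["smoker"] * scale
        for factor in IPF_ORDER:
            totals = wy.groupby(block[factor]).sum()
            for level in FACTOR_LEVELS[factor]:
                rows.append(
                    {
                        "domain": d,
                        "wave": t,
                        "factor": factor,
                        "level": level,
                        "total": float(totals.get(level, 0.0)),
                    }
                )
    return pd.DataFrame(rows)


def build_frame(
    smoking: pd.DataFrame, population: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble and rake the full post-stratification frame.

    Returns ``(frame, margins)`` where ``frame`` has one row per
    (domain, wave, cell) carrying the direct, model, composite and raked
    quantities, and ``margins`` is the raking-target table.
    """
    keys = ["domain", "wave", *CELL_FACTORS]
    de = direct_estimates(smoking)
    me = model_estimates(smoking)
    frame = de.merge(me, on=keys, how="left", validate="one_to_one")
    if frame["p_model"].isna().any():
        bad = frame[frame["p_model"].isna()].iloc[0]
        raise ValueError(
            f"model estimate missing for domain={bad['domain']} wave={bad['wave']}"
        )

    p_d = frame["p_direct"].to_numpy()
    v_d = frame["v_direct"].to_numpy()
    p_m = frame["p_model"].to_numpy()
    v_m = frame["v_model"].to_numpy()
    # composite only where the direct variance is defined and positive
    composable = np.isfinite(p_d) & np.isfinite(v_d) & (v_d + v_m > 0)
    a = np.full(len(frame), np.nan)
    theta = np.full(len(frame), np.nan)
    a[composable] = v_m[composable] / (v_m[composable] + v_d[composable])
    theta[composable] = (
        a[composable] * p_d[composable] + (1 - a[composable]) * p_m[composable]
    )
    frame["a"] = a
    frame["theta"] = theta

    chosen = np.empty(len(frame))
    flags = []
    n_d = frame["n_direct"].to_numpy()
    for i in range(len(frame)):
        chosen[i], flag = apply_fallback(n_d[i], p_d[i], theta[i], p_m[i])
        flags.append(flag)
    frame["chosen_p"] = chosen
    frame["chosen"] = flags

    pop = population.set_index(keys)["population"]
    idx = pd.MultiIndex.from_frame(frame[keys])
    missing = idx.difference(pop.index)
    if len(missing):
        raise ValueError(f"population missing for cell {tuple(missing[0])}")
    frame["population"] = pop.reindex(idx).to_numpy()
    frame["N_raw"] = frame["chosen_p"] * frame["population"]

    margins = survey_margins(smoking, population)
    mkey = margins.set_index(["domain", "wave", "factor", "level"])["total"]

    shape = tuple(len(FACTOR_LEVELS[f]) for f in IPF_ORDER)
    level_pos = {
        f: {lv: i for i, lv in enumerate(FACTOR_LEVELS[f])} for f in IPF_ORDER
    }
    raked = np.empty(len(frame))
    frame = frame.sort_values(keys, kind="stable").reset_index(drop=True)
    for (d, t), block in frame.groupby(["domain", "wave"], sort=True):
        seedtab = np.zeros(shape)
        pos = [
            tuple(level_pos[f][block.iloc[i][f]] for f in IPF_ORDER)
            for i in range(len(block))
        ]
        for i, p in enumerate(pos):
            seedtab[p] = block["N_raw"].to_numpy()[i]
        marg = [
            np.asarray(
                [mkey.loc[(d, t, f, lv)] for lv in FACTOR_LEVELS[f]]
            )
            for f in IPF_ORDER
        ]
        fitted = rake(seedtab, marg, factor_names=list(IPF_ORDER))
        raked[block.index.to_numpy()] = [fitted[p] for p in pos]
    frame["N"] = raked
    return frame, margins
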