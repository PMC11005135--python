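"""Bootstrap percentile confidence intervals for post-stratified prevalence.

Respondents of the outcome survey are resampled with replacement within
each (domain, wave) stratum, keeping replicate stratum sizes equal to
the original sizes.  The selected model is refit on every replicate, the
post-stratification frame is held fixed, and percentile intervals are
read off the replicate distribution of each estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import design, glmm
from .design import CELL_FACTORS, FACTOR_LEVELS, ModelSpec
from .poststratify import KEYS, SUBGROUP_FAMILIES

__all__ = ["BootstrapConfig", "resample", "percentile_ci", "bootstrap_pipeline"]

logger = logging.getLogger(__name__)

MAX_DROP_FRACTION = 0.10


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, two-sided level and seed for the bootstrap."""

    n_replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, replicate_index]))


def _resample_indices(
    strata: list[tuple[tuple, np.ndarray]], rng: np.random.Generator
) -> np.ndarray:
    parts = []
    for _, rows in strata:
        n = len(rows)
        parts.append(rows[rng.integers(0, n, n)])
    return np.concatenate(parts)


def _strata(records: pd.DataFrame) -> list[tuple[tuple, np.ndarray]]:
    if len(records) == 0:
        raise ValueError("empty stratum: no records in any (domain, wave)")
    out = []
    for key, block in records.groupby(["domain", "wave"], sort=True):
        out.append((key, block.index.to_numpy()))
    return out


def resample(
    records: pd.DataFrame, config: BootstrapConfig, replicate_index: int
) -> pd.DataFrame:
    """One replicate dataset: equal-probability with-replacement draws
    within each (domain, wave), replicate stratum sizes matching the
    original.  Deterministic in (config.seed, replicate_index)."""
    rng = _replicate_rng(config.seed, replicate_index)
    idx = _resample_indices(_strata(records), rng)
    return records.loc[idx].reset_index(drop=True)


def percentile_ci(values: Sequence[float], alpha: float) -> tuple[float, float]:
    """Equal-tail percentile interval with linear (type-7) interpolation."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(arr) < 2:
        raise ValueError("need >= 2 finite replicate values")
    lo, hi = np.quantile(arr, [alpha / 2, 1 - alpha / 2], method="linear")
    if lo == hi:
        logger.info("degenerate zero-width interval at %g", lo)
    return float(lo), float(hi)


def bootstrap_pipeline(
    records: pd.DataFrame,
    frame: pd.DataFrame,
    spec: ModelSpec,
    labor_force: pd.DataFrame,
    config: BootstrapConfig,
    families: Sequence[str] = SUBGROUP_FAMILIES,
    variance_mode: str = "refit",
    return_replicates: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Attach percentile CIs to every domain/wave/subgroup estimate.

    The frame (raked smoker totals) is held fixed; only the outcome
    survey is resampled.  ``variance_mode`` is ``"refit"`` (re-estimate
    variance components per replicate, warm-started at the base fit) or
    ``"fixed"`` (pin them at the base estimates).  Replicates whose fit
    fails to converge are dropped; more than 10% drops is a hard error.
    """
    if variance_mode not in ("refit", "fixed"):
        raise ValueError("variance_mode must be 'refit' or 'fixed'")
    records = records.reset_index(drop=True)
    prep = glmm.prepare(records, spec)
    base = glmm._fit_prepared(prep)
    if not base.converged:
        raise RuntimeError("base fit did not converge")

    # prediction grid aligned with the frame's row order
    grid = frame[KEYS].copy()
    lf = labor_force.set_index(["domain", "wave"])["lf_partic_c"]
    gkey = pd.MultiIndex.from_frame(grid[["domain", "wave"]])
    missing = gkey.unique().difference(lf.index)
    if len(missing):
        raise ValueError(f"labor-force value missing for {tuple(missing[0])}")
    grid["lf_partic_c"] = lf.reindex(gkey).to_numpy()
    Xg, names, _ = design.design_matrix(grid, spec)
    N = frame["N"].to_numpy(dtype=float)

    # random-effect lookup keys per grid row, one list per term
    grid_keys: dict[str, list] = {}
    for term in spec.random_intercepts:
        if term == "domain":
            grid_keys[term] = grid["domain"].tolist()
        elif term == "wave":
            grid_keys[term] = grid["wave"].tolist()
        else:
            grid_keys[term] = list(zip(grid["domain"], grid["race_eth"]))

    # (domain, wave) aggregation codes and subgroup masks over grid rows
    dw = grid[["domain", "wave"]].drop_duplicates().sort_values(["domain", "wave"])
    dw_labels = list(dw.itertuples(index=False, name=None))
    dw_pos = {k: i for i, k in enumerate(dw_labels)}
    dw_codes = np.asarray([dw_pos[k] for k in gkey])
    masks: list[tuple[str, np.ndarray]] = [("overall", np.ones(len(grid), bool))]
    for factor in families:
        for level in FACTOR_LEVELS[factor]:
            masks.append(
                (f"{factor}={level}", (grid[factor] == level).to_numpy())
            )

    def estimates_from(beta: np.ndarray, reff: dict[str, pd.Series]) -> np.ndarray:
        eta = Xg @ beta
        for term, u in reff.items():
            lookup = dict(u.items())
            eta = eta + np.asarray(
                [lookup.get(k, 0.0) for k in grid_keys[term]]
            )
        pi = expit(eta)
        out = np.empty((len(masks), len(dw_labels)))
        for j, (_, mask) in enumerate(masks):
            num = np.bincount(dw_codes[mask], weights=(N * pi)[mask],
                              minlength=len(dw_labels))
            den = np.bincount(dw_codes[mask], weights=N[mask],
                              minlength=len(dw_labels))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[j] = np.where(den > 0, num / den, np.nan)
        return out

    point = estimates_from(base.beta.to_numpy(), base.random_effects)

    strata = _strata(records)
    theta0 = {
        t: float(np.log(max(v, 1e-7)))
        for t, v in base.variance_components.items()
    }
    fixed = base.variance_components if variance_mode == "fixed" else None

    reps: list[np.ndarray] = []
    rep_ids: list[int] = []
    dropped = 0
    for r in range(config.n_replicates):
        rng = _replicate_rng(config.seed, r)
        idx = _resample_indices(strata, rng)
        rprep = glmm._Prepared(
            X=prep.X[idx],
            y=prep.y[idx],
            w=prep.w[idx],
            names=prep.names,
            terms=[(t, codes[idx], labels) for t, codes, labels in prep.terms],
            spec=spec,
        )
        try:
            fitr = glmm._fit_prepared(
                rprep,
                fix_variances=fixed,
                theta0=theta0,
                outer_tol=1e-4,
                outer_maxiter=60,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("replicate %d failed: %s", r, exc)
            dropped += 1
            continue
        if not fitr.converged:
            logger.warning("replicate %d did not converge; dropped", r)
            dropped += 1
            continue
        reps.append(estimates_from(fitr.beta.to_numpy(), fitr.random_effects))
        rep_ids.append(r)

    if dropped > MAX_DROP_FRACTION * config.n_replicates:
        raise RuntimeError(
            f"{dropped}/{config.n_replicates} bootstrap replicates dropped"
        )
    stack = np.stack(reps)  # (B, n_subgroups, n_dw)

    rows = []
    for j, (label, _) in enumerate(masks):
        for i, (d, t) in enumerate(dw_labels):
            vals = stack[:, j, i]
            finite = vals[np.isfinite(vals)]
            if len(finite) >= 2:
                lo, hi = percentile_ci(finite, config.alpha)
            else:
                lo = hi = np.nan
            rows.append(
                {"domain": d, "wave": t, "subgroup": label,
                 "p_hat": point[j, i], "ci_low": lo, "ci_high": hi,
                 "n_replicates_used": len(finite)}
            )
    estimates = pd.DataFrame(rows)
    if not return_replicates:
        return estimates
    rep_rows = []
    for b, r in enumerate(rep_ids):
        for j, (label, _) in enumerate(masks):
            for i, (d, t) in enumerate(dw_labels):
                rep_rows.append(
                    {"replicate": r, "domain": d, "wave": t,
                     "subgroup": label, "p_hat": stack[b, j, i]}
                )
    return estimates, pd.DataFrame(rep_rows)
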