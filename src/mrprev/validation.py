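"""Agreement with an external gold survey and recovery against truth.

Agreement uses the concordance correlation coefficient, factored into a
precision component (Pearson correlation) and an accuracy component
(bias correction); with two paired series the overall coefficient
reduces exactly to Lin's coefficient, computed here with population
(1/n) moment estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceResult",
    "concordance",
    "agreement_report",
    "recovery_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceResult:
    occc: float
    precision: float
    accuracy: float
    n_pairs: int


def concordance(modeled, gold) -> ConcordanceResult:
    """Concordance correlation between two paired series.

    occc = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2);
    precision is the Pearson correlation, accuracy the bias-correction
    factor, with occc = precision * accuracy exactly.
    """
    x = np.asarray(modeled, dtype=float)
    y = np.asarray(gold, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired series must be equal-length 1-d arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    tiny = (1e-12 * (abs(mx) + abs(my) + 1.0)) ** 2
    if vx < tiny or vy < tiny:
        raise ValueError("zero variance in a series: correlation undefined")
    cxy = ((x - mx) * (y - my)).mean()
    precision = cxy / np.sqrt(vx * vy)
    accuracy = 2 * np.sqrt(vx * vy) / (vx + vy + (mx - my) ** 2)
    return ConcordanceResult(
        occc=float(precision * accuracy),
        precision=float(precision),
        accuracy=float(accuracy),
        n_pairs=len(x),
    )


def agreement_report(
    modeled: pd.DataFrame, gold: pd.DataFrame, group_col: str = "subgroup"
) -> pd.DataFrame:
    """Per-subgroup agreement between modeled and gold estimates.

    Both inputs carry ``domain``, ``wave``, ``subgroup`` and an estimate
    column (``p_hat`` for modeled, ``estimate`` for gold).  Pairs are
    pooled across domain-waves within each subgroup label.  Groups with
    fewer than 3 pairs are skipped with a warning.  The slope/intercept
    columns are the least-squares fit of modeled on gold.
    """
    joined = modeled.merge(
        gold, on=["domain", "wave", group_col], suffixes=("_m", "_g")
    )
    rows = []
    for label, block in joined.groupby(group_col, sort=True):
        block = block.dropna(subset=["p_hat", "estimate"])
        if len(block) < 3:
            logger.warning("subgroup %s has <3 pairs; skipped", label)
            continue
        x = block["p_hat"].to_numpy()
        y = block["estimate"].to_numpy()
        res = concordance(x, y)
        slope, intercept = np.polyfit(y, x, 1)
        rows.append(
            {group_col: label, "n_pairs": res.n_pairs, "occc": res.occc,
             "precision": res.precision, "accuracy": res.accuracy,
             "slope": float(slope), "intercept": float(intercept)}
        )
    return pd.DataFrame(rows)


def recovery_metrics(estimates: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Bias, RMSE and (when CIs are present) coverage against truth.

    ``estimates`` carries domain, wave, subgroup, p_hat and optional
    ci_low/ci_high; ``truth`` carries domain, wave, subgroup, p_true.
    """
    keys = ["domain", "wave", "subgroup"]
    merged = estimates.merge(truth, on=keys, how="left")
    if merged["p_true"].isna().any():
        bad = merged[merged["p_true"].isna()].iloc[0]
        raise ValueError(
            f"truth missing for domain={bad['domain']} wave={bad['wave']} "
            f"subgroup={bad['subgroup']}"
        )
    err = merged["p_hat"] - merged["p_true"]
    out = {
        "bias": float(err.mean()),
        "rmse": float(np.sqrt((err**2).mean())),
        "n": int(len(merged)),
    }
    if {"ci_low", "ci_high"} <= set(estimates.columns):
        ok = merged.dropna(subset=["ci_low", "ci_high"])
        covered = (ok["ci_low"] <= ok["p_true"]) & (ok["p_true"] <= ok["ci_high"])
        out["coverage"] = float(covered.mean()) if len(ok) else np.nan
    return out
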