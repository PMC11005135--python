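"""Population-weighted aggregation of cell predictions.

Domain-wave prevalence is the weighted average of the 72 cell-level
predicted probabilities, weighted by the raked smoker totals of the
post-stratification frame.  Subgroup estimates reuse the same cell
predictions restricted to the relevant cells; no refitting occurs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CELL_FACTORS, FACTOR_LEVELS

__all__ = ["poststratified_prevalence", "subgroup_estimates", "SUBGROUP_FAMILIES"]

KEYS = ["domain", "wave", *CELL_FACTORS]

#: factors over which standard subgroup estimates are produced
SUBGROUP_FAMILIES = ("sex", "age_group", "race_eth")


def _merged(predictions: pd.DataFrame, frame: pd.DataFrame) -> pd.DataFrame:
    pred_idx = pd.MultiIndex.from_frame(predictions[KEYS])
    frame_idx = pd.MultiIndex.from_frame(frame[KEYS])
    missing = pred_idx.symmetric_difference(frame_idx)
    if len(missing):
        sample = [tuple(k) for k in missing[:5]]
        raise ValueError(
            f"predictions and frame cover different grids; "
            f"{len(missing)} mismatched keys, e.g. {sample}"
        )
    return predictions.merge(
        frame[KEYS + ["N"]], on=KEYS, validate="one_to_one"
    )


def poststratified_prevalence(
    predictions: pd.DataFrame,
    frame: pd.DataFrame,
    subgroup: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Prevalence per (domain, wave) for one subgroup.

    ``subgroup`` maps cell factors to required levels (empty or None for
    the overall estimate).  Cells with zero total support yield a NaN
    ``p_hat`` with ``support`` = 0 rather than a numeric zero.
    """
    merged = _merged(predictions, frame)
    label = "overall"
    if subgroup:
        parts = []
        for factor, level in subgroup.items():
            if factor not in CELL_FACTORS:
                raise ValueError(f"unknown subgroup factor {factor!r}")
            if level not in FACTOR_LEVELS[factor]:
                raise ValueError(f"unknown level {level!r} for factor {factor!r}")
            merged = merged[merged[factor] == level]
            parts.append(f"{factor}={level}")
        label = ",".join(parts)
    rows = []
    for (d, t), block in merged.groupby(["domain", "wave"], sort=True):
        total = block["N"].sum()
        p_hat = (
            float((block["N"] * block["pi_hat"]).sum() / total)
            if total > 0
            else np.nan
        )
        rows.append(
            {"domain": d, "wave": t, "subgroup": label,
             "p_hat": p_hat, "support": float(total)}
        )
    return pd.DataFrame(rows)


def subgroup_estimates(
    predictions: pd.DataFrame,
    frame: pd.DataFrame,
    families: Sequence[str] = SUBGROUP_FAMILIES,
) -> pd.DataFrame:
    """Overall plus one estimate per level of each requested factor."""
    parts = [poststratified_prevalence(predictions, frame)]
    for factor in families:
        for level in FACTOR_LEVELS[factor]:
            parts.append(
                poststratified_prevalence(predictions, frame, {factor: level})
            )
    return pd.concat(parts, ignore_index=True)
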