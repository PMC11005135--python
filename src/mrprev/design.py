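"""Covariate coding for the prevalence models.

Defines the demographic cell cross-classification (sex x age group x
race/ethnicity x socioeconomic status, 72 cells), the SES composite, the
domain-centred labor-force covariate, the temporal bases (linear,
categorical, piecewise-linear with hinge terms), and the nine candidate
model specifications together with their design matrices and parameter
counts.

Reference levels are fixed: male, age 50+, non-Hispanic White, high SES,
wave 0.  Predictions are invariant to this choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEX_LEVELS",
    "AGE_LEVELS",
    "RACE_LEVELS",
    "SES_LEVELS",
    "FACTOR_LEVELS",
    "CELL_FACTORS",
    "CellKey",
    "build_cells",
    "derive_ses",
    "center_labor_force",
    "modeled_time_points",
    "TimeBasisSpec",
    "time_basis",
    "time_basis_matrix",
    "ModelSpec",
    "design_matrix",
    "count_parameters",
    "default_model_specs",
]

SEX_LEVELS = ("female", "male")
AGE_LEVELS = ("18-29", "30-49", "50+")
RACE_LEVELS = ("nh_white", "nh_black", "hispanic", "other_nh")
SES_LEVELS = ("low", "moderate", "high")

CELL_FACTORS = ("sex", "age_group", "race_eth", "ses")

FACTOR_LEVELS: Mapping[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "age_group": AGE_LEVELS,
    "race_eth": RACE_LEVELS,
    "ses": SES_LEVELS,
}

#: reference level per factor (omitted from dummy coding)
REFERENCE_LEVELS: Mapping[str, str] = {
    "sex": "male",
    "age_group": "50+",
    "race_eth": "nh_white",
    "ses": "high",
}

RANDOM_INTERCEPT_TERMS = ("domain", "race_in_domain", "wave")

# fixed-effect columns that do not depend on the time basis:
# intercept(1) + sex(1) + age(2) + race(3) + ses(2) + labor force(1)
# + sex:age(2) + sex:race(3) + age:race(6) + sex:age:race(6)
_N_FIXED_NON_TIME = 27


class CellKey(NamedTuple):
    """One demographic post-stratification cell."""

    sex: str
    age_group: str
    race_eth: str
    ses: str


def build_cells() -> list[CellKey]:
    """Return the 72 demographic cells in a fixed, total order.

    The order is the lexicographic cross-product of the declared level
    orders (sex, age group, race/ethnicity, SES).
    """
    return [
        CellKey(s, a, r, e)
        for s, a, r, e in itertools.product(
            SEX_LEVELS, AGE_LEVELS, RACE_LEVELS, SES_LEVELS
        )
    ]


def cell_frame() -> pd.DataFrame:
    """The 72 cells as a DataFrame with one column per factor."""
    return pd.DataFrame(build_cells(), columns=list(CELL_FACTORS))


def derive_ses(education_gt_hs: bool, income_ge_threshold: bool) -> str:
    """Collapse binary education and income indicators into the SES composite.

    ``education_gt_hs`` is True for more than a high-school education
    (not-reported folds into False); ``income_ge_threshold`` is True for
    household income at or above the threshold (not-reported folds into
    False).  Both True -> ``high``; both False -> ``low``; otherwise
    ``moderate``.
    """
    if education_gt_hs and income_ge_threshold:
        return "high"
    if not education_gt_hs and not income_ge_threshold:
        return "low"
    return "moderate"


def center_labor_force(rates: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre labor-force participation rates within each domain.

    Parameters
    ----------
    rates
        Columns ``domain``, ``wave``, ``rate``; one row per (domain, wave).

    Returns
    -------
    DataFrame with an added ``lf_partic_c`` column (rate minus the
    domain mean over waves).  Every domain must carry a rate for every
    wave present anywhere in the table.
    """
    required = {"domain", "wave", "rate"}
    missing_cols = required - set(rates.columns)
    if missing_cols:
        raise ValueError(f"labor-force table missing columns: {sorted(missing_cols)}")
    if rates.duplicated(["domain", "wave"]).any():
        dup = rates[rates.duplicated(["domain", "wave"])].iloc[0]
        raise ValueError(
            f"duplicate labor-force rate for domain={dup['domain']} wave={dup['wave']}"
        )
    domains = sorted(rates["domain"].unique())
    waves = sorted(rates["wave"].unique())
    have = set(zip(rates["domain"], rates["wave"]))
    for d in domains:
        for t in waves:
            if (d, t) not in have:
                raise ValueError(f"missing labor-force rate for domain={d} wave={t}")
    out = rates.copy()
    out["lf_partic_c"] = out["rate"] - out.groupby("domain")["rate"].transform("mean")
    return out


def modeled_time_points(n_survey_waves: int, split_waves: Sequence[int] = ()) -> int:
    """Number of temporal points after splitting extended waves in two.

    Each wave listed in ``split_waves`` contributes one extra time point
    (its collection period is split into two sub-waves).
    """
    if n_survey_waves < 1:
        raise ValueError("n_survey_waves must be >= 1")
    for wv in split_waves:
        if not 1 <= wv <= n_survey_waves:
            raise ValueError(f"split wave {wv} outside 1..{n_survey_waves}")
    return n_survey_waves + len(split_waves)


@dataclass(frozen=True)
class TimeBasisSpec:
    """Temporal basis: ``linear``, ``categorical``, or ``pwlt`` (hinges)."""

    kind: str
    n_waves: int
    knots: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "categorical", "pwlt"):
            raise ValueError(f"unknown time basis kind: {self.kind!r}")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")
        object.__setattr__(self, "knots", tuple(self.knots))
        if self.kind == "pwlt":
            if not self.knots:
                raise ValueError("pwlt basis requires at least one knot")
            prev = 0.0
            for k in self.knots:
                if not (0 < k < self.n_waves - 1):
                    raise ValueError(
                        f"knot {k} outside open interval (0, {self.n_waves - 1})"
                    )
                if k <= prev and prev != 0.0:
                    raise ValueError("knots must be strictly increasing")
                prev = k
            if len(self.knots) > 1 and any(
                b <= a for a, b in zip(self.knots, self.knots[1:])
            ):
                raise ValueError("knots must be strictly increasing")
        elif self.knots:
            raise ValueError(f"{self.kind} basis takes no knots")

    @property
    def n_columns(self) -> int:
        if self.kind == "linear":
            return 1
        if self.kind == "categorical":
            return self.n_waves - 1
        return 1 + len(self.knots)

    @property
    def column_names(self) -> list[str]:
        if self.kind == "linear":
            return ["time"]
        if self.kind == "categorical":
            return [f"wave_{t}" for t in range(1, self.n_waves)]
        return ["time"] + [f"time_hinge_{k:g}" for k in self.knots]


def time_basis(wave_index: int, spec: TimeBasisSpec) -> np.ndarray:
    """Basis row for a single 0-based wave index."""
    if not 0 <= wave_index < spec.n_waves:
        raise ValueError(f"wave_index {wave_index} outside 0..{spec.n_waves - 1}")
    return time_basis_matrix(np.asarray([wave_index]), spec)[0]


def time_basis_matrix(waves: np.ndarray, spec: TimeBasisSpec) -> np.ndarray:
    """Basis rows for an array of 0-based wave indices."""
    waves = np.asarray(waves)
    if waves.size and (waves.min() < 0 or waves.max() > spec.n_waves - 1):
        bad = waves[(waves < 0) | (waves > spec.n_waves - 1)][0]
        raise ValueError(f"wave_index {bad} outside 0..{spec.n_waves - 1}")
    t = waves.astype(float)
    if spec.kind == "linear":
        return t[:, None]
    if spec.kind == "categorical":
        out = np.zeros((len(t), spec.n_waves - 1))
        for j in range(1, spec.n_waves):
            out[:, j - 1] = t == j
        return out
    cols = [t] + [np.maximum(0.0, t - k) for k in spec.knots]
    return np.column_stack(cols)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: time basis, random intercepts, weighting flag.

    The fixed-effect structure is identical across candidates: main
    effects for sex, age group, race/ethnicity and SES, the centred
    labor-force rate, the time basis, and the sex:age, sex:race,
    age:race and sex:age:race interactions.
    """

    id: str
    time_spec: TimeBasisSpec
    random_intercepts: tuple[str, ...] = ("domain",)
    use_weights: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "random_intercepts", tuple(self.random_intercepts))
        for term in self.random_intercepts:
            if term not in RANDOM_INTERCEPT_TERMS:
                raise ValueError(
                    f"unknown random-intercept term {term!r}; "
                    f"expected one of {RANDOM_INTERCEPT_TERMS}"
                )
        if len(set(self.random_intercepts)) != len(self.random_intercepts):
            raise ValueError("duplicate random-intercept terms")


def count_parameters(spec: ModelSpec) -> int:
    """Fixed-effect column count plus number of variance components."""
    return _N_FIXED_NON_TIME + spec.time_spec.n_columns + len(spec.random_intercepts)


def _dummy_block(
    values: pd.Series, factor: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Dummy columns for all non-reference levels of one factor."""
    levels = FACTOR_LEVELS[factor]
    ref = REFERENCE_LEVELS[factor]
    arr = values.to_numpy()
    unknown = set(arr) - set(levels)
    if unknown:
        bad = sorted(unknown)[0]
        idx = values.index[values == bad][0]
        raise ValueError(
            f"unknown level {bad!r} for field {factor!r} in record {idx}"
        )
    nonref = [lv for lv in levels if lv != ref]
    cols = np.column_stack([(arr == lv).astype(float) for lv in nonref])
    names = [f"{factor}[{lv}]" for lv in nonref]
    return cols, names, nonref


def design_matrix(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], dict[str, tuple[np.ndarray, list]]]:
    """Fixed-effects design matrix and random-effect grouping labels.

    Parameters
    ----------
    records
        Must carry ``domain``, ``wave``, the four cell factors, and
        ``lf_partic_c`` (domain-centred labor-force rate).

    Returns
    -------
    (X, column_names, groups) where ``groups`` maps each random-intercept
    term of ``spec`` to ``(codes, labels)``: integer group codes per row
    and the sorted group labels they index.
    """
    required = {"domain", "wave", "lf_partic_c", *CELL_FACTORS}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    n = len(records)
    sex_b, sex_names, _ = _dummy_block(records["sex"], "sex")
    age_b, age_names, _ = _dummy_block(records["age_group"], "age_group")
    race_b, race_names, _ = _dummy_block(records["race_eth"], "race_eth")
    ses_b, ses_names, _ = _dummy_block(records["ses"], "ses")

    tmat = time_basis_matrix(records["wave"].to_numpy(), spec.time_spec)

    blocks = [np.ones((n, 1)), sex_b, age_b, race_b, ses_b,
              records["lf_partic_c"].to_numpy()[:, None], tmat]
    names: list[str] = (
        ["intercept"] + sex_names + age_names + race_names + ses_names
        + ["lf_partic_c"] + spec.time_spec.column_names
    )

    def _interact(b1, n1, b2, n2):
        cols, cnames = [], []
        for j1, nm1 in enumerate(n1):
            for j2, nm2 in enumerate(n2):
                cols.append(b1[:, j1] * b2[:, j2])
                cnames.append(f"{nm1}:{nm2}")
        return np.column_stack(cols), cnames

    sa, sa_names = _interact(sex_b, sex_names, age_b, age_names)
    sr, sr_names = _interact(sex_b, sex_names, race_b, race_names)
    ar, ar_names = _interact(age_b, age_names, race_b, race_names)
    sar_cols, sar_names = [], []
    for j1, nm1 in enumerate(sex_names):
        for j2, nm2 in enumerate(age_names):
            for j3, nm3 in enumerate(race_names):
                sar_cols.append(sex_b[:, j1] * age_b[:, j2] * race_b[:, j3])
                sar_names.append(f"{nm1}:{nm2}:{nm3}")
    blocks += [sa, sr, ar, np.column_stack(sar_cols)]
    names += sa_names + sr_names + ar_names + sar_names

    X = np.hstack(blocks)
    assert X.shape[1] == len(names) == _N_FIXED_NON_TIME + spec.time_spec.n_columns

    groups: dict[str, tuple[np.ndarray, list]] = {}
    for term in spec.random_intercepts:
        if term == "domain":
            labels = sorted(records["domain"].unique().tolist())
            lookup = {g: i for i, g in enumerate(labels)}
            codes = records["domain"].map(lookup).to_numpy()
        elif term == "wave":
            labels = sorted(records["wave"].unique().tolist())
            lookup = {g: i for i, g in enumerate(labels)}
            codes = records["wave"].map(lookup).to_numpy()
        else:  # race_in_domain
            pairs = list(zip(records["domain"], records["race_eth"]))
            labels = sorted(set(pairs))
            lookup = {g: i for i, g in enumerate(labels)}
            codes = np.asarray([lookup[p] for p in pairs])
        groups[term] = (codes.astype(np.intp), labels)
    return X, names, groups


def _default_knots(n_waves: int) -> tuple[int, int, int]:
    """Knot positions (cc, lag, cv) on the 0-based wave-index scale.

    At 13 waves these are the anchor positions 6, 7 and 10 (first wave
    at/after the named calendar years); for other wave counts they are
    placed proportionally, kept interior and ordered cc <= lag < cv.
    """
    if n_waves == 13:
        return 6, 7, 10
    if n_waves < 4:
        raise ValueError("default specs need at least 4 waves")
    top = n_waves - 2
    cv = min(top, max(2, int(np.floor(10 / 12 * (n_waves - 1)))))
    lag = min(cv - 1, max(1, int(np.floor(7 / 12 * (n_waves - 1)))))
    cc = min(lag, max(1, int(np.floor(6 / 12 * (n_waves - 1)))))
    return cc, lag, cv


def default_model_specs(n_waves: int = 13) -> list[ModelSpec]:
    """The nine candidate specifications.

    Models 1-2: linear and categorical time with a domain intercept.
    Models 3-7: piecewise-linear trends with one or two hinge terms.
    Model 8: model 7 plus a race-within-domain intercept.  Model 9:
    model 7's trend with domain and wave intercepts, fit unweighted.
    """
    cc, lag, cv = _default_knots(n_waves)

    def pwlt(*knots: float) -> TimeBasisSpec:
        return TimeBasisSpec("pwlt", n_waves, tuple(knots))

    lin = TimeBasisSpec("linear", n_waves)
    cat = TimeBasisSpec("categorical", n_waves)
    return [
        ModelSpec("model1", lin),
        ModelSpec("model2", cat),
        ModelSpec("model3", pwlt(cc)),
        ModelSpec("model4", pwlt(lag)),
        ModelSpec("model5", pwlt(cv)),
        ModelSpec("model6", pwlt(cc, cv)),
        ModelSpec("model7", pwlt(lag, cv)),
        ModelSpec("model8", pwlt(lag, cv), ("domain", "race_in_domain")),
        ModelSpec("model9", pwlt(lag, cv), ("domain", "wave"), use_weights=False),
    ]
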