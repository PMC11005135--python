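"""Synthetic surveys with known truth for exercising the pipeline.

Generates, from one seeded configuration: (i) a cell population census,
(ii) an outcome survey with domain random intercepts, demographic fixed
effects and temporal trends, (iii) a large smoking-status survey used to
build the post-stratification frame, and (iv) an independent gold survey
reporting direct subgroup estimates with design-based variances.  A truth
table records every cell's outcome probability and smoker population so
downstream estimates can be scored against known values.

All randomness flows from ``TruthConfig.seed`` through a fixed spawn
order, so identical configurations give byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import design
from .design import CELL_FACTORS, FACTOR_LEVELS, ModelSpec, TimeBasisSpec

__all__ = [
    "SampleSizes",
    "TruthConfig",
    "Truth",
    "build_truth",
    "generate_population",
    "generate_outcome_survey",
    "generate_smoking_survey",
    "generate_gold_survey",
    "true_aggregates",
    "default_truth_config",
    "write_all",
]

# fixed spawn order for child RNG streams
_STREAMS = ("population", "labor_force", "domain_effects", "nested_effects",
            "outcome_survey", "smoking_survey", "gold_survey")


@dataclass(frozen=True)
class SampleSizes:
    """Respondents per (domain, wave) for each generated survey."""

    outcome: int = 500
    smoking: int = 2000
    gold: int = 2000

    def __post_init__(self) -> None:
        for name in ("outcome", "smoking", "gold"):
            if getattr(self, name) < 1:
                raise ValueError(f"sample size {name!r} must be >= 1")


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the data-generating process.

    ``fixed_effects`` and ``smoking_model_coefs`` are coefficient maps on
    the log-odds scale keyed by the design-matrix column names of
    :func:`mrprev.design.design_matrix` (unknown keys are an error;
    missing keys are zero).
    """

    n_domains: int
    n_waves: int
    fixed_effects: Mapping[str, float]
    sigma_domain: float
    smoking_model_coefs: Mapping[str, float]
    sigma_nested: float = 0.0
    time_spec: TimeBasisSpec | None = None
    cell_population_range: tuple[int, int] = (200, 2000)
    sample_sizes: SampleSizes = field(default_factory=SampleSizes)
    lf_rate_range: tuple[float, float] = (55.0, 70.0)
    weight_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("field n_domains: must be >= 2")
        if self.n_waves < 2:
            raise ValueError("field n_waves: must be >= 2")
        if self.sigma_domain < 0:
            raise ValueError("field sigma_domain: must be >= 0")
        if self.sigma_nested < 0:
            raise ValueError("field sigma_nested: must be >= 0")
        if self.weight_sigma < 0:
            raise ValueError("field weight_sigma: must be >= 0")
        lo, hi = self.cell_population_range
        if lo < 1 or hi < lo:
            raise ValueError("field cell_population_range: need 1 <= min <= max")
        if self.time_spec is None:
            object.__setattr__(
                self, "time_spec", TimeBasisSpec("linear", self.n_waves)
            )
        elif self.time_spec.n_waves != self.n_waves:
            raise ValueError("field time_spec: n_waves mismatch with config")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child generator for one named stream."""
        idx = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[idx])


def default_truth_config(
    n_domains: int = 3,
    n_waves: int = 4,
    seed: int = 0,
    sample_sizes: SampleSizes | None = None,
    sigma_domain: float = 0.3,
    sigma_nested: float = 0.0,
) -> TruthConfig:
    """A plausible, moderately heterogeneous generating process."""
    fixed = {
        "intercept": logit(0.30),
        "sex[female]": 0.25,
        "age_group[18-29]": 0.50,
        "age_group[30-49]": 0.20,
        "race_eth[nh_black]": 2.0,
        "race_eth[hispanic]": 0.6,
        "race_eth[other_nh]": 0.3,
        "ses[low]": 0.10,
        "ses[moderate]": 0.05,
        "lf_partic_c": 0.02,
        "time": 0.06,
        "sex[female]:age_group[18-29]": 0.10,
        "sex[female]:race_eth[nh_black]": 0.15,
        "age_group[18-29]:race_eth[nh_black]": -0.20,
    }
    smoking = {
        "intercept": logit(0.18),
        "age_group[18-29]": 0.30,
        "age_group[30-49]": 0.15,
        "ses[low]": 0.45,
        "ses[moderate]": 0.25,
        "race_eth[nh_black]": 0.10,
        "race_eth[hispanic]": -0.15,
        "time": -0.03,
    }
    return TruthConfig(
        n_domains=n_domains,
        n_waves=n_waves,
        fixed_effects=fixed,
        sigma_domain=sigma_domain,
        sigma_nested=sigma_nested,
        smoking_model_coefs=smoking,
        sample_sizes=sample_sizes or SampleSizes(),
        seed=seed,
    )


@dataclass(frozen=True)
class Truth:
    """Ground truth: per-cell probabilities and populations.

    ``table`` has one row per (domain, wave, cell) with the true outcome
    probability ``pi_true``, smoking probability ``p_smoke``, adult
    ``population`` and smoker population ``n_true``.  ``labor_force``
    holds the uncentred rate per (domain, wave).
    """

    table: pd.DataFrame
    labor_force: pd.DataFrame
    domain_effects: pd.Series
    nested_effects: pd.Series


def _grid(config: TruthConfig) -> pd.DataFrame:
    cells = design.cell_frame()
    rows = []
    for d in range(config.n_domains):
        for t in range(config.n_waves):
            block = cells.copy()
            block.insert(0, "domain", d)
            block.insert(1, "wave", t)
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


def generate_population(config: TruthConfig) -> pd.DataFrame:
    """One positive integer adult population per (domain, wave, cell)."""
    rng = config.rng("population")
    grid = _grid(config)
    lo, hi = config.cell_population_range
    grid["population"] = rng.integers(lo, hi + 1, size=len(grid))
    return grid


def _labor_force(config: TruthConfig) -> pd.DataFrame:
    rng = config.rng("labor_force")
    lo, hi = config.lf_rate_range
    rows = [
        {"domain": d, "wave": t, "rate": rng.uniform(lo, hi)}
        for d in range(config.n_domains)
        for t in range(config.n_waves)
    ]
    return pd.DataFrame(rows)


def _coef_vector(coefs: Mapping[str, float], names: list[str]) -> np.ndarray:
    unknown = set(coefs) - set(names)
    if unknown:
        raise ValueError(
            f"coefficient keys not in design columns: {sorted(unknown)}"
        )
    return np.asarray([coefs.get(nm, 0.0) for nm in names])


def build_truth(config: TruthConfig) -> Truth:
    """Construct the full truth table for a configuration."""
    pop = generate_population(config)
    lf = design.center_labor_force(_labor_force(config))
    grid = pop.merge(lf[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"])

    spec = ModelSpec("truth", config.time_spec, random_intercepts=())
    X, names, _ = design.design_matrix(grid, spec)

    eta = X @ _coef_vector(config.fixed_effects, names)
    dom_rng = config.rng("domain_effects")
    dom_eff = pd.Series(
        dom_rng.normal(0.0, config.sigma_domain, config.n_domains),
        index=range(config.n_domains),
        name="domain_effect",
    )
    eta += dom_eff.to_numpy()[grid["domain"].to_numpy()]

    nest_rng = config.rng("nested_effects")
    pairs = [(d, r) for d in range(config.n_domains) for r in FACTOR_LEVELS["race_eth"]]
    nest_eff = pd.Series(
        nest_rng.normal(0.0, config.sigma_nested, len(pairs)),
        index=pd.MultiIndex.from_tuples(pairs, names=["domain", "race_eth"]),
        name="nested_effect",
    )
    if config.sigma_nested > 0:
        keys = list(zip(grid["domain"], grid["race_eth"]))
        eta += nest_eff.loc[keys].to_numpy()

    grid["pi_true"] = expit(eta)
    eta_s = X @ _coef_vector(config.smoking_model_coefs, names)
    grid["p_smoke"] = expit(eta_s)
    grid["n_true"] = grid["p_smoke"] * grid["population"]
    grid = grid.drop(columns=["lf_partic_c"])
    return Truth(table=grid, labor_force=lf[["domain", "wave", "rate"]],
                 domain_effects=dom_eff, nested_effects=nest_eff)


def _sample_survey(
    config: TruthConfig,
    truth: Truth,
    rng: np.random.Generator,
    n_per_stratum: int,
    size_col: str,
    prob_col: str,
    outcome_col: str,
) -> pd.DataFrame:
    """Draw respondents stratified by (domain, wave).

    Cell membership is multinomial proportional to ``size_col``; the
    binary outcome is Bernoulli with the cell's ``prob_col``; weights are
    lognormal, normalised to mean 1 within the stratum.
    """
    lf_lookup = truth.labor_force.set_index(["domain", "wave"])["rate"]
    frames = []
    for (d, t), block in truth.table.groupby(["domain", "wave"], sort=True):
        sizes = block[size_col].to_numpy().astype(float)
        probs = sizes / sizes.sum()
        counts = rng.multinomial(n_per_stratum, probs)
        idx = np.repeat(block.index.to_numpy(), counts)
        rows = truth.table.loc[idx, ["domain", "wave", *CELL_FACTORS]].reset_index(
            drop=True
        )
        p = np.repeat(block[prob_col].to_numpy(), counts)
        rows[outcome_col] = (rng.random(len(rows)) < p).astype(int)
        if config.weight_sigma > 0:
            w = rng.lognormal(
                -0.5 * config.weight_sigma**2, config.weight_sigma, len(rows)
            )
            w /= w.mean()
        else:
            w = np.ones(len(rows))
        rows["weight"] = w
        rows["labor_force_rate"] = lf_lookup.loc[(d, t)]
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def generate_outcome_survey(
    config: TruthConfig, truth: Truth | None = None
) -> pd.DataFrame:
    """Outcome survey: smokers sampled within smoker populations.

    Columns: domain, wave, sex, age_group, race_eth, ses, weight,
    outcome, labor_force_rate.
    """
    truth = truth or build_truth(config)
    return _sample_survey(
        config, truth, config.rng("outcome_survey"),
        config.sample_sizes.outcome, "n_true", "pi_true", "outcome",
    )


def generate_smoking_survey(
    config: TruthConfig, truth: Truth | None = None
) -> pd.DataFrame:
    """Smoking-status survey: adults sampled within total populations."""
    truth = truth or build_truth(config)
    return _sample_survey(
        config, truth, config.rng("smoking_survey"),
        config.sample_sizes.smoking, "population", "p_smoke", "smoker",
    )


def _subgroup_masks(df: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    out: list[tuple[str, pd.Series]] = [("overall", pd.Series(True, index=df.index))]
    for factor in ("sex", "age_group", "race_eth"):
        for level in FACTOR_LEVELS[factor]:
            out.append((f"{factor}={level}", df[factor] == level))
    return out


def generate_gold_survey(
    config: TruthConfig, truth: Truth | None = None
) -> pd.DataFrame:
    """Independent gold survey reported as direct subgroup estimates.

    Respondents are drawn like the outcome survey (equal weights), then
    collapsed to per-(domain, wave, subgroup) estimates with the simple
    binomial variance p(1-p)/n.  Columns: domain, wave, subgroup,
    estimate, variance, n.
    """
    truth = truth or build_truth(config)
    cfg = replace(config, weight_sigma=0.0)
    micro = _sample_survey(
        cfg, truth, config.rng("gold_survey"),
        config.sample_sizes.gold, "n_true", "pi_true", "outcome",
    )
    rows = []
    for (d, t), block in micro.groupby(["domain", "wave"], sort=True):
        for label, mask in _subgroup_masks(block):
            sel = block[mask]
            n = len(sel)
            if n == 0:
                rows.append({"domain": d, "wave": t, "subgroup": label,
                             "estimate": np.nan, "variance": np.nan, "n": 0})
                continue
            p = sel["outcome"].mean()
            rows.append({"domain": d, "wave": t, "subgroup": label,
                         "estimate": p, "variance": p * (1 - p) / n, "n": n})
    return pd.DataFrame(rows)


def true_aggregates(
    truth: Truth, subgroup: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """True prevalence per (domain, wave): smoker-weighted mean of pi_true.

    ``subgroup`` filters cells by factor level, e.g. ``{"sex": "female"}``.
    """
    df = truth.table
    if subgroup:
        for factor, level in subgroup.items():
            if factor not in CELL_FACTORS:
                raise ValueError(f"unknown subgroup factor {factor!r}")
            df = df[df[factor] == level]
    if df.empty:
        raise ValueError(f"subgroup filter selects no cells: {subgroup!r}")
    def agg(block: pd.DataFrame) -> float:
        return float(
            np.average(block["pi_true"], weights=block["n_true"])
        )
    out = (
        df.groupby(["domain", "wave"], sort=True)
        .apply(agg, include_groups=False)
        .rename("p_true")
        .reset_index()
    )
    return out


def true_subgroup_aggregates(truth: Truth) -> pd.DataFrame:
    """Long truth table over the standard subgroup labels."""
    frames = []
    base = true_aggregates(truth)
    base.insert(2, "subgroup", "overall")
    frames.append(base)
    for factor in ("sex", "age_group", "race_eth"):
        for level in FACTOR_LEVELS[factor]:
            part = true_aggregates(truth, {factor: level})
            part.insert(2, "subgroup", f"{factor}={level}")
            frames.append(part)
    return pd.concat(frames, ignore_index=True)


def write_all(config: TruthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every artifact and write it as CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)
    artifacts = {
        "population": truth.table[
            ["domain", "wave", *CELL_FACTORS, "population"]
        ],
        "outcome_survey": generate_outcome_survey(config, truth),
        "smoking_survey": generate_smoking_survey(config, truth),
        "gold": generate_gold_survey(config, truth),
        "truth": truth.table,
    }
    paths = {}
    for name, df in artifacts.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
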