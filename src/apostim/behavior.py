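"""Synthetic chick-trial generator with the study's design.

Emulates the wariness experiment: 80 naive chicks split over four groups
(low/high Michelson contrast x spots/stripes; N = 19, 21, 20, 20), two
hatch batches, and five test trials per chick with two binary outcomes
per trial — whether the chick approached the patterned prey and whether
it ate it.

The generative model is a two-stage (hurdle) random-intercept logistic
process.  Each chick i draws b_i ~ Normal(0, sigma_chick^2), shared by
both stages:

    P(approach) = logistic(b0_a + bc_a * high + bp_a * spots + b_i)
    P(eat | approach) = logistic(b0_e + bc_e * high + bt_e * (trial-1) + b_i)
    eaten = approached * Bernoulli(P(eat | approach))

so ``eaten == 1`` implies ``approached == 1`` by construction, matching
how the experiment scores outcomes (an unapproached prey cannot be
eaten).  Default effect sizes are synthetic — the study reports no
log-odds estimates — chosen once so a default cohort shows the study's
qualitative structure: fewer approaches and eats of high-contrast prey,
eating probability rising over trials, no batch effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DesignSpec",
    "BehaviorParams",
    "TrialRecord",
    "GROUPS",
    "simulate_cohort",
    "summarize_proportions",
    "write_trials_csv",
    "read_trials_csv",
]

#: Group labels in the order (contrast, pattern) of the study's 2x2 design.
GROUPS = ("low-stripes", "low-spots", "high-stripes", "high-spots")

TRIALS_COLUMNS = [
    "chick_id", "group", "pattern_class", "contrast_level",
    "batch", "trial", "approached", "eaten",
]


@dataclass(frozen=True)
class DesignSpec:
    """Cohort layout: chicks per group, trials per chick, batches."""

    group_sizes: tuple[int, int, int, int] = (19, 21, 20, 20)
    n_trials: int = 5
    n_batches: int = 2
    # "alternate": chicks alternate batches within group (balanced);
    # "split": first half of each group in batch 1, rest in batch 2
    batch_assignment: str = "alternate"

    def __post_init__(self):
        if any(n <= 0 for n in self.group_sizes) or len(self.group_sizes) != 4:
            raise ValueError("group_sizes must be 4 positive counts")
        if self.n_trials < 1 or self.n_batches < 1:
            raise ValueError("n_trials and n_batches must be >= 1")
        if self.batch_assignment not in ("alternate", "split"):
            raise ValueError("batch_assignment must be 'alternate' or 'split'")

    @property
    def n_chicks(self) -> int:
        return sum(self.group_sizes)


@dataclass(frozen=True)
class BehaviorParams:
    """Log-odds scale parameters of the two-stage generative model."""

    beta0_approach: float = 1.1
    beta0_eat: float = 0.0
    beta_contrast_approach: float = -2.2
    beta_contrast_eat: float = -1.2
    beta_trial_eat: float = 0.35
    beta_pattern: float = 0.0  # spots-vs-stripes shift, both stages
    sigma_chick: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_chick < 0:
            raise ValueError("sigma_chick must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """One chick x one test trial; the row schema of the trials table."""

    chick_id: int
    group: str
    batch: int
    trial: int
    approached: int
    eaten: int

    def __post_init__(self):
        if self.eaten and not self.approached:
            raise ValueError("eaten=1 requires approached=1")
        if self.trial < 1:
            raise ValueError("trial numbering starts at 1")


def _group_attrs(group: str) -> tuple[str, str]:
    contrast, pattern = group.split("-")
    return contrast, pattern


def stage_probabilities(
    params: BehaviorParams, group: str, trial: int, intercept: float = 0.0
) -> tuple[float, float]:
    """Analytic (P(approach), P(eat|approach)) for one cell, given the
    chick intercept.  Exposed so tests can check empirical calibration."""
    contrast, pattern = _group_attrs(group)
    is_high = 1.0 if contrast == "high" else 0.0
    is_spots = 1.0 if pattern == "spots" else 0.0
    eta_a = (
        params.beta0_approach
        + params.beta_contrast_approach * is_high
        + params.beta_pattern * is_spots
        + intercept
    )
    eta_e = (
        params.beta0_eat
        + params.beta_contrast_eat * is_high
        + params.beta_trial_eat * (trial - 1)
        + params.beta_pattern * is_spots
        + intercept
    )
    return float(expit(eta_a)), float(expit(eta_e))


def simulate_cohort(
    design: DesignSpec = DesignSpec(), params: BehaviorParams = BehaviorParams()
) -> pd.DataFrame:
    """Simulate one cohort; returns the trials table (one row per
    chick x trial) in the trial-record CSV schema.  Deterministic given
    ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    rows = []
    chick_id = 0
    for group, n in zip(GROUPS, design.group_sizes):
        contrast, pattern = _group_attrs(group)
        for j in range(n):
            if design.batch_assignment == "alternate":
                batch = 1 + (j % design.n_batches)
            else:
                batch = 1 + (j * design.n_batches) // n
            b = rng.normal(0.0, params.sigma_chick)
            for trial in range(1, design.n_trials + 1):
                p_a, p_e = stage_probabilities(params, group, trial, b)
                approached = int(rng.random() < p_a)
                eaten = approached * int(rng.random() < p_e)
                rows.append(
                    (chick_id, group, pattern, contrast, batch, trial, approached, eaten)
                )
            chick_id += 1
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def summarize_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group-per-trial proportions approached, eaten, eaten|approached.

    ``p_eaten_given_approached`` is NaN (never a conventional zero) for
    cells where no prey was approached.
    """
    if records.empty:
        raise ValueError("no trial records")

    def agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        n_app = int(g["approached"].sum())
        n_eat = int(g["eaten"].sum())
        return pd.Series(
            {
                "n": n,
                "n_approached": n_app,
                "n_eaten": n_eat,
                "p_approached": n_app / n,
                "p_eaten": n_eat / n,
                "p_eaten_given_approached": (n_eat / n_app) if n_app > 0 else np.nan,
            }
        )

    out = (
        records.groupby(["group", "trial"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    for c in ("n", "n_approached", "n_eaten"):
        out[c] = out[c].astype(int)
    return out


def write_trials_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=TRIALS_COLUMNS)


def read_trials_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trials CSV (synthetic output or a deposited dataset after
    renaming columns via ``column_map``); validates schema and the
    eaten-implies-approached constraint."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials table missing columns: {missing}")
    df = df[TRIALS_COLUMNS]
    if ((df["eaten"] == 1) & (df["approached"] == 0)).any():
        raise ValueError("invalid records: eaten=1 with approached=0")
    return df
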