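"""Synthetic questionnaire scores from a two-component normal mixture.

No subject-level data were released by the motivating screening survey, so
everything downstream is exercised on synthetic scores whose generating truth
is known.  Each subject is diseased with probability ``prevalence``; diseased
subjects draw a score from N(mu_pos, sigma_pos^2), the rest from
N(mu_neg, sigma_neg^2).  Scores are rounded to integers and clipped to the
questionnaire range [0, 64] by default, because real Nijmegen totals are
integers; a ``continuous`` mode skips rounding for tests that need the exact
normal mixture.

The ``study-like`` preset reproduces the published stratum summaries of the
motivating survey: 86 men with 4 expected cases (components
N(9.84, 5.81^2) / N(26.75, 2.75^2)) and 129 women with 18 expected cases
(N(12.59, 6.14^2) / N(29.89, 7.10^2)); pooled, 22/215 cases with components
N(11.42, 6.14^2) / N(29.32, 6.59^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .questionnaire_io import ScoredDataset, TOTAL_MAX

__all__ = [
    "MixtureTruth",
    "STUDY_MALE",
    "STUDY_FEMALE",
    "STUDY_POOLED",
    "generate_mixture_scores",
    "generate_study_like",
]


@dataclass(frozen=True)
class MixtureTruth:
    """Generating parameters of a two-component normal mixture of scores.

    The diseased component must have the larger mean (``mu_pos > mu_neg``),
    matching the clinical direction: HVS subjects score higher.
    """

    prevalence: float
    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_neg <= 0 or self.sigma_pos <= 0:
            raise ValueError("component SDs must be positive")
        if self.mu_pos <= self.mu_neg:
            raise ValueError("diseased component mean must exceed the non-diseased mean")
        if self.n < 2:
            raise ValueError("n must be at least 2")


# Published stratum summaries of the motivating survey (score units).
STUDY_MALE = MixtureTruth(
    prevalence=4 / 86, mu_neg=9.84, sigma_neg=5.81, mu_pos=26.75, sigma_pos=2.75, n=86
)
STUDY_FEMALE = MixtureTruth(
    prevalence=18 / 129, mu_neg=12.59, sigma_neg=6.14, mu_pos=29.89, sigma_pos=7.10, n=129
)
STUDY_POOLED = MixtureTruth(
    prevalence=22 / 215, mu_neg=11.42, sigma_neg=6.14, mu_pos=29.32, sigma_pos=6.59, n=215
)


def _draw_labels(
    truth: MixtureTruth, rng: np.random.Generator, fixed_margin: bool
) -> np.ndarray:
    p = truth.prevalence
    if not (0.0 < p < 1.0):
        warnings.warn(
            f"prevalence {p} outside (0,1); generating a degenerate "
            "single-component dataset",
            stacklevel=3,
        )
        return np.full(truth.n, int(p >= 1.0), dtype=int)
    if fixed_margin:
        # exact case count (rounded), positions randomised
        k = int(round(p * truth.n))
        z = np.zeros(truth.n, dtype=int)
        z[rng.choice(truth.n, size=k, replace=False)] = 1
        return z
    return rng.binomial(1, p, size=truth.n)


def generate_mixture_scores(
    truth: MixtureTruth,
    rounding: str = "round_clip",
    fixed_margin: bool = False,
    rng: np.random.Generator | None = None,
    stratum: str | None = None,
) -> ScoredDataset:
    """Draw ``truth.n`` labelled scores from the mixture.

    Parameters
    ----------
    truth
        Generating parameters, including the sample size and seed.
    rounding
        ``round_clip`` (default) rounds to the nearest integer and clips to
        [0, 64]; ``continuous`` returns the raw normal draws.
    fixed_margin
        Draw exactly ``round(prevalence * n)`` cases (deterministic case
        count) instead of Bernoulli labels.
    rng
        Optional generator overriding ``truth.seed`` (used by the study-like
        preset to give each stratum its own substream).

    The same ``truth`` (including seed) always yields the identical dataset.
    """
    if rounding not in ("round_clip", "continuous"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    z = _draw_labels(truth, rng, fixed_margin)
    mu = np.where(z == 1, truth.mu_pos, truth.mu_neg)
    sd = np.where(z == 1, truth.sigma_pos, truth.sigma_neg)
    x = rng.normal(mu, sd)
    if rounding == "round_clip":
        x = np.clip(np.rint(x), 0, TOTAL_MAX).astype(int)
    strata = None if stratum is None else np.full(truth.n, stratum)
    return ScoredDataset(scores=x, stratum=strata, true_label=z)


def generate_study_like(
    seed: int,
    rounding: str = "round_clip",
    fixed_margin: bool = False,
) -> ScoredDataset:
    """Generate one study-like sample: 86 male + 129 female rows (n = 215).

    Each stratum draws from its own deterministic substream of ``seed``, so
    the male rows do not change when the female parameters do.
    """
    child_m, child_f = np.random.SeedSequence(seed).spawn(2)
    male = generate_mixture_scores(
        STUDY_MALE,
        rounding=rounding,
        fixed_margin=fixed_margin,
        rng=np.random.default_rng(child_m),
        stratum="male",
    )
    female = generate_mixture_scores(
        STUDY_FEMALE,
        rounding=rounding,
        fixed_margin=fixed_margin,
        rng=np.random.default_rng(child_f),
        stratum="female",
    )
    return ScoredDataset(
        scores=np.concatenate([male.scores, female.scores]),
        stratum=np.concatenate([male.stratum, female.stratum]),
        true_label=np.concatenate([male.true_label, female.true_label]),
    )
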