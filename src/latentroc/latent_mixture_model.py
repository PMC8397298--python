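"""Bayesian latent-class normal-mixture model for a single continuous test.

Without a gold standard, each subject's disease status z_i is unobserved.
The model treats the observed total scores x_1..x_n as a two-component
normal mixture

    x_i | z_i = 1  ~  N(mu_pos, sigma_pos^2)      (diseased)
    x_i | z_i = 0  ~  N(mu_neg, sigma_neg^2)      (healthy)
    z_i            ~  Bernoulli(pi)

with priors pi ~ Beta(a, b) (default Beta(1,1)), mu_k ~ N(mu0_k, sd_mu_k^2)
(vague by default), and sigma_k ~ Uniform(sigma_low, sigma_high).  Posterior
inference is by Markov chain Monte Carlo: Gibbs updates for z, pi and the
means (all conjugate), and a random-walk Metropolis step on log sigma for the
standard deviations, whose uniform prior breaks conjugacy.

Component labels are identified by the constraint mu_pos > mu_neg (diseased
subjects score higher); any draw violating it is resolved by swapping the
components, which also flips the latent labels and the prevalence.

Sensitivity, specificity, ROC curves and cut-off selection are computed from
the retained draws in :mod:`latentroc.accuracy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .questionnaire_io import ScoredDataset

__all__ = [
    "MixturePriors",
    "MCMCConfig",
    "GibbsState",
    "PosteriorDraws",
    "UnidentifiableDataError",
    "label_posterior",
    "gibbs_step",
    "fit_latent_mixture",
    "mc_error",
]

logger = logging.getLogger(__name__)


class UnidentifiableDataError(ValueError):
    """The data cannot identify a two-component mixture (e.g. all scores equal)."""


@dataclass(frozen=True)
class MixturePriors:
    """Hyperparameters of the latent-class mixture model.

    Two prior policies are supported:

    * **vague** (``MixturePriors()``): ``mu0_neg`` / ``mu0_pos`` default to
      the 25th / 75th percentile of the data, with prior SDs of 100 score
      units (effectively flat on [0, 64]) and sigma ~ U(0.5, 30) for both
      components.  With study-sized samples and ~10% prevalence this
      posterior is weakly identified: the diseased component can widen and
      absorb the healthy upper tail, so accuracy summaries are diffuse.
    * **anchored** (:meth:`anchored`, the package default in
      :func:`fit_latent_mixture`): hyperparameters derived from the
      questionnaire's established clinical rule, which is genuine prior
      knowledge available in any application of this model.

    ``sigma_high_neg`` / ``sigma_high_pos`` override the shared upper bound
    per component (the anchored policy uses this; each latent class gets its
    own scale bound).
    """

    prev_alpha: float = 1.0
    prev_beta: float = 1.0
    mu0_neg: float | None = None
    mu0_pos: float | None = None
    sd_mu_neg: float = 100.0
    sd_mu_pos: float = 100.0
    sigma_low: float = 0.5
    sigma_high: float = 30.0
    sigma_high_neg: float | None = None
    sigma_high_pos: float | None = None

    def __post_init__(self) -> None:
        if self.prev_alpha <= 0 or self.prev_beta <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if self.sd_mu_neg <= 0 or self.sd_mu_pos <= 0:
            raise ValueError("prior SDs on the means must be positive")
        for high in (self.sigma_high, self.sigma_high_neg, self.sigma_high_pos):
            if high is not None and not (0 < self.sigma_low < high):
                raise ValueError("need 0 < sigma_low < sigma_high")

    def sigma_bounds(self, component: str) -> tuple[float, float]:
        high = getattr(self, f"sigma_high_{component}") or self.sigma_high
        return self.sigma_low, high

    @classmethod
    def anchored(
        cls,
        scores: np.ndarray,
        anchor_cutoff: int = 23,
        sd_mu: float = 2.0,
        scale_factor: float = 2.0,
    ) -> "MixturePriors":
        """Priors anchored on the conventional clinical classification.

        The questionnaire ships with an accepted rule (total above
        ``anchor_cutoff`` suggests disease).  Splitting the sample by that
        rule gives a rough but informative picture of the two latent
        classes; the priors encode it: each component mean is centred at
        its side's conditional mean with prior SD ``sd_mu`` score units
        (about the standard error of a small group mean on this scale), and
        each component SD gets the uniform bound
        (0.5, ``scale_factor`` x conditional SD) — a latent class should
        not be dispersed much beyond its conventional proxy group.  When a
        side of the split is nearly empty the anchor falls back to an outer
        decile with a wide scale bound.
        """
        x = np.asarray(scores, dtype=float)
        hi = x[x > anchor_cutoff]
        lo = x[x <= anchor_cutoff]
        sd_all = float(np.std(x, ddof=1))
        if len(hi) >= 2:
            mu0_pos = float(hi.mean())
            high_pos = max(3.0, scale_factor * float(hi.std(ddof=1)))
        else:
            mu0_pos = float(np.percentile(x, 90.0))
            high_pos = max(3.0, sd_all)
        if len(lo) >= 2:
            mu0_neg = float(lo.mean())
            high_neg = max(3.0, scale_factor * float(lo.std(ddof=1)))
        else:
            mu0_neg = float(np.percentile(x, 10.0))
            high_neg = max(3.0, sd_all)
        if mu0_pos <= mu0_neg:
            mu0_pos = mu0_neg + 1.0
        return cls(
            mu0_neg=mu0_neg,
            mu0_pos=mu0_pos,
            sd_mu_neg=sd_mu,
            sd_mu_pos=sd_mu,
            sigma_high_neg=high_neg,
            sigma_high_pos=high_pos,
        )

    def resolve(self, scores: np.ndarray) -> "MixturePriors":
        """Fill data-dependent defaults (quartile-centred mean priors)."""
        q25, q75 = np.percentile(scores, [25.0, 75.0])
        if q75 <= q25:
            q75 = q25 + 1.0
        return replace(
            self,
            mu0_neg=float(q25) if self.mu0_neg is None else self.mu0_neg,
            mu0_pos=float(q75) if self.mu0_pos is None else self.mu0_pos,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings: kept draws, burn-in, thinning, seed, proposal scale.

    The sigma proposal SD (on the log scale) is adapted during burn-in to
    keep Metropolis acceptance in the 20-50% band, then frozen.
    """

    n_iter: int = 20_000
    n_burnin: int = 5_000
    thin: int = 1
    seed: int = 0
    sigma_proposal_sd: float = 0.1
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be at least 100 for usable summaries")
        if self.n_burnin < 0 or self.thin < 1:
            raise ValueError("invalid burn-in or thinning")
        if self.sigma_proposal_sd <= 0:
            raise ValueError("sigma_proposal_sd must be positive")


@dataclass
class GibbsState:
    """Current parameter values and latent labels of the chain."""

    pi: float
    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float
    z: np.ndarray  # 0/1 per subject


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus chain diagnostics.

    ``label_prob[i]`` is the posterior probability that subject i is
    diseased (the mean of its latent indicator over retained draws).
    """

    pi: np.ndarray
    mu_neg: np.ndarray
    sigma_neg: np.ndarray
    mu_pos: np.ndarray
    sigma_pos: np.ndarray
    label_prob: np.ndarray | None = None
    accept_rate: dict = field(default_factory=dict)

    PARAMS = ("pi", "mu_neg", "sigma_neg", "mu_pos", "sigma_pos")

    @property
    def n_draws(self) -> int:
        return len(self.pi)

    @classmethod
    def from_point(
        cls,
        pi: float,
        mu_neg: float,
        sigma_neg: float,
        mu_pos: float,
        sigma_pos: float,
    ) -> "PosteriorDraws":
        """Single plug-in 'draw' — handy for closed-form spot checks."""
        return cls(
            pi=np.array([pi]),
            mu_neg=np.array([mu_neg]),
            sigma_neg=np.array([sigma_neg]),
            mu_pos=np.array([mu_pos]),
            sigma_pos=np.array([sigma_pos]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({p: getattr(self, p) for p in self.PARAMS})

    def summary(self):
        """Posterior mean, SD and batch-means Monte Carlo error per parameter."""
        import pandas as pd

        rows = {}
        for p in self.PARAMS:
            chain = getattr(self, p)
            rows[p] = {
                "mean": float(np.mean(chain)),
                "sd": float(np.std(chain, ddof=1)),
                "mc_error": mc_error(chain),
                "q2.5": float(np.quantile(chain, 0.025)),
                "q97.5": float(np.quantile(chain, 0.975)),
            }
        return pd.DataFrame(rows).T


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    # constant term omitted: only used in ratios
    return -np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def label_posterior(
    x: np.ndarray | float,
    pi: float,
    mu_neg: float,
    sigma_neg: float,
    mu_pos: float,
    sigma_pos: float,
) -> np.ndarray | float:
    """P(z=1 | x) under fixed mixture parameters (the Gibbs label probability).

    Computed as pi*phi(x; mu_pos, sigma_pos) over the mixture density.
    """
    x = np.asarray(x, dtype=float)
    d = _norm_logpdf(x, mu_neg, sigma_neg) - _norm_logpdf(x, mu_pos, sigma_pos)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + (1.0 - pi) / pi * np.exp(d))
    return float(p) if p.ndim == 0 else p


def _update_sigma(
    sigma: float,
    n_k: int,
    ss: float,
    low: float,
    high: float,
    proposal_sd: float,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Random-walk Metropolis on log sigma against sigma^-n_k exp(-ss/2s^2) 1[low,high].

    The log transform contributes a Jacobian factor sigma, hence the extra
    (log s' - log s) term in the acceptance ratio.
    """
    log_s = np.log(sigma)
    log_s_new = log_s + proposal_sd * rng.standard_normal()
    s_new = np.exp(log_s_new)
    if not (low <= s_new <= high):
        return sigma, False
    log_ratio = (
        -n_k * (log_s_new - log_s)
        - 0.5 * ss * (1.0 / s_new**2 - 1.0 / sigma**2)
        + (log_s_new - log_s)
    )
    if np.log(rng.random()) < log_ratio:
        return float(s_new), True
    return sigma, False


def gibbs_step(
    state: GibbsState,
    scores: np.ndarray,
    priors: MixturePriors,
    rng: np.random.Generator,
    proposal_sd: tuple[float, float] = (0.1, 0.1),
    fixed_labels: bool = False,
) -> tuple[GibbsState, tuple[bool, bool]]:
    """One full sweep of the sampler; mutates and returns ``state``.

    Sweep order: latent labels -> prevalence -> component means (conjugate
    normal) -> component SDs (Metropolis on log sigma) -> identifiability
    swap.  With ``fixed_labels`` the labels are clamped (conjugate-limit
    checks) and the swap is skipped, since the clamped labels define the
    components.  Returns the state and the (neg, pos) sigma-move acceptances.
    """
    x = scores
    n = len(x)

    if not fixed_labels:
        p1 = label_posterior(
            x, state.pi, state.mu_neg, state.sigma_neg, state.mu_pos, state.sigma_pos
        )
        state.z = (rng.random(n) < p1).astype(int)

    k = int(state.z.sum())
    state.pi = float(rng.beta(priors.prev_alpha + k, priors.prev_beta + n - k))

    accepts = [False, False]
    for j, comp in enumerate(("neg", "pos")):
        members = x[state.z == (1 if comp == "pos" else 0)]
        n_k = len(members)
        mu0 = getattr(priors, f"mu0_{comp}")
        sd_mu = getattr(priors, f"sd_mu_{comp}")
        sigma = getattr(state, f"sigma_{comp}")
        if n_k == 0:
            # orphaned component: draw its mean from the prior, hold sigma
            logger.debug("component %s empty; drawing mean from prior", comp)
            setattr(state, f"mu_{comp}", float(rng.normal(mu0, sd_mu)))
            continue
        prec = n_k / sigma**2 + 1.0 / sd_mu**2
        mean = (members.sum() / sigma**2 + mu0 / sd_mu**2) / prec
        mu_new = float(rng.normal(mean, np.sqrt(1.0 / prec)))
        setattr(state, f"mu_{comp}", mu_new)
        ss = float(((members - mu_new) ** 2).sum())
        low, high = priors.sigma_bounds(comp)
        sigma_new, acc = _update_sigma(
            sigma, n_k, ss, low, high, proposal_sd[j], rng
        )
        setattr(state, f"sigma_{comp}", sigma_new)
        accepts[j] = acc

    if not fixed_labels and state.mu_pos <= state.mu_neg:
        state.mu_neg, state.mu_pos = state.mu_pos, state.mu_neg
        state.sigma_neg, state.sigma_pos = state.sigma_pos, state.sigma_neg
        state.z = 1 - state.z
        state.pi = 1.0 - state.pi

    return state, (accepts[0], accepts[1])


def _initial_state(
    scores: np.ndarray, priors: MixturePriors, rng: np.random.Generator
) -> GibbsState:
    q25, q75 = np.percentile(scores, [25.0, 75.0])
    if q75 <= q25:
        q75 = q25 + 1.0
    sd = float(np.std(scores, ddof=1))
    z = (scores >= (q25 + q75) / 2.0).astype(int)
    return GibbsState(
        pi=0.5,
        mu_neg=priors.mu0_neg if priors.mu0_neg is not None else float(q25),
        sigma_neg=float(np.clip(sd, *priors.sigma_bounds("neg"))),
        mu_pos=priors.mu0_pos if priors.mu0_pos is not None else float(q75),
        sigma_pos=float(np.clip(sd, *priors.sigma_bounds("pos"))),
        z=z,
    )


def fit_latent_mixture(
    data: ScoredDataset | np.ndarray,
    priors: MixturePriors | None = None,
    config: MCMCConfig | None = None,
    fixed_labels: np.ndarray | None = None,
) -> PosteriorDraws:
    """Fit the latent-class mixture by MCMC and return retained draws.

    Parameters
    ----------
    data
        A :class:`ScoredDataset` or a plain array of scores (n >= 4, at
        least two distinct values).
    priors, config
        Model hyperparameters and chain settings; defaults as documented on
        :class:`MixturePriors` and :class:`MCMCConfig`.
    fixed_labels
        Clamp the latent labels to this 0/1 vector instead of sampling them
        (conjugate-limit validation); the prevalence update then targets its
        closed-form Beta posterior.

    When ``priors`` is None the anchored policy
    (:meth:`MixturePriors.anchored`) is used — the package default, since
    the fully vague priors leave the model weakly identified at realistic
    sample sizes.  Identical (data, priors, config) always reproduce
    identical draws.
    """
    scores = np.asarray(
        data.scores if isinstance(data, ScoredDataset) else data, dtype=float
    )
    n = len(scores)
    if n < 4:
        raise ValueError(f"need at least 4 scores, got {n}")
    if np.unique(scores).size < 2:
        raise UnidentifiableDataError(
            "all scores identical: a two-component mixture is not identifiable"
        )
    priors = (
        MixturePriors.anchored(scores) if priors is None else priors
    ).resolve(scores)
    config = config or MCMCConfig()

    rng = np.random.default_rng(config.seed)
    state = _initial_state(scores, priors, rng)
    clamp = fixed_labels is not None
    if clamp:
        state.z = np.asarray(fixed_labels, dtype=int).copy()
        if len(state.z) != n:
            raise ValueError("fixed_labels length mismatch")

    prop = [config.sigma_proposal_sd, config.sigma_proposal_sd]
    acc_window = [0, 0]
    win_len = 100

    n_keep = config.n_iter
    keep = {p: np.empty(n_keep) for p in PosteriorDraws.PARAMS}
    z_sum = np.zeros(n, dtype=float)
    acc_total = [0, 0]
    kept = 0

    total_sweeps = config.n_burnin + n_keep * config.thin
    for it in range(total_sweeps):
        state, (a_neg, a_pos) = gibbs_step(
            state, scores, priors, rng, proposal_sd=(prop[0], prop[1]),
            fixed_labels=clamp,
        )
        burnin = it < config.n_burnin
        if burnin and config.adapt:
            acc_window[0] += a_neg
            acc_window[1] += a_pos
            if (it + 1) % win_len == 0:
                for j in range(2):
                    rate = acc_window[j] / win_len
                    if rate > 0.5:
                        prop[j] = min(prop[j] * 1.25, 2.0)
                    elif rate < 0.2:
                        prop[j] = max(prop[j] * 0.8, 1e-3)
                    acc_window[j] = 0
        if not burnin:
            post_it = it - config.n_burnin
            if (post_it + 1) % config.thin == 0:
                keep["pi"][kept] = state.pi
                keep["mu_neg"][kept] = state.mu_neg
                keep["sigma_neg"][kept] = state.sigma_neg
                keep["mu_pos"][kept] = state.mu_pos
                keep["sigma_pos"][kept] = state.sigma_pos
                z_sum += state.z
                kept += 1
            acc_total[0] += a_neg
            acc_total[1] += a_pos

    post_sweeps = n_keep * config.thin
    draws = PosteriorDraws(
        **keep,
        label_prob=z_sum / kept,
        accept_rate={
            "sigma_neg": acc_total[0] / post_sweeps,
            "sigma_pos": acc_total[1] / post_sweeps,
        },
    )
    return draws


def mc_error(chain: np.ndarray) -> float:
    """Batch-means Monte Carlo standard error with floor(sqrt(n)) batches.

    The chain is split into a = floor(sqrt(n)) consecutive batches of equal
    size b = n // a (trailing remainder dropped); the MCSE of the chain mean
    is sd(batch means, ddof=1) / sqrt(a).
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise ValueError(f"chain length {n} < 100: too short for batch means")
    a = int(np.sqrt(n))
    b = n // a
    batches = chain[: a * b].reshape(a, b).mean(axis=1)
    return float(np.std(batches, ddof=1) / np.sqrt(a))
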