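"""Group-level random-effects Bayesian model selection.

Treats the model identity behind each subject's data as a random effect:
subject labels are drawn from a multinomial with unknown frequencies r,
which carry a Dirichlet prior.  A Gibbs sampler alternates between the
posterior over subject labels (evidence-weighted frequencies) and the
Dirichlet posterior over frequencies given label counts.  Reported are the
expected frequency of each model (ef, posterior mean of r) and its
exceedance probability (xp, the posterior probability that its frequency
tops every other model's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

__all__ = ["BMSResult", "FamilyPartition", "rfx_bms", "family_inference"]


@dataclass
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    n_samples: int
    names: Optional[tuple] = None
    sampler: dict = field(default_factory=dict)

    def best(self) -> int:
        return int(np.argmax(self.expected_frequency))


@dataclass(frozen=True)
class FamilyPartition:
    """Named disjoint groups of model indices covering the whole space."""

    families: Mapping[str, tuple]
    n_models: int

    def __post_init__(self) -> None:
        seen: list = []
        for members in self.families.values():
            seen.extend(members)
        if sorted(seen) != list(range(self.n_models)):
            raise ValueError("families must disjointly cover all model indices")


def _as_matrix(evidence) -> np.ndarray:
    if hasattr(evidence, "log_evidence"):
        evidence = evidence.log_evidence
    mat = np.asarray(evidence, dtype=float)
    if mat.ndim != 2:
        raise ValueError("evidence must be a subjects x models matrix")
    if not np.all(np.isfinite(mat)):
        raise ValueError("evidence matrix contains non-finite entries")
    return mat


def _xp_from_alpha(
    alpha: np.ndarray, rng: np.random.Generator, n_draws: int, groups=None
) -> np.ndarray:
    draws = rng.dirichlet(alpha, size=n_draws)
    if groups is not None:
        draws = np.stack([draws[:, idx].sum(axis=1) for idx in groups], axis=1)
    maxima = draws.max(axis=1, keepdims=True)
    winners = draws >= maxima  # ties split equally
    return (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)


def _gibbs_alpha(
    log_ev: np.ndarray,
    alpha0: np.ndarray,
    sweeps: int,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Posterior Dirichlet parameters via Rao-Blackwellised Gibbs averaging."""
    burn_in = min(burn_in, sweeps // 2)  # always keep at least half the sweeps
    n, k = log_ev.shape
    r = alpha0 / alpha0.sum()
    mean_p = np.zeros((n, k))
    kept = 0
    for sweep in range(sweeps):
        logp = log_ev + np.log(np.maximum(r, 1e-300))
        logp -= logsumexp(logp, axis=1, keepdims=True)
        p = np.exp(logp)
        if sweep >= burn_in:
            mean_p += p
            kept += 1
        # sample labels
        cdf = np.cumsum(p, axis=1)
        u = rng.random((n, 1))
        z = (u > cdf).sum(axis=1)
        counts = np.bincount(z, minlength=k).astype(float)
        r = rng.dirichlet(alpha0 + counts)
    return alpha0 + mean_p.sum(axis=0) / max(kept, 1)


def rfx_bms(
    evidence: Union[np.ndarray, "object"],
    prior_alpha: Optional[np.ndarray] = None,
    sweeps: int = 5000,
    burn_in: int = 1000,
    xp_draws: int = 100_000,
    seed: int = 0,
    names: Optional[Sequence] = None,
) -> BMSResult:
    """Random-effects model selection over a subjects x models evidence matrix.

    Only within-subject evidence differences matter; adding a constant to a
    subject's row leaves the result unchanged.  With a single model the
    result is trivially ef = xp = 1.
    """
    log_ev = _as_matrix(evidence)
    n, k = log_ev.shape
    if n < 1:
        raise ValueError("need at least one subject")
    if prior_alpha is None:
        prior_alpha = np.ones(k)
    alpha0 = np.asarray(prior_alpha, dtype=float)
    if alpha0.shape != (k,) or np.any(alpha0 <= 0):
        raise ValueError("prior_alpha must be positive with one entry per model")
    sampler = {"sweeps": sweeps, "burn_in": burn_in, "xp_draws": xp_draws, "seed": seed}
    if k == 1:
        return BMSResult(
            alpha0 + n, np.array([1.0]), np.array([1.0]), 0,
            tuple(names) if names else None, sampler,
        )
    rng = np.random.default_rng(seed)
    alpha = _gibbs_alpha(log_ev, alpha0, sweeps, burn_in, rng)
    ef = alpha / alpha.sum()
    xp = _xp_from_alpha(alpha, rng, xp_draws)
    return BMSResult(alpha, ef, xp, xp_draws, tuple(names) if names else None, sampler)


def family_inference(
    evidence: Union[np.ndarray, "object"],
    partition: FamilyPartition,
    sweeps: int = 5000,
    burn_in: int = 1000,
    xp_draws: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Model selection over a partition of the space into families.

    Prior mass is uniform over families and split uniformly within each
    family (per-model prior alpha = 1 / family size), so a large family
    gains no head start from its size alone.  Family ef aggregates member
    frequencies; family xp is computed on aggregated frequency draws.
    """
    log_ev = _as_matrix(evidence)
    k = log_ev.shape[1]
    if partition.n_models != k:
        raise ValueError("partition does not match the evidence matrix width")
    alpha0 = np.empty(k)
    for members in partition.families.values():
        alpha0[list(members)] = 1.0 / len(members)
    rng = np.random.default_rng(seed)
    alpha = _gibbs_alpha(log_ev, alpha0, sweeps, burn_in, rng)
    groups = [list(members) for members in partition.families.values()]
    family_alpha = np.array([alpha[idx].sum() for idx in groups])
    ef = family_alpha / alpha.sum()
    xp = _xp_from_alpha(alpha, rng, xp_draws, groups=groups)
    return BMSResult(
        family_alpha,
        ef,
        xp,
        xp_draws,
        tuple(partition.families.keys()),
        {"sweeps": sweeps, "burn_in": burn_in, "xp_draws": xp_draws, "seed": seed},
    )
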