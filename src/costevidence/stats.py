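"""Regression and group-inference layer: standardised betas, one-sample
t-tests, and exhaustive sign-flip permutation tests.

Subject-level multiple regressions use z-scored regressors (and response)
so coefficients are standardised effect sizes; group significance is a
random-effects one-sample t-test of the per-subject betas against zero.
Paired contrasts can be assessed non-parametrically by enumerating all
2^n sign flips of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionSpec",
    "TTestResult",
    "subject_regression",
    "group_ttest",
    "permutation_ttest",
    "orthogonalize",
]


@dataclass(frozen=True)
class RegressionSpec:
    """Which columns predict the response, and how they are prepared.

    interactions: pairs of regressor names whose product (of the z-scored
    columns, re-z-scored) enters as an additional term.
    orthogonalize: maps a regressor to the regressors whose variance is
    removed from it (residualisation) before z-scoring.
    """

    response: str
    regressors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    orthogonalize: dict = field(default_factory=dict)
    zscore_response: bool = True


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def orthogonalize(target: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Residual of ``target`` after OLS projection on ``others`` (+ intercept)."""
    design = np.column_stack([np.ones(len(target)), others])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ beta


def subject_regression(table: pd.DataFrame, spec: RegressionSpec) -> pd.Series:
    """Standardised OLS betas for one subject's trial table.

    Raises on rank deficiency, naming the collinear columns.
    """
    n = len(table)
    if n < len(spec.regressors) + 2:
        raise ValueError("not enough rows for the requested regressors")
    y = table[spec.response].to_numpy(dtype=float)
    if spec.zscore_response:
        y = _zscore(y)

    columns: dict[str, np.ndarray] = {}
    for name in spec.regressors:
        x = table[name].to_numpy(dtype=float)
        if name in spec.orthogonalize:
            others = np.column_stack(
                [table[o].to_numpy(dtype=float) for o in spec.orthogonalize[name]]
            )
            x = orthogonalize(x, others)
        columns[name] = _zscore(x)
    for a, b in spec.interactions:
        columns[f"{a}:{b}"] = _zscore(columns[a] * columns[b])

    names = list(columns)
    design = np.column_stack([np.ones(n)] + [columns[c] for c in names])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(design)
        bad = [names[i - 1] for i in range(1, design.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return pd.Series(beta[1:], index=names, name=spec.response)


def group_ttest(betas: Sequence[float]) -> TTestResult:
    """Two-sided one-sample t-test of per-subject betas against zero.

    Zero-variance input yields t = +/-inf (p = 0) when the mean is nonzero
    and t = 0 (p = 1) when all betas are exactly zero.
    """
    b = np.asarray(betas, dtype=float)
    n = b.size
    if n < 2:
        raise ValueError("need at least two subjects")
    df = n - 1
    sd = b.std(ddof=1)
    if sd <= 1e-12 * max(float(np.abs(b).max()), 1e-300):  # identical betas
        sd = 0.0
    if sd == 0:
        if b.mean() == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(b.mean()) * np.inf), df, 0.0)
    t = float(b.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(t, df, p)


def _paired_t(diffs: np.ndarray, axis: int = -1) -> np.ndarray:
    n = diffs.shape[axis]
    mean = diffs.mean(axis=axis)
    sd = diffs.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def permutation_ttest(
    betas_a: Sequence[float],
    betas_b: Sequence[float],
    n_perm: int = 2**15,
    seed: Optional[int] = None,
) -> float:
    """Two-sided sign-flip permutation p for a paired t statistic.

    All 2^n sign assignments are enumerated when that many fit in
    ``n_perm`` (the null distribution is then exact and deterministic);
    otherwise ``n_perm`` random flips are drawn from ``seed``.
    """
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n = d.size
    t_obs = float(_paired_t(d))
    if 2**n <= n_perm:
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))
    t_null = _paired_t(signs * d[None, :], axis=1)
    return float(np.mean(np.abs(t_null) >= abs(t_obs) - 1e-12))
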