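"""Nonparametric inference for the PLSC decomposition.

Two resampling procedures:

* **Permutation test of the singular values** — participant rows of the
  gray-matter block are shuffled (breaking the cross-block pairing
  while preserving each block's internal structure), the decomposition
  is refitted, and each observed singular value is compared to the null
  distribution of its positional counterpart.

* **Bootstrap ratios (BSR)** — participants are resampled with
  replacement (the same resample applied to both blocks), blocks are
  re-normalized, the decomposition refitted and sign-aligned to the
  original, and per-element running mean and variance of the saliences
  are accumulated with the Welford single-pass recurrence; no
  per-iteration salience matrices are retained.  BSR = bootstrap mean /
  bootstrap SE behaves like a z-score: |BSR| > 1.96 corresponds to
  p ~ .05 and |BSR| > 3 to p ~ .0027.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from structcov.plsc import (
    PLSCModel,
    cross_block_singular_values,
    cross_block_svd,
)
from structcov.preprocess import PreprocessedBlock

_NULL_QUANTILES = (0.5, 0.95, 0.99)


class InferenceError(ValueError):
    pass


@dataclass
class PermutationResult:
    n_perm: int
    p_per_component: np.ndarray
    null_quantiles: dict
    seed: int
    observed_delta: np.ndarray


@dataclass
class BootstrapResult:
    n_boot: int
    bsr_X: np.ndarray
    bsr_Y: np.ndarray
    boot_mean_X: np.ndarray
    boot_mean_Y: np.ndarray
    boot_se_X: np.ndarray
    boot_se_Y: np.ndarray
    degenerate_X: np.ndarray  # elements with zero bootstrap SE (flagged, not inf)
    degenerate_Y: np.ndarray
    n_redrawn: int
    seed: int


class WelfordAccumulator:
    """Single-pass running mean and variance (Welford/Knuth recurrence).

    Numerically stable streaming moments for arbitrarily shaped arrays;
    used so bootstrap salience moments never require storing iterates.
    """

    def __init__(self, shape: tuple) -> None:
        self.count = 0
        self.mean = np.zeros(shape)
        self._m2 = np.zeros(shape)

    def update(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self._m2 += delta * (x - self.mean)

    @property
    def variance(self) -> np.ndarray:
        if self.count < 2:
            return np.full_like(self.mean, np.nan)
        return self._m2 / (self.count - 1)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)


def _renormalize(values: np.ndarray) -> np.ndarray | None:
    """Center columns and scale to unit sum of squares; None if degenerate."""
    centered = values - values.mean(axis=0, keepdims=True)
    ss = np.sqrt(np.sum(centered**2, axis=0))
    if np.any(ss == 0):
        return None
    return centered / ss


def permutation_test_components(
    X: PreprocessedBlock,
    Y: PreprocessedBlock,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "add_one",
) -> PermutationResult:
    """Row-permutation null for the PLSC singular values.

    Each iteration shuffles the participant rows of the Y (gray-matter)
    block, re-normalizes (a no-op for a row permutation, executed for
    safety) and records the singular values of the reshuffled
    cross-block matrix.  Permuted values are matched to observed ones
    positionally (k-th to k-th).  ``mode="add_one"`` gives
    p_k = (#{delta_perm_k >= delta_k} + 1) / (n_perm + 1); ``mode=
    "paper_literal"`` the raw proportion.
    """
    if n_perm < 100:
        raise InferenceError("n_perm must be >= 100")
    if mode not in ("add_one", "paper_literal"):
        raise InferenceError(f"unknown mode {mode!r}")
    Xv, Yv = X.values, Y.values
    obs = cross_block_singular_values(Xv, Yv)
    K = len(obs)
    n = Xv.shape[0]
    null = np.zeros((n_perm, K))
    small_is_y = Yv.shape[1] <= Xv.shape[1]
    G = (Xv @ Xv.T) if small_is_y else None
    kmax = min(Xv.shape[1], Yv.shape[1], n - 1)
    for b in range(n_perm):
        rng = np.random.default_rng([seed, 4, b])
        perm = rng.permutation(n)
        Yp = _renormalize(Yv[perm])
        if Yp is None:  # cannot happen for a pure row shuffle; guard anyway
            Yp = Yv[perm]
        if small_is_y:
            M = Yp.T @ G @ Yp
            lam = np.linalg.eigvalsh((M + M.T) / 2.0)[::-1]
            null[b] = np.sqrt(np.clip(lam[:kmax], 0.0, None))[:K]
        else:
            null[b] = cross_block_singular_values(Xv, Yp)[:K]
    exceed = np.sum(null >= obs[None, :], axis=0)
    if mode == "add_one":
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    quant = {
        q: np.quantile(null, q, axis=0) for q in _NULL_QUANTILES
    }
    return PermutationResult(
        n_perm=n_perm,
        p_per_component=p,
        null_quantiles=quant,
        seed=seed,
        observed_delta=obs,
    )


def _align_components(
    Ub: np.ndarray, Vb: np.ndarray, U0: np.ndarray, V0: np.ndarray, align: str
) -> tuple[np.ndarray, np.ndarray]:
    if align == "sign":
        d = np.sum(Ub * U0, axis=0) + np.sum(Vb * V0, axis=0)
        s = np.where(d >= 0, 1.0, -1.0)
        return Ub * s, Vb * s
    if align == "procrustes":
        B0 = np.vstack([U0, V0])
        Bb = np.vstack([Ub, Vb])
        A, _, Bt = np.linalg.svd(Bb.T @ B0)
        Q = A @ Bt
        return Ub @ Q, Vb @ Q
    raise InferenceError(f"unknown alignment {align!r}")


def bootstrap_bsr(
    X: PreprocessedBlock,
    Y: PreprocessedBlock,
    model: PLSCModel,
    n_boot: int = 10_000,
    seed: int = 0,
    component: int = 0,
    align: str = "sign",
    max_redraws: int = 100,
) -> BootstrapResult:
    """Bootstrap-ratio stability of the saliences of one component.

    Participants are resampled with replacement (same indices in both
    blocks), columns re-centered/normalized within each resample, the
    decomposition refitted and aligned to the original model (sign
    flip maximizing the dot product per component by default; a full
    Procrustes rotation with ``align="procrustes"`` for near-degenerate
    singular values).  Per-element first and second moments are
    streamed through the Welford recurrence.  Resamples producing a
    constant column (or losing the component) are redrawn and counted.
    """
    if n_boot < 100:
        raise InferenceError("n_boot must be >= 100")
    Xv, Yv = X.values, Y.values
    n = Xv.shape[0]
    K = model.n_components
    if not 0 <= component < K:
        raise InferenceError("component index out of range")
    acc_U = WelfordAccumulator(model.U.shape)
    acc_V = WelfordAccumulator(model.V.shape)
    n_redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_redraws):
            rng = np.random.default_rng([seed, 5, b, attempt])
            idx = rng.integers(0, n, size=n)
            Xb = _renormalize(Xv[idx])
            Yb = _renormalize(Yv[idx])
            if Xb is None or Yb is None:
                n_redrawn += 1
                continue
            Ub, db, Vb = cross_block_svd(Xb, Yb, fix_signs=False)
            if len(db) < K:
                n_redrawn += 1
                continue
            break
        else:
            raise InferenceError("exceeded redraw budget for degenerate resamples")
        Ub, Vb = _align_components(Ub[:, :K], Vb[:, :K], model.U, model.V, align)
        acc_U.update(Ub)
        acc_V.update(Vb)
    se_U, se_V = acc_U.sd, acc_V.sd
    k = component

    def ratio(mean, se):
        out = np.zeros_like(mean)
        ok = se > 0
        out[ok] = mean[ok] / se[ok]
        return out, ~ok

    bsr_X, degen_X = ratio(acc_U.mean[:, k], se_U[:, k])
    bsr_Y, degen_Y = ratio(acc_V.mean[:, k], se_V[:, k])
    return BootstrapResult(
        n_boot=n_boot,
        bsr_X=bsr_X,
        bsr_Y=bsr_Y,
        boot_mean_X=acc_U.mean[:, k],
        boot_mean_Y=acc_V.mean[:, k],
        boot_se_X=se_U[:, k],
        boot_se_Y=se_V[:, k],
        degenerate_X=degen_X,
        degenerate_Y=degen_Y,
        n_redrawn=n_redrawn,
        seed=seed,
    )


def bsr_to_pvalue(bsr: float | np.ndarray) -> float | np.ndarray:
    """Two-tailed normal p-value of a bootstrap ratio: 2 (1 - Phi(|bsr|)).

    BSR 1.96 maps to p ~ .05 and BSR 3 to p ~ .0027.
    """
    return 2.0 * stats.norm.sf(np.abs(bsr))


def threshold_bsr(
    result: BootstrapResult, cutoff: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Significance masks (|BSR| >= cutoff, boundary inclusive) per block."""
    return np.abs(result.bsr_X) >= cutoff, np.abs(result.bsr_Y) >= cutoff


@dataclass
class ScoreAgeFit:
    """Linear and quadratic regressions of a latent brain score on age."""

    f_linear: float
    p_linear: float
    df_linear: tuple[int, int]
    f_quadratic: float
    p_quadratic: float
    df_quadratic: tuple[int, int]
    p_quad_term: float
    preferred: str  # "linear" or "quadratic"


def regress_scores_on_age(
    scores: np.ndarray, age: np.ndarray, alpha: float = 0.05
) -> ScoreAgeFit:
    """Fit score ~ age and score ~ age + age^2 with F statistics.

    The quadratic form is preferred iff its age^2 term is significant
    at ``alpha``; age is centered before squaring to decorrelate the
    regressors.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(age)
    if n < 10:
        raise InferenceError("need at least 10 participants")
    ac = age - age.mean()
    lin = sm.OLS(scores, sm.add_constant(ac)).fit()
    quad = sm.OLS(scores, sm.add_constant(np.column_stack([ac, ac**2]))).fit()
    if lin.ssr <= 1e-12 * max(lin.centered_tss, 1e-300):
        # linear fit is exact to machine precision; the quadratic term
        # cannot improve it and its t-statistic is numerically undefined
        p_quad_term = 1.0
    else:
        p_quad_term = float(quad.pvalues[2])
    return ScoreAgeFit(
        f_linear=float(lin.fvalue),
        p_linear=float(lin.f_pvalue),
        df_linear=(1, n - 2),
        f_quadratic=float(quad.fvalue),
        p_quadratic=float(quad.f_pvalue),
        df_quadratic=(2, n - 3),
        p_quad_term=p_quad_term,
        preferred="quadratic" if p_quad_term < alpha else "linear",
    )


__all__ = [
    "InferenceError",
    "PermutationResult",
    "BootstrapResult",
    "WelfordAccumulator",
    "permutation_test_components",
    "bootstrap_bsr",
    "bsr_to_pvalue",
    "threshold_bsr",
    "ScoreAgeFit",
    "regress_scores_on_age",
]
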