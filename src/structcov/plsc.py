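"""Two-block partial least squares correlation (PLSC).

Given two column-normalized blocks X (participants x WM voxels) and Y
(participants x GM regions), the cross-block correlation matrix
R = X^T Y is decomposed by singular value decomposition,

    R = U diag(delta) V^T,

where the columns of U and V are the *saliences* (loading patterns) of
the WM and GM features, and each singular value delta_k is the
cross-block covariance captured by component k.  Participants'
projections L_X = X U and L_Y = Y V are their latent *brain scores*;
delta_k^2 / sum(delta^2) is the fraction of cross-block covariance
explained.

For voxelwise X the full R (voxels x regions) is never materialized:
the decomposition runs through the smaller block's Gram matrix
(Y^T (X X^T) Y when Y is smaller), which is algebraically identical to
the direct SVD and is equality-tested against it on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from structcov.preprocess import PreprocessedBlock

#: Relative singular-value cutoff below which a component is treated as
#: numerical rank deficiency and dropped.
RANK_TOL = 1e-10


class PLSCError(ValueError):
    pass


@dataclass
class PLSCModel:
    """Fitted PLSC decomposition.

    Attributes
    ----------
    U, V : (features_X x K), (features_Y x K) salience matrices.
    delta : (K,) singular values, nonnegative and nonincreasing.
    var_explained : (K,) fractions delta_k^2 / sum(delta^2).
    Lx, Ly : (n x K) latent brain scores of the fitting data.
    """

    U: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    var_explained: np.ndarray
    Lx: np.ndarray
    Ly: np.ndarray
    x_feature_ids: np.ndarray
    y_feature_ids: np.ndarray
    participants: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.delta)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic sign convention: Y-block salience sums positive
    # (falling back to its largest-magnitude entry when the sum is 0).
    for k in range(V.shape[1]):
        s = V[:, k].sum()
        if s == 0:
            s = V[np.argmax(np.abs(V[:, k])), k]
        if s < 0:
            U[:, k] *= -1.0
            V[:, k] *= -1.0
    return U, V


def cross_block_svd(
    Xv: np.ndarray, Yv: np.ndarray, fix_signs: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of X^T Y computed through the smaller block's Gram matrix.

    Returns ``(U, delta, V)`` with components of numerically nonzero
    singular value, delta descending.  Never forms the features_X x
    features_Y matrix when X is the wide (voxel) block.
    """
    n, p = Xv.shape
    q = Yv.shape[1]
    if Yv.shape[0] != n:
        raise PLSCError("blocks have different numbers of rows")
    if q <= p:
        small, big = Yv, Xv
    else:
        small, big = Xv, Yv
    # eigen-decompose (big^T small)^T (big^T small) = small^T G small
    G = big @ big.T  # n x n
    M = small.T @ G @ small
    M = (M + M.T) / 2.0
    lam, W = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    W = W[:, order]
    delta = np.sqrt(lam)
    keep = delta > RANK_TOL * (delta[0] if delta.size else 1.0)
    kmax = min(p, q, n - 1)
    keep[kmax:] = False
    delta, W = delta[keep], W[:, keep]
    other = big.T @ (small @ W) / delta  # saliences of the big block
    if q <= p:
        U, V = other, W
    else:
        U, V = W, other
    if fix_signs:
        U, V = _fix_signs(U, V)
    return U, delta, V


def cross_block_singular_values(Xv: np.ndarray, Yv: np.ndarray) -> np.ndarray:
    """Singular values of X^T Y only (fast path for permutation loops)."""
    n = Xv.shape[0]
    small, big = (Yv, Xv) if Yv.shape[1] <= Xv.shape[1] else (Xv, Yv)
    M = small.T @ (big @ big.T) @ small
    lam = np.linalg.eigvalsh((M + M.T) / 2.0)[::-1]
    kmax = min(Xv.shape[1], Yv.shape[1], n - 1)
    return np.sqrt(np.clip(lam[:kmax], 0.0, None))


def plsc_fit(X: PreprocessedBlock, Y: PreprocessedBlock) -> PLSCModel:
    """Fit the PLSC decomposition of two preprocessed blocks.

    Both blocks must have been through :func:`~structcov.preprocess.
    center_normalize` (so that X^T Y holds Pearson correlations) and
    share their participant order.
    """
    if not (X.is_normalized and Y.is_normalized):
        raise PLSCError("blocks must be center-normalized before plsc_fit")
    if not np.array_equal(X.participants, Y.participants):
        raise PLSCError("blocks have mismatched participant order")
    U, delta, V = cross_block_svd(X.values, Y.values)
    if delta.size == 0:
        raise PLSCError("cross-block matrix has no nonzero singular values")
    return PLSCModel(
        U=U,
        V=V,
        delta=delta,
        var_explained=delta**2 / np.sum(delta**2),
        Lx=X.values @ U,
        Ly=Y.values @ V,
        x_feature_ids=X.feature_ids,
        y_feature_ids=Y.feature_ids,
        participants=X.participants,
    )


def variance_explained(model: PLSCModel) -> np.ndarray:
    """Fraction of cross-block covariance per component: delta_k^2 / sum."""
    total = np.sum(model.delta**2)
    if total == 0:
        raise PLSCError("all singular values are zero")
    return model.delta**2 / total


def brain_scores(
    model: PLSCModel, X: PreprocessedBlock, Y: PreprocessedBlock
) -> tuple[np.ndarray, np.ndarray]:
    """Project (identically preprocessed) blocks onto the saliences.

    On the fitting data the covariance identity
    ``Lx[:, k] @ Ly[:, k] == delta_k`` holds.
    """
    if X.values.shape[1] != model.U.shape[0] or Y.values.shape[1] != model.V.shape[0]:
        raise PLSCError("block feature counts do not match the fitted model")
    return X.values @ model.U, Y.values @ model.V


__all__ = [
    "PLSCError",
    "PLSCModel",
    "RANK_TOL",
    "cross_block_svd",
    "cross_block_singular_values",
    "plsc_fit",
    "variance_explained",
    "brain_scores",
]
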