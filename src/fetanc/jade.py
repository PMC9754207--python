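"""JADE blind source separation and fetal-component selection.

Joint Approximate Diagonalization of Eigen-matrices: the observations are
whitened through an eigendecomposition of their covariance, a maximal set
of parallel fourth-order cumulant matrices is estimated, and an orthogonal
rotation jointly diagonalizing the set is found by Givens sweeps.  Sources
are recovered up to permutation, sign and scale — the usual BSS
indeterminacies — so the fetal component is chosen afterwards by
correlation against the stage-2 primary estimate and affinely re-fit to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateInputError(ValueError):
    """Covariance of the inputs is (numerically) rank deficient."""


@dataclass
class BSSResult:
    sources: np.ndarray        # [n_components, N]
    unmixing: np.ndarray       # [n_components, n_inputs], applied to centered X
    selected_index: int = None
    sign_scale: tuple = None   # (a, b): corrected = a * source + b


def _cumulant_matrices(z: np.ndarray) -> np.ndarray:
    """Parallel set of m(m+1)/2 fourth-order cumulant matrices of whitened z."""
    m, T = z.shape
    nbcm = m * (m + 1) // 2
    CM = np.zeros((nbcm, m, m))
    R = np.eye(m)
    s = 0
    for im in range(m):
        xim = z[im]
        Q = ((xim * xim) * z) @ z.T / T - R - 2.0 * np.outer(R[:, im], R[:, im])
        CM[s] = Q
        s += 1
        for jm in range(im):
            xjm = z[jm]
            Q = ((xim * xjm) * z) @ z.T / T \
                - np.outer(R[:, im], R[:, jm]) - np.outer(R[:, jm], R[:, im])
            CM[s] = np.sqrt(2.0) * Q
            s += 1
    return CM


def _joint_diagonalize(CM: np.ndarray, threshold: float = 1e-8, max_sweeps: int = 100):
    """Orthogonal V jointly diagonalizing the stack CM by Givens rotations."""
    _, m, _ = CM.shape
    V = np.eye(m)
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                g1 = CM[:, p, p] - CM[:, q, q]
                g2 = CM[:, p, q] + CM[:, q, p]
                ton = g1 @ g1 - g2 @ g2
                toff = 2.0 * (g1 @ g2)
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton * ton + toff * toff))
                if abs(np.sin(theta)) > threshold:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    G = np.array([[c, -s], [s, c]])
                    pair = [p, q]
                    CM[:, :, pair] = CM[:, :, pair] @ G
                    CM[:, pair, :] = np.einsum("ij,kjl->kil", G.T, CM[:, pair, :])
                    V[:, pair] = V[:, pair] @ G
        if not rotated:
            break
    return V


def jade_separate(X: np.ndarray, n_components: int = None) -> BSSResult:
    """Separate mixed rows of X into independent sources.

    X : (n_inputs, N) with N >> n_inputs.  Raises DegenerateInputError for
    rank-deficient covariance (e.g. duplicated rows).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, N = X.shape
    if m < 2:
        raise ValueError("need at least 2 input channels")
    n_components = n_components or m
    if n_components > m:
        raise ValueError("cannot extract more components than inputs")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / N
    evals, evecs = np.linalg.eigh(C)
    if evals[-1] <= 0 or evals[0] < 1e-10 * evals[-1]:
        raise DegenerateInputError("input covariance is rank deficient")
    order = np.argsort(evals)[::-1][:n_components]
    W = (evecs[:, order] / np.sqrt(evals[order])).T  # whitener
    Z = W @ Xc
    CM = _cumulant_matrices(Z)
    V = _joint_diagonalize(CM)
    B = V.T @ W
    return BSSResult(sources=B @ Xc, unmixing=B)


def select_fetal_component(bss: BSSResult, primary: np.ndarray) -> np.ndarray:
    """Pick the source best |correlated| with the primary estimate and
    re-fit its sign and scale by least squares against it."""
    primary = np.asarray(primary, dtype=float).ravel()
    if bss.sources.shape[0] < 1:
        raise ValueError("no sources to select from")
    best_i, best_c = 0, -1.0
    for i, s in enumerate(bss.sources):
        sd = s.std()
        c = abs(np.corrcoef(s, primary)[0, 1]) if sd > 0 and primary.std() > 0 else 0.0
        if c > best_c:
            best_i, best_c = i, c
    s = bss.sources[best_i]
    A = np.vstack([s, np.ones_like(s)]).T
    (a, b), *_ = np.linalg.lstsq(A, primary, rcond=None)
    bss.selected_index = best_i
    bss.sign_scale = (float(a), float(b))
    return a * s + b
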