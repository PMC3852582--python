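"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive (double loops, dense matrices,
projected gradient) and independent of the package's production paths.
"""

from __future__ import annotations

import numpy as np
from scipy.special import j1


def airy_amplitude_scalar(r: float, a: float, big_r: float) -> float:
    """Pointwise obscured-Airy amplitude, scalar evaluation."""

    def jinc(x):
        return 1.0 if x == 0 else 2.0 * j1(x) / x

    return (jinc(a * r) - big_r**2 * jinc(big_r * a * r)) / (1.0 - big_r**2)


def airy_array_bruteforce(a: float, big_r: float, hw: int) -> np.ndarray:
    """Unit-sum obscured-Airy array by an explicit scalar loop."""
    out = np.empty((2 * hw + 1, 2 * hw + 1))
    for i, u in enumerate(range(-hw, hw + 1)):
        for j, v in enumerate(range(-hw, hw + 1)):
            out[i, j] = airy_amplitude_scalar(np.hypot(u, v), a, big_r)
    return out / out.sum()


def convolve_reflect_bruteforce(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Double-loop correlation with symmetric (reflect) boundary handling."""
    rows, cols = image.shape
    hw = kernel.shape[0] // 2

    def reflect(i, n):
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i

    out = np.zeros_like(image, dtype=float)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for dr in range(-hw, hw + 1):
                for dc in range(-hw, hw + 1):
                    acc += kernel[dr + hw, dc + hw] * image[
                        reflect(r + dr, rows), reflect(c + dc, cols)
                    ]
            out[r, c] = acc
    return out


def similarity_graph_bruteforce(image: np.ndarray, neighborhood: str, sigma_floor=1e-12):
    """Exhaustive neighbor-pair construction of (sigma1, W, L)."""
    rows, cols = image.shape
    n = rows * cols
    offsets = [(0, 1), (1, 0)]
    if neighborhood == "8-connected":
        offsets += [(1, 1), (1, -1)]
    pairs = []
    for r in range(rows):
        for c in range(cols):
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    pairs.append((r * cols + c, r2 * cols + c2))
    diffs2 = [(image.flat[m] - image.flat[nn]) ** 2 for m, nn in pairs]
    sigma1 = max(float(np.mean(diffs2)), sigma_floor)
    W = np.zeros((n, n))
    for (m, nn), d2 in zip(pairs, diffs2):
        W[m, nn] = W[nn, m] = np.exp(-d2 / sigma1)
    L = np.diag(W.sum(axis=1)) - W
    return sigma1, W, L


def nonneg_quadratic_pgd(H: np.ndarray, b: np.ndarray, f0: np.ndarray,
                         max_steps: int = 100_000, tol: float = 1e-14) -> np.ndarray:
    """Projected gradient on 0.5 f^T H f + b^T f subject to f >= 0."""
    lip = float(np.linalg.eigvalsh(H).max())
    f = f0.copy()
    for _ in range(max_steps):
        f_new = np.maximum(0.0, f - (H @ f + b) / lip)
        if np.abs(f_new - f).max() < tol:
            return f_new
        f = f_new
    return f


def elastic_net_pgd(x: np.ndarray, atoms: np.ndarray, gamma1: float, gamma2: float,
                    max_steps: int = 1_000_000, tol: float = 1e-14):
    """Projected gradient reference for the nonnegative elastic-net code."""
    G = atoms.T @ atoms
    c = atoms.T @ x
    lip = 2.0 * float(np.linalg.eigvalsh(G).max()) + 2.0 * gamma2
    w = np.zeros(atoms.shape[1])
    for _ in range(max_steps):
        grad = 2.0 * (G @ w - c) + gamma1 + 2.0 * gamma2 * w
        w_new = np.maximum(0.0, w - grad / lip)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    r = x - atoms @ w
    return w, float(r @ r + gamma1 * w.sum() + gamma2 * w @ w)


def surrogate_pgd(atoms0: np.ndarray, A: np.ndarray, B: np.ndarray,
                  max_steps: int = 100_000, tol: float = 1e-12) -> np.ndarray:
    """Projected gradient on tr(Phi^T Phi A) - 2 tr(Phi^T B) over unit-ball columns."""
    lip = 2.0 * float(np.linalg.eigvalsh(A).max()) + 1e-12
    phi = atoms0.copy()
    for _ in range(max_steps):
        grad = 2.0 * phi @ A - 2.0 * B
        phi_new = phi - grad / lip
        norms = np.linalg.norm(phi_new, axis=0)
        scale = np.maximum(1.0, norms)
        phi_new = phi_new / scale
        if np.abs(phi_new - phi).max() < tol:
            return phi_new
        phi = phi_new
    return phi
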