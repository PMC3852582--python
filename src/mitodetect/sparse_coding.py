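"""Nonnegative L1/L2 mix-norm (elastic-net) sparse coding.

Each candidate's low-level feature x is decomposed over a dictionary Phi as
x = Phi w + r with w >= 0 by minimizing

    ||x - Phi w||_2^2 + gamma1 ||w||_1 + gamma2 ||w||_2^2 ,   w >= 0.

The L1 term induces sparsity; the squared-L2 (ridge) term makes the problem
strictly convex, so highly correlated atoms receive near-equal coefficients
(the "consistence" that keeps codes stable under redundant dictionaries).
The solver is cyclic coordinate descent with the exact nonnegative
per-coordinate minimizer, certified by its KKT violation on return.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dictionary",
    "CodingConfig",
    "SparseCode",
    "coding_objective",
    "sparse_code",
    "encode_set",
    "normalize_features",
]

ATOM_NORM_TOL = 1e-10


@dataclass
class Dictionary:
    """d x M atom matrix; every column phi_i satisfies ||phi_i||_2^2 <= 1."""

    atoms: np.ndarray
    atom_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D d x M array")
        norms2 = np.sum(self.atoms**2, axis=0)
        if np.any(norms2 > 1.0 + ATOM_NORM_TOL):
            raise ValueError("every atom must satisfy ||phi||_2^2 <= 1")
        if np.any(norms2 == 0.0):
            raise ValueError("dictionary contains an all-zero atom")
        if self.atom_labels is not None and len(self.atom_labels) != self.atoms.shape[1]:
            raise ValueError("atom_labels length must equal the atom count")

    @property
    def d(self) -> int:
        return self.atoms.shape[0]

    @property
    def M(self) -> int:
        return self.atoms.shape[1]

    def save(self, csv_path, json_path) -> None:
        np.savetxt(csv_path, self.atoms, delimiter=",")
        meta = {
            "d": self.d,
            "M": self.M,
            "atom_labels": self.atom_labels,
            "unit_normalized_inputs": True,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, csv_path, json_path=None) -> "Dictionary":
        atoms = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        labels = None
        if json_path is not None:
            with open(json_path) as fh:
                labels = json.load(fh).get("atom_labels")
        return cls(atoms=atoms, atom_labels=labels)


@dataclass(frozen=True)
class CodingConfig:
    """Elastic-net weights and solver schedule.

    gamma1/gamma2 are meaningful on unit-L2-normalized inputs; the paper-
    style working range is the logarithmic grid 1e-4 .. 1e-1.
    """

    gamma1: float = 0.1
    gamma2: float = 0.1
    max_iters: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1 and gamma2 must be nonnegative")
        if self.max_iters <= 0 or self.tol <= 0:
            raise ValueError("max_iters and tol must be positive")

    @staticmethod
    def default_gamma_grid() -> list[float]:
        return [1e-4, 1e-3, 1e-2, 1e-1]


@dataclass
class SparseCode:
    w: np.ndarray
    residual: np.ndarray
    objective: float
    kkt_violation: float
    converged: bool = True


def normalize_features(x: np.ndarray) -> np.ndarray:
    """L2-normalize a feature vector (zero vectors pass through)."""
    x = np.asarray(x, dtype=float).ravel()
    nrm = np.linalg.norm(x)
    return x / nrm if nrm > 0 else x


def coding_objective(
    x: np.ndarray, dictionary: Dictionary, w: np.ndarray, config: CodingConfig
) -> float:
    """||x - Phi w||_2^2 + gamma1 * sum(w) + gamma2 * sum(w^2) for w >= 0."""
    x = np.asarray(x, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("w must be elementwise nonnegative")
    if x.size != dictionary.d or w.size != dictionary.M:
        raise ValueError("dimension mismatch between x, dictionary and w")
    r = x - dictionary.atoms @ w
    return float(r @ r + config.gamma1 * w.sum() + config.gamma2 * w @ w)


def _kkt_violation(gram_w, corr, w, gamma1, gamma2):
    grad = 2.0 * (gram_w - corr) + gamma1 + 2.0 * gamma2 * w
    active = w > 0
    viol_active = np.abs(grad[active]).max() if np.any(active) else 0.0
    viol_inactive = np.maximum(0.0, -grad[~active]).max() if np.any(~active) else 0.0
    return float(max(viol_active, viol_inactive))


def sparse_code(
    x: np.ndarray,
    dictionary: Dictionary,
    config: CodingConfig | None = None,
    normalize: bool = True,
) -> SparseCode:
    """Solve the nonnegative elastic-net coding problem for one sample.

    Cyclic coordinate descent: each coordinate is set to its exact
    nonnegative minimizer

        w_j <- max(0, (2 phi_j^T r_j - gamma1) / (2 ||phi_j||^2 + 2 gamma2))

    (r_j the residual excluding atom j), sweeping atoms in ascending index
    until the KKT violation falls below ``config.tol``.  When ``normalize``
    is True the input is unit-L2-normalized first and the returned code
    refers to the normalized sample.
    """
    if config is None:
        config = CodingConfig()
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if x.size != dictionary.d:
        raise ValueError(f"x has length {x.size}, dictionary expects {dictionary.d}")
    if normalize:
        x = normalize_features(x)

    phi = dictionary.atoms
    gram = phi.T @ phi                      # M x M
    corr = phi.T @ x                        # M
    diag = np.diag(gram).copy()
    denom = 2.0 * diag + 2.0 * config.gamma2

    w = np.zeros(dictionary.M)
    gram_w = np.zeros(dictionary.M)         # gram @ w, maintained incrementally
    converged = False
    for _ in range(config.max_iters):
        for j in range(dictionary.M):
            if denom[j] <= 0:
                continue
            # 2 phi_j^T (x - Phi w + phi_j w_j) - gamma1, via the Gram matrix
            num = 2.0 * (corr[j] - gram_w[j] + diag[j] * w[j]) - config.gamma1
            wj_new = max(0.0, num / denom[j])
            delta = wj_new - w[j]
            if delta != 0.0:
                gram_w += gram[:, j] * delta
                w[j] = wj_new
        if _kkt_violation(gram_w, corr, w, config.gamma1, config.gamma2) < config.tol:
            converged = True
            break
    kkt = _kkt_violation(gram_w, corr, w, config.gamma1, config.gamma2)
    if not converged:
        warnings.warn(
            f"sparse_code did not reach KKT tolerance {config.tol:g} "
            f"within {config.max_iters} sweeps (violation {kkt:.3g})",
            RuntimeWarning,
        )
    residual = x - phi @ w
    objective = float(
        residual @ residual + config.gamma1 * w.sum() + config.gamma2 * w @ w
    )
    return SparseCode(
        w=w, residual=residual, objective=objective,
        kkt_violation=kkt, converged=converged,
    )


def encode_set(
    X,
    dictionary: Dictionary,
    config: CodingConfig | None = None,
    normalize: bool = True,
) -> list[SparseCode]:
    """Independent per-sample sparse coding, order preserved."""
    codes = []
    for i, x in enumerate(X):
        try:
            codes.append(sparse_code(x, dictionary, config, normalize=normalize))
        except ValueError as exc:
            raise ValueError(f"sample {i}: {exc}") from exc
    return codes
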