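"""Online dictionary learning for the nonnegative mix-norm coding model.

One sample is drawn uniformly at random per iteration; its nonnegative
elastic-net code over the current dictionary is computed, the sufficient
statistics A = sum w w^T and B = sum x w^T are accumulated, and one block
coordinate-descent pass updates the atoms under the constraint set
C = { Phi : ||phi_i||_2^2 <= 1 }.  The number of iterations T_max is
independent of the sample count.  After the loop every sample is re-encoded
over the final dictionary to produce the high-level feature set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .sparse_coding import CodingConfig, Dictionary, SparseCode, encode_set, normalize_features, sparse_code

__all__ = [
    "LearningState",
    "init_dictionary",
    "dictionary_update",
    "surrogate_objective",
    "learn_dictionary",
]

DEAD_ATOM_TOL = 1e-12


@dataclass
class LearningState:
    t: int
    T_max: int
    A: np.ndarray            # M x M accumulator of w w^T
    B: np.ndarray            # d x M accumulator of x w^T
    dictionary: Dictionary
    rng_seed: int
    history: list[tuple[int, int, float]] | None = None  # (t, sample index, objective)


def init_dictionary(X, M: int, seed: int = 0) -> Dictionary:
    """Seed the dictionary with M distinct unit-normalized training samples."""
    X = [np.asarray(x, dtype=float).ravel() for x in X]
    if M > len(X):
        raise ValueError(f"M={M} exceeds the number of samples ({len(X)})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(X), size=M, replace=False)
    atoms = np.stack([normalize_features(X[i]) for i in picks], axis=1)
    return Dictionary(atoms=atoms)


def surrogate_objective(atoms: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    """tr(Phi^T Phi A) - 2 tr(Phi^T B): the accumulated quadratic surrogate."""
    return float(np.trace(atoms.T @ atoms @ A) - 2.0 * np.trace(atoms.T @ B))


def dictionary_update(dictionary: Dictionary, A: np.ndarray, B: np.ndarray) -> Dictionary:
    """One block coordinate-descent pass over atoms.

    For each atom j with A_jj > 0:  u_j = phi_j + (b_j - Phi a_j) / A_jj,
    then phi_j = u_j / max(1, ||u_j||_2) — the exact constrained minimizer
    of the surrogate in atom j.  Atoms with A_jj ~ 0 (never activated) are
    left unchanged to keep learning deterministic.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != (dictionary.M, dictionary.M) or B.shape != (dictionary.d, dictionary.M):
        raise ValueError("accumulator dimensions do not match the dictionary")
    atoms = dictionary.atoms.copy()
    for j in range(atoms.shape[1]):
        if A[j, j] < DEAD_ATOM_TOL:
            continue
        u = atoms[:, j] + (B[:, j] - atoms @ A[:, j]) / A[j, j]
        atoms[:, j] = u / max(1.0, float(np.linalg.norm(u)))
    return Dictionary(atoms=atoms, atom_labels=dictionary.atom_labels)


def learn_dictionary(
    X,
    M: int,
    coding_config: CodingConfig | None = None,
    T_max: int | None = None,
    seed: int = 0,
    normalize: bool = True,
    history_out: list | None = None,
) -> tuple[Dictionary, list[SparseCode]]:
    """Online alternation of sparse coding and dictionary updating.

    Returns the learned dictionary and the codes of all samples over it.
    Fully deterministic given (X, M, config, T_max, seed); T_max defaults
    to 10 * len(X).
    """
    if coding_config is None:
        coding_config = CodingConfig()
    X = [np.asarray(x, dtype=float).ravel() for x in X]
    if M < 2:
        raise ValueError("M must be at least 2")
    if M > len(X):
        raise ValueError(f"M={M} exceeds the number of samples ({len(X)})")
    if normalize:
        X = [normalize_features(x) for x in X]
    if T_max is None:
        T_max = 10 * len(X)
    if T_max < 1:
        raise ValueError("T_max must be >= 1")

    dictionary = init_dictionary(X, M, seed=seed)
    rng = np.random.default_rng(seed)
    A = np.zeros((M, M))
    B = np.zeros((dictionary.d, M))

    for t in range(1, T_max + 1):
        idx = int(rng.integers(0, len(X)))
        try:
            code = sparse_code(X[idx], dictionary, coding_config, normalize=False)
        except ValueError as exc:
            raise ValueError(f"iteration {t} (sample {idx}): {exc}") from exc
        A += np.outer(code.w, code.w)
        B += np.outer(X[idx], code.w)
        dictionary = dictionary_update(dictionary, A, B)
        if history_out is not None:
            history_out.append((t, idx, code.objective))

    codes = encode_set(X, dictionary, coding_config, normalize=False)
    return dictionary, codes


def write_training_log(history, path) -> None:
    """CSV log of (iteration, sampled index, sparse-coding objective)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "sample_index", "objective"])
        writer.writerows(history)
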