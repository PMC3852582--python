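"""Synthetic phase-contrast frames and labeled patch datasets.

The frame generator runs the delta-minus-airy forward model in both
directions: normal cells contribute +P f_normal and mitotic cells
-P f_mitotic, so the mitosis-enhanced restoration (which explains the
inverted frame with a nonnegative phase image) is exercised by exactly the
mechanism it inverts.  Cells are disks with cosine-tapered phase profiles
so halos render smoothly through the kernel; ground-truth masks and
bounding boxes accompany every frame.

The patch generator emulates the class-conditional sparse structure the
coding model assumes: mitotic samples are nonnegative k-sparse combinations
of mitotic-tagged atoms, nonmitotic samples of the remaining atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .candidates import Annotation
from .detection import MITOTIC, NONMITOTIC, LabeledFeature
from .imaging_model import PhaseContrastPSF, apply_psf, make_psf
from .sparse_coding import Dictionary, normalize_features

__all__ = [
    "SimulationParams",
    "simulate_frame",
    "simulate_sequence",
    "make_class_dictionary",
    "simulate_patch_dataset",
]

MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SimulationParams:
    frame_shape: tuple[int, int] = (96, 96)
    n_normal_cells: int = 8
    n_mitotic_cells: int = 5
    cell_radius_range: tuple[float, float] = (3.0, 5.0)
    amplitude_range: tuple[float, float] = (0.6, 1.0)
    background_level: float = 0.5
    noise_sigma: float = 0.01
    seed: int = 0
    psf_outer_radius: float = 2.0
    psf_obscuration_ratio: float = 0.5
    psf_half_width: int = 5

    def __post_init__(self) -> None:
        if self.n_normal_cells < 0 or self.n_mitotic_cells < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.cell_radius_range[0] <= 0 or self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise ValueError("cell_radius_range must be positive and ordered")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[0] > self.amplitude_range[1]:
            raise ValueError("amplitude_range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    def make_psf(self) -> PhaseContrastPSF:
        return make_psf(self.psf_outer_radius, self.psf_obscuration_ratio, self.psf_half_width)


def _place_cells(rng, params: SimulationParams, n_cells: int):
    """Rejection-sample (row, col, radius, amplitude) for non-overlapping disks."""
    rows, cols = params.frame_shape
    placed = []
    r_lo, r_hi = params.cell_radius_range
    a_lo, a_hi = params.amplitude_range
    for _ in range(n_cells):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            radius = float(rng.uniform(r_lo, r_hi))
            margin = int(np.ceil(radius))
            if rows - margin <= margin or cols - margin <= margin:
                raise ValueError("frame too small for the requested cell radii")
            r = float(rng.uniform(margin, rows - margin))
            c = float(rng.uniform(margin, cols - margin))
            if all(np.hypot(r - pr, c - pc) >= radius + prad for pr, pc, prad, _ in placed):
                placed.append((r, c, radius, float(rng.uniform(a_lo, a_hi))))
                break
        else:
            raise ValueError(
                f"could not place {n_cells} cells after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return placed


def _render_cells(shape, cells) -> np.ndarray:
    """Sum of cosine-tapered disk phase profiles."""
    img = np.zeros(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c, radius, amp in cells:
        dist = np.hypot(rr - r, cc - c)
        inside = dist <= radius
        img[inside] += amp * 0.5 * (1.0 + np.cos(np.pi * dist[inside] / radius))
    return img


def _cell_bbox(r, c, radius, shape) -> tuple[int, int, int, int]:
    r0 = max(int(np.floor(r - radius)), 0)
    c0 = max(int(np.floor(c - radius)), 0)
    r1 = min(int(np.ceil(r + radius)) + 1, shape[0])
    c1 = min(int(np.ceil(c + radius)) + 1, shape[1])
    return r0, c0, r1, c1


def simulate_frame(
    params: SimulationParams, frame_id: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[Annotation]]:
    """One synthetic frame with ground-truth phase images and annotations.

    observed = P f_normal - P f_mitotic + background + N(0, noise_sigma^2).
    Deterministic given params.seed (the frame_id does not enter the RNG;
    use :func:`simulate_sequence` for multi-frame sequences).
    """
    rng = np.random.default_rng(params.seed)
    psf = params.make_psf()
    cells = _place_cells(rng, params, params.n_normal_cells + params.n_mitotic_cells)
    normal_cells = cells[: params.n_normal_cells]
    mitotic_cells = cells[params.n_normal_cells :]

    f_normal = _render_cells(params.frame_shape, normal_cells)
    f_mitotic = _render_cells(params.frame_shape, mitotic_cells)
    observed = (
        apply_psf(f_normal, psf)
        - apply_psf(f_mitotic, psf)
        + params.background_level
        + rng.normal(0.0, params.noise_sigma, params.frame_shape)
    )

    annotations = [
        Annotation(frame_id=frame_id, bbox=_cell_bbox(r, c, rad, params.frame_shape), label=NONMITOTIC)
        for r, c, rad, _ in normal_cells
    ] + [
        Annotation(frame_id=frame_id, bbox=_cell_bbox(r, c, rad, params.frame_shape), label=MITOTIC)
        for r, c, rad, _ in mitotic_cells
    ]
    return observed, f_normal, f_mitotic, annotations


def simulate_sequence(params: SimulationParams, n_frames: int):
    """Independent frames with per-frame seeds params.seed + frame_id."""
    out = []
    for fid in range(n_frames):
        frame_params = replace(params, seed=params.seed + fid)
        out.append(simulate_frame(frame_params, frame_id=fid))
    return out


def make_class_dictionary(
    n_mitotic_atoms: int = 8,
    n_nonmitotic_atoms: int = 8,
    d: int = 625,
    seed: int = 0,
) -> Dictionary:
    """Random unit atoms tagged by class, for patch-dataset generation."""
    rng = np.random.default_rng(seed)
    atoms = rng.normal(size=(d, n_mitotic_atoms + n_nonmitotic_atoms))
    atoms /= np.linalg.norm(atoms, axis=0)
    labels = [MITOTIC] * n_mitotic_atoms + [NONMITOTIC] * n_nonmitotic_atoms
    return Dictionary(atoms=atoms, atom_labels=labels)


def simulate_patch_dataset(
    true_dictionary: Dictionary,
    n_pos: int = 200,
    n_neg: int = 200,
    sparsity_k: int = 2,
    coeff_range: tuple[float, float] = (0.5, 1.5),
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> list[LabeledFeature]:
    """Class-conditional k-sparse samples over a labeled dictionary.

    Positives are nonnegative ``sparsity_k``-sparse combinations of
    mitotic-tagged atoms plus Gaussian noise, negatives likewise from
    nonmitotic-tagged atoms; outputs are unit-L2-normalized.
    """
    if true_dictionary.atom_labels is None:
        raise ValueError("true_dictionary must carry atom class labels")
    labels = np.array(true_dictionary.atom_labels)
    pos_idx = np.flatnonzero(labels == MITOTIC)
    neg_idx = np.flatnonzero(labels == NONMITOTIC)
    for name, idx in ((MITOTIC, pos_idx), (NONMITOTIC, neg_idx)):
        if sparsity_k > idx.size:
            raise ValueError(f"sparsity_k={sparsity_k} exceeds {name} atom count {idx.size}")

    rng = np.random.default_rng(seed)
    atoms = true_dictionary.atoms
    out: list[LabeledFeature] = []
    specs = [(MITOTIC, pos_idx)] * n_pos + [(NONMITOTIC, neg_idx)] * n_neg
    for sid, (label, idx) in enumerate(specs):
        chosen = rng.choice(idx, size=sparsity_k, replace=False)
        coeffs = rng.uniform(coeff_range[0], coeff_range[1], size=sparsity_k)
        x = atoms[:, chosen] @ coeffs
        if noise_sigma > 0:
            x = x + rng.normal(0.0, noise_sigma, size=x.shape)
        out.append(LabeledFeature(sample_id=sid, vector=normalize_features(x), label=label))
    return out
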