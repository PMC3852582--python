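"""Mitotic candidate extraction and candidate/annotation matching.

The mitosis-enhanced restored image is near-zero in the background and
positive inside mitotic regions, so candidates are simply its connected
components above a (relative) threshold.  Each surviving component yields a
fixed-size appearance patch cropped from the original frame — the restored
image localizes, the original frame carries the visual pattern the
classifier sees.

Bounding boxes are 0-based half-open (row_min, col_min, row_max, col_max)
everywhere, including CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage import measure, transform

__all__ = [
    "CandidateRegion",
    "Annotation",
    "extract_candidates",
    "match_candidates",
    "read_annotations_csv",
    "write_annotations_csv",
    "write_candidates_csv",
    "read_candidates_csv",
    "write_patch_stack",
]


@dataclass
class CandidateRegion:
    frame_id: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area: int
    patch: np.ndarray


@dataclass(frozen=True)
class Annotation:
    frame_id: int
    bbox: tuple[int, int, int, int]
    label: str  # "mitotic" | "nonmitotic"


def _square_bbox(bbox, shape, min_side: int = 1):
    """Expand a half-open bbox to a square, clamped inside the frame."""
    r0, c0, r1, c1 = bbox
    side = max(r1 - r0, c1 - c0, min_side)
    rows, cols = shape
    side = min(side, rows, cols)
    rc = (r0 + r1) / 2.0
    cc = (c0 + c1) / 2.0
    r0n = int(round(rc - side / 2.0))
    c0n = int(round(cc - side / 2.0))
    r0n = min(max(r0n, 0), rows - side)
    c0n = min(max(c0n, 0), cols - side)
    return r0n, c0n, r0n + side, c0n + side


def extract_candidates(
    restored,
    original: np.ndarray,
    min_area: int = 10,
    threshold_frac: float = 0.1,
    patch_size: int = 25,
    frame_id: int = 0,
    from_original: bool = True,
) -> list[CandidateRegion]:
    """Connected components of the restored image -> candidate patches.

    Binarizes ``restored > threshold_frac * max(restored)``, labels
    8-connected components, drops those smaller than ``min_area`` pixels,
    and crops each survivor's square-expanded bounding box from the
    original frame (or from the restored image when ``from_original`` is
    False), resized to ``patch_size`` x ``patch_size`` bilinearly.
    """
    restored = np.asarray(getattr(restored, "restored", restored), dtype=float)
    original = np.asarray(original, dtype=float)
    if restored.shape != original.shape:
        raise ValueError(
            f"restored {restored.shape} and original {original.shape} shapes differ"
        )
    peak = restored.max()
    if peak <= 0:
        return []
    mask = restored > threshold_frac * peak
    labeled = measure.label(mask, connectivity=2)
    source = original if from_original else restored

    out: list[CandidateRegion] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        sq = _square_bbox((r0, c0, r1, c1), restored.shape)
        crop = source[sq[0] : sq[2], sq[1] : sq[3]]
        patch = transform.resize(
            crop, (patch_size, patch_size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        out.append(
            CandidateRegion(
                frame_id=int(frame_id),
                bbox=(r0, c0, r1, c1),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area=int(region.area),
                patch=np.asarray(patch, dtype=float),
            )
        )
    out.sort(key=lambda c: (c.frame_id, c.bbox[0], c.bbox[1]))
    return out


def match_candidates(
    candidates: list[CandidateRegion], annotations: list[Annotation]
) -> tuple[int, int, int]:
    """Greedy centroid-in-box matching against mitotic annotations.

    Candidates are visited in (frame, row, col) order; each claims the first
    unmatched mitotic annotation (same order) whose half-open bbox contains
    its centroid.  Returns (TP, FP, FN): unmatched candidates are false
    positives, unmatched mitotic annotations false negatives.
    """
    mitotic = sorted(
        (a for a in annotations if a.label == "mitotic"),
        key=lambda a: (a.frame_id, a.bbox[0], a.bbox[1]),
    )
    cands = sorted(candidates, key=lambda c: (c.frame_id, c.bbox[0], c.bbox[1]))
    taken = [False] * len(mitotic)
    tp = 0
    for cand in cands:
        r, c = cand.centroid
        for i, ann in enumerate(mitotic):
            if taken[i] or ann.frame_id != cand.frame_id:
                continue
            r0, c0, r1, c1 = ann.bbox
            if r0 <= r < r1 and c0 <= c < c1:
                taken[i] = True
                tp += 1
                break
    fp = len(cands) - tp
    fn = len(mitotic) - tp
    return tp, fp, fn


_ANN_COLS = ["frame_id", "row_min", "col_min", "row_max", "col_max", "label"]


def write_annotations_csv(annotations: list[Annotation], path) -> None:
    rows = [
        {"frame_id": a.frame_id, "row_min": a.bbox[0], "col_min": a.bbox[1],
         "row_max": a.bbox[2], "col_max": a.bbox[3], "label": a.label}
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, index=False)


def read_annotations_csv(path) -> list[Annotation]:
    df = pd.read_csv(path)
    return [
        Annotation(
            frame_id=int(r.frame_id),
            bbox=(int(r.row_min), int(r.col_min), int(r.row_max), int(r.col_max)),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def write_candidates_csv(candidates: list[CandidateRegion], path) -> None:
    rows = [
        {"frame_id": c.frame_id, "row_min": c.bbox[0], "col_min": c.bbox[1],
         "row_max": c.bbox[2], "col_max": c.bbox[3], "area": c.area,
         "centroid_row": c.centroid[0], "centroid_col": c.centroid[1]}
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=_ANN_COLS[:-1] + ["area", "centroid_row", "centroid_col"],
    ).to_csv(path, index=False)


def read_candidates_csv(path, patch_size: int = 25) -> list[CandidateRegion]:
    df = pd.read_csv(path)
    empty = np.zeros((patch_size, patch_size))
    return [
        CandidateRegion(
            frame_id=int(r.frame_id),
            bbox=(int(r.row_min), int(r.col_min), int(r.row_max), int(r.col_max)),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            area=int(r.area),
            patch=empty,
        )
        for r in df.itertuples()
    ]


def write_patch_stack(candidates: list[CandidateRegion], tiff_path, index_csv_path) -> None:
    """Write candidate patches as a multi-page TIFF plus an index CSV."""
    if candidates:
        stack = np.stack([c.patch for c in candidates]).astype(np.float32)
        tifffile.imwrite(tiff_path, stack)
    write_candidates_csv(candidates, index_csv_path)
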