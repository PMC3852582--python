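import numpy as np
import pytest

from mitodetect.candidates import (
    Annotation,
    CandidateRegion,
    extract_candidates,
    match_candidates,
    read_annotations_csv,
    read_candidates_csv,
    write_annotations_csv,
    write_candidates_csv,
)


def _blocks_image(shape=(64, 64)):
    """Three 5x5 unit blocks plus one 2x2 block at known positions."""
    img = np.zeros(shape)
    corners = [(5, 5), (20, 40), (50, 10)]
    for r, c in corners:
        img[r : r + 5, c : c + 5] = 1.0
    img[40, 55] = img[40, 56] = img[41, 55] = img[41, 56] = 1.0
    centers = [(r + 2.0, c + 2.0) for r, c in corners]
    return img, centers


class TestExtractCandidates:
    def test_zero_restored_gives_empty_list(self):
        assert extract_candidates(np.zeros((32, 32)), np.zeros((32, 32))) == []

    def test_blocks_extracted_with_known_centroids(self, rng):
        restored, centers = _blocks_image()
        original = rng.normal(size=restored.shape)
        cands = extract_candidates(restored, original, min_area=9, threshold_frac=0.0)
        assert len(cands) == 3
        got = sorted(c.centroid for c in cands)
        for (gr, gc), (er, ec) in zip(got, sorted(centers)):
            assert gr == pytest.approx(er)
            assert gc == pytest.approx(ec)
        for c in cands:
            assert c.patch.shape == (25, 25)
            assert np.all(np.isfinite(c.patch))

    def test_patch_size_respected(self, rng):
        restored, _ = _blocks_image()
        cands = extract_candidates(
            restored, rng.normal(size=restored.shape), min_area=9, patch_size=25
        )
        assert all(c.patch.shape == (25, 25) for c in cands)

    def test_count_monotone_in_min_area(self, rng):
        restored = np.maximum(rng.normal(size=(48, 48)), 0.0)
        original = rng.normal(size=(48, 48))
        counts_area = [
            len(extract_candidates(restored, original, min_area=a, threshold_frac=0.1))
            for a in (1, 3, 6, 12, 24)
        ]
        assert counts_area == sorted(counts_area, reverse=True)

    def test_total_candidate_area_monotone_in_threshold(self, rng):
        # raising the threshold can SPLIT one merged component into several,
        # so the count is not monotone — but the retained pixel mass is
        restored = np.maximum(rng.normal(size=(48, 48)), 0.0)
        original = rng.normal(size=(48, 48))
        areas = [
            sum(c.area for c in
                extract_candidates(restored, original, min_area=1, threshold_frac=t))
            for t in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert areas == sorted(areas, reverse=True)

    def test_bboxes_inside_frame(self, rng):
        restored = np.maximum(rng.normal(size=(40, 30)), 0.0)
        for c in extract_candidates(restored, restored, min_area=1, threshold_frac=0.3):
            r0, c0, r1, c1 = c.bbox
            assert 0 <= r0 < r1 <= 40
            assert 0 <= c0 < c1 <= 30

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_candidates(np.zeros((8, 8)), np.zeros((9, 8)))

    def test_accepts_restoration_result(self, small_psf):
        from mitodetect.restoration import restore

        g = np.zeros((16, 16))
        res = restore(g, small_psf)
        assert extract_candidates(res, g) == []


class TestMatchCandidates:
    @staticmethod
    def _candidate(frame_id, centroid):
        r, c = centroid
        return CandidateRegion(
            frame_id=frame_id,
            bbox=(int(r) - 1, int(c) - 1, int(r) + 2, int(c) + 2),
            centroid=centroid,
            area=9,
            patch=np.zeros((25, 25)),
        )

    def test_empty_inputs(self):
        assert match_candidates([], []) == (0, 0, 0)

    def test_single_direct_match(self):
        cand = self._candidate(0, (10.0, 10.0))
        ann = Annotation(frame_id=0, bbox=(8, 8, 13, 13), label="mitotic")
        assert match_candidates([cand], [ann]) == (1, 0, 0)

    def test_candidate_stage_operating_point(self):
        # 5 candidates, 2 annotations, exactly 2 centroid-inside matches:
        # recall 1.0 and precision 0.4, the candidate-stage regime
        anns = [
            Annotation(frame_id=0, bbox=(0, 0, 10, 10), label="mitotic"),
            Annotation(frame_id=0, bbox=(30, 30, 40, 40), label="mitotic"),
        ]
        cands = [
            self._candidate(0, (5.0, 5.0)),     # inside ann 1
            self._candidate(0, (35.0, 35.0)),   # inside ann 2
            self._candidate(0, (20.0, 20.0)),
            self._candidate(0, (50.0, 5.0)),
            self._candidate(0, (5.0, 50.0)),
        ]
        tp, fp, fn = match_candidates(cands, anns)
        assert (tp, fp, fn) == (2, 3, 0)
        assert tp / (tp + fn) == 1.0
        assert tp / (tp + fp) == pytest.approx(0.4)

    def test_annotation_claimed_at_most_once(self):
        ann = Annotation(frame_id=0, bbox=(0, 0, 10, 10), label="mitotic")
        cands = [self._candidate(0, (4.0, 4.0)), self._candidate(0, (6.0, 6.0))]
        assert match_candidates(cands, [ann]) == (1, 1, 0)

    def test_nonmitotic_annotations_ignored(self):
        ann = Annotation(frame_id=0, bbox=(0, 0, 10, 10), label="nonmitotic")
        assert match_candidates([self._candidate(0, (5.0, 5.0))], [ann]) == (0, 1, 0)

    def test_count_identities(self, rng):
        anns = [
            Annotation(frame_id=0, bbox=(r, c, r + 8, c + 8), label="mitotic")
            for r, c in rng.integers(0, 80, size=(6, 2))
        ]
        cands = [
            self._candidate(0, (float(r), float(c)))
            for r, c in rng.integers(0, 90, size=(10, 2))
        ]
        tp, fp, fn = match_candidates(cands, anns)
        assert tp + fn == len(anns)
        assert tp + fp == len(cands)


class TestCSVIO:
    def test_annotation_round_trip(self, tmp_path):
        anns = [
            Annotation(frame_id=0, bbox=(1, 2, 10, 12), label="mitotic"),
            Annotation(frame_id=3, bbox=(4, 5, 9, 9), label="nonmitotic"),
        ]
        path = tmp_path / "ann.csv"
        write_annotations_csv(anns, path)
        assert read_annotations_csv(path) == anns

    def test_candidate_round_trip(self, tmp_path):
        cands = [
            CandidateRegion(frame_id=1, bbox=(2, 3, 9, 10), centroid=(5.5, 6.25),
                            area=42, patch=np.zeros((25, 25)))
        ]
        path = tmp_path / "cand.csv"
        write_candidates_csv(cands, path)
        loaded = read_candidates_csv(path)
        assert loaded[0].frame_id == 1
        assert loaded[0].bbox == (2, 3, 9, 10)
        assert loaded[0].centroid == (5.5, 6.25)
        assert loaded[0].area == 42
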