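# mitodetect

Detection of mitotic cells in time-lapse **phase-contrast microscopy**,
built for quantifying proliferation in label-free stem-cell cultures.
Mitotic cells round up and appear as drastically intensified bright halo
blobs; this package finds them without cell tracking or temporal inference
models, using an imaging-model-based restoration to propose candidates and
a nonnegative mix-norm sparse representation to classify them.

## Method

**1. Candidate extraction by restoration.** Under positive phase contrast
the point spread function is well approximated by a delta minus an obscured
Airy pattern, `PSF(u,v) = δ(u,v) − airy(√(u²+v²))`, discretized as the
linear operator **P**. The artifact-free image f ≥ 0 is recovered by
minimizing

```
O(f) = ‖P f ∓ g‖₂² + w_smooth fᵀ L f + w_sparse ‖D f‖₁ ,  f ≥ 0
```

where g is the observed frame, L the similarity-weighted graph Laplacian
(weights `exp(−(g_m−g_n)²/σ₁)` between neighboring pixels), and D an
iteratively reweighted diagonal (`D_kk = 1/(|f_k|+ε)`). The `+g` sign
selectively enhances mitotic regions: a mitotic blob in the inverted frame
looks like a normal cell in the original, so explaining −g with a
nonnegative phase image isolates mitosis. The solver is an iteratively
reweighted **nonnegative multiplicative update** (monotone, matrix-free).
Connected components of the restored image become candidate regions,
cropped from the original frame as 25×25 patches.

**2. Sparse representation.** Each candidate's pixel-intensity feature x is
coded over a learned dictionary Φ (atoms ‖φᵢ‖₂² ≤ 1) by the nonnegative
elastic net

```
w* = argmin_{w≥0} ‖x − Φ w‖₂² + γ₁‖w‖₁ + γ₂‖w‖₂²
```

solved by coordinate descent with KKT certificates. The ridge term makes
the problem strictly convex so correlated atoms share weight (stable codes
under redundant dictionaries). The dictionary is learned **online**: one
sample drawn per iteration, coded, accumulated into sufficient statistics
A = Σ w wᵀ, B = Σ x wᵀ, followed by one block coordinate-descent pass over
atoms.

**3. Detection.** A linear SVM on the code vectors w separates mitotic from
nonmitotic candidates; performance is reported as Precision, Recall, F1 and
Accuracy.

A synthetic phase-contrast simulator (cosine-tapered disk cells rendered
through the same δ−airy forward model, with ground-truth masks and boxes)
exercises every stage at desk scale.

## Worked example

```python
import numpy as np
from mitodetect import (
    SimulationParams, simulate_sequence, restore, extract_candidates,
    match_candidates, make_class_dictionary, simulate_patch_dataset,
    learn_dictionary, encode_set, train_classifier, evaluate, CodingConfig,
)

params = SimulationParams(seed=0)          # 96x96 frames, 8 normal + 5 mitotic cells
psf = params.make_psf()
tp = fp = fn = 0
for observed, _, _, annotations in simulate_sequence(params, 10):
    result = restore(observed, psf, sign="mitotic")
    cands = extract_candidates(result, observed, frame_id=annotations[0].frame_id)
    t, f, n = match_candidates(cands, annotations)
    tp, fp, fn = tp + t, fp + f, fn + n
print(f"candidate stage: recall {tp/(tp+fn):.2f}, precision {tp/(tp+fp):.2f}")

true_dict = make_class_dictionary(8, 8, d=625, seed=0)
train = simulate_patch_dataset(true_dict, 200, 200, seed=1)
test = simulate_patch_dataset(true_dict, 200, 200, seed=2)
cfg = CodingConfig(gamma1=0.1, gamma2=0.1)
dictionary, train_codes = learn_dictionary([s.vector for s in train], M=16,
                                           coding_config=cfg, seed=0)
model = train_classifier(train_codes, [s.label for s in train])
metrics = evaluate(model.predict(encode_set([s.vector for s in test], dictionary, cfg)),
                   [s.label for s in test])
print(f"detection: precision {metrics.precision:.3f}, recall {metrics.recall:.3f}, "
      f"F1 {metrics.f1:.3f}, accuracy {metrics.accuracy:.3f}")
```

prints

```
candidate stage: recall 1.00, precision 0.44
detection: precision 1.000, recall 1.000, F1 1.000, accuracy 1.000
```

The candidate stage finds every planted mitotic cell (recall 1.00) while
keeping less than half of its proposals true (precision 0.44) — the
intended high-recall operating point, since the SVM stage filters the rest.
On the synthetic patch regime the codes separate the classes perfectly.

## Command line

`mitodetect` exposes each stage (`simulate`, `restore`, `candidates`,
`learn-dict`, `encode`, `train`, `evaluate`) plus a `detect` command that
chains restoration → candidates → coding → prediction over a directory of
frames. All commands take `--config config.yaml` (see
`mitodetect.config.default_config()` for the schema) and `--seed`.

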