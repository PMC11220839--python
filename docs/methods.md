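# Methods

This note documents the models, algorithms and numerical choices behind
`mapseg`, in the spirit of a methods section: what is computed, under which
assumptions, and what the desk-scale experiments do and do not show.

## Grid model and I/O

Density lives on a periodic unit-cell grid: `values[i, j, k]` sits at
fractional coordinate `(i/nx, j/ny, k/nz)`, with array axis 0 along the
crystallographic *a* axis. CCP4/MRC files written with any header axis
order are permuted to this convention on read (gemmi performs the header
interpretation); all tiling and masking code can therefore assume one
layout. Masks are serialized as real-valued 0/1 volumes rather than a
packed mask dialect, for maximal downstream compatibility. Grid dimensions
for a target resolution `d` are the smallest 2,3,5-smooth integers giving a
spacing of at most `d/2` on every axis (Shannon sampling of a band-limited
map).

Symmetry operators are read from the map header when present, otherwise P1
is assumed. The solvent-content expectation over the asymmetric unit is
defined as the full-cell mean of the symmetry-averaged grid; applying
operators on voxel indices requires grids sampled compatibly with the space
group, which holds for the P1 synthesis used throughout.

## Ground-truth masks

A voxel is protein iff its periodic (minimum-image) distance to some atom
centre is at most that atom's van der Waals radius plus a configurable
`shrink` margin (default 0). Radii come from a packaged JSON table (Bondi
main-group values, Alvarez metals); the table is swappable per call and
unknown elements receive a configurable default (1.8 Å). Small solvent
islands — 6-connected components under periodic wrap-around smaller than
`min_island_fraction` of the cell — are reassigned to protein, because
density modification treats enclosed pockets as part of the molecular
envelope. Island removal defaults to off in the library and to a documented
0.001 of cell voxels in the CLI; the synthetic generator uses 0.001.
6-connectivity was chosen as the conservative standard; the periodic merge
is a union-find pass over the box-label faces, verified in the tests
against a brute-force periodic BFS.

## Synthetic phasing maps

The generator emulates the statistical structure of experimentally phased
(SAD-style) maps:

* **Structure.** A pseudo-protein grows as random-walk chains of ~C-like
  atoms (radius 2.0 Å, step 2.8 Å, a mild centripetal pull keeping chains
  globular) in a cubic P1 cell. The atom count is calibrated iteratively so
  the true mask's solvent fraction lands within 0.05 (inner margin 0.03) of
  the requested target; an explicit atom count bypasses calibration.
* **Density.** Unit Gaussians (σ = 1.0 Å; band-limiting dominates the
  appearance, so the exact width is not critical) are summed periodically,
  Fourier-transformed, and truncated at `1/d_high`.
* **Phase error.** Every non-DC coefficient's phase is rotated by a draw
  from a von Mises distribution whose concentration is solved numerically
  (Brent on a stable quadrature of E|θ|) so that the *mean absolute wrapped
  error equals the requested value in degrees* — the same unit in which
  phasing quality is conventionally reported; ≥ 89.9° switches to uniform
  phases. The perturbation field is constructed antisymmetric
  (θ(−h) = −θ(h), zero on self-conjugate points) so the spectrum stays
  exactly Hermitian and the map exactly real; the calibration tests recover
  the requested error to ~0.3° and the tests assert 3°.
* **Amplitude noise.** Amplitudes are scaled by `1 + f·N(0,1)` with a
  symmetric factor field; negative factors are allowed (they act as phase
  flips), matching the simple multiplicative model.
* Maps are standardized to zero mean and unit variance; masks are exact.

Default dataset ranges (cell 48–64 Å, solvent 0.35–0.70, phase error
10–60°, noise 0.05–0.15, d = 2 Å) emulate a realistic spread from good to
mediocre phasing over the common crystal solvent range. What the generator
does *not* reproduce: non-P1 symmetry, resolution-dependent error profiles,
solvent disorder, series-termination ripples and model bias — so passing
tests demonstrate correct mechanics and learnability of the synthetic
signal, not performance on deposited crystallographic data.

## Windowing and augmentation

Training windows (edge 48) are cut at uniformly random origins with
periodic wrap; overlaps are intentionally allowed and windows are re-drawn
each epoch from epoch-indexed seeds. Augmentation flips a random subset of
the three axes and applies one of seven equally likely 90° rotations
(identity or ±90° about one axis) identically to density and labels; a
config flag extends to uniform quarter-turn counts, which together with
flips spans the full cubic group. At inference the map is tiled without
overlap, plus one edge-aligned window per axis when a dimension is not
divisible by 48; reassembly averages probabilities where tiles overlap
(symmetric and order-independent — the natural choice where no rule is
canonical). Grids smaller than the window on any axis are rejected with a
regridding hint.

## Network and training

Architecture (window `w` divisible by 8): four encoder blocks of two 3×3×3
convolutions, each followed by batch normalization and ReLU; 2×2×2 max
pooling after the first three blocks; filters start at `base_filters`
(default 24) and double per block. Three decoder blocks: stride-2
transposed 3×3×3 convolution halving the filters and doubling the spatial
dims, concatenation with the same-resolution encoder output (the skip
connections), then one 3×3×3 convolution + BN + ReLU. A final 1×1×1
convolution maps to two classes. Transposed convolutions carry no BN/ReLU
of their own (a flag can add them); convolutions keep their bias terms even
before BN (redundant but conventional). The default configuration has
3,285,002 trainable parameters (BN scale/shift counted, running statistics
not), verified in the tests against an independent closed-form per-layer
sum.

The engine is a small numpy/BLAS implementation with explicit
forward/backward passes: convolutions are evaluated as 27 shifted matrix
products (so the arithmetic runs through BLAS), and every layer's gradient
is verified against central finite differences in the test suite. Weights
use He-normal fan-in initialization from a seeded generator. The loss is
per-voxel sparse categorical cross-entropy; the optimizer is Adam
(default learning rate 1e-4, batch size 32, 100 epochs for full-scale
configuration). The epoch with the best validation voxel accuracy is
restored into the returned model, and checkpoints (`.npz` weights +
embedded architecture config) round-trip bit-exactly.

Input normalization is the parent map's zero-mean/unit-variance scaling,
applied identically at training (maps are standardized before windowing)
and at inference (`segment_map` standardizes by default). Class weighting
is not used; protein/solvent balance is near 1:1 in practice.

### Desk-scale experiments

The scaled-down runs used by the tests and the acceptance script train a
`base_filters=8` network on 3 synthetic maps (phase error 10–30°, solvent
0.45–0.65) with 80 windows/epoch for 5 epochs at learning rate 1e-3 and
batch size 4 — sizes chosen so a run takes a few minutes on one CPU while
still reaching ≥ 0.8 validation voxel accuracy and recovering held-out
solvent contents within 0.1. The higher learning rate compensates for the
short schedule; the full-scale defaults remain 1e-4/32/100.

## Solvent-content machinery

* `expected_solvent`: mean of `P_i` over the cell (equals the brute-force
  sum to 1e-12 in the oracle tests).
* `find_logit_cutoff`: voxels with `log(P_i/(1−P_i)) > l_c` are solvent;
  the cutoff reproducing a target fraction is the midpoint between the
  adjacent order statistics of the sorted logits, reaching the target
  within one voxel quantum `1/N`. Degenerate all-equal grids return the
  boundary cutoff with a warning. Probabilities are clipped to
  `[1e-9, 1−1e-9]` before the logit.
* `P_U` is the normalized histogram of per-dataset cutoffs over a
  configurable logit range (default 50 bins on [−8, 8]; the bin count and
  range are not canonical and are surfaced in the JSON serialization).
  Cutoffs outside the range are clipped into the edge bins, and evaluation
  clips consistently.
* `P_M` is the piecewise-linear interpolation through (0, 0), all
  candidate points and (1, 0).
* Evaluating `P_U` at a candidate solvent content goes through the
  dataset's own probability grid — the candidate maps to the cutoff
  achieving it, and the distribution is read at that cutoff. This is the
  only construction consistent with `P_U` being a distribution over
  cutoffs rather than contents.
* `conflate_centroid` integrates `S·P_M(S)·P_U(S)` by the trapezoid rule on
  a uniform grid (step 0.001); "centroid" is read as the first moment of
  the normalized product, with a mode-of-product alternative behind a
  config switch. An identically zero product falls back to the
  segmentation expectation with a warning.
* `combine_estimates` implements the three cases with auditable thresholds
  (defaults: δ_tight = 0.05, δ_loose = 0.15, and "high probability" =
  0.5 × the largest candidate probability); the case taken, the thresholds
  and `S_U` are all recorded in the returned estimate. Case-1 and case-3
  outputs are bitwise copies of their inputs (no arithmetic drift). The
  estimate is computed once, from the map after initial phasing, and
  flagged final — re-estimation from model-biased later-cycle maps is
  deliberately unsupported.
* `matthews_candidates` computes `S_z = 1 − z·n_sym·MW·ν̄/(V·N_A·10⁻²⁴)`
  with ν̄ = 0.74 cm³/g (the usual protein partial specific volume,
  exposed as a parameter). Probabilities are caller-supplied — the
  published Matthews-probability fit functions live outside this package —
  with a uniform fallback.

## Known limitations

* The numpy engine is CPU-only and orders of magnitude slower than a GPU
  framework; full-scale training (tens of thousands of windows, 100
  epochs) is out of reach, and the package makes no claim about
  reproducing full-scale validation accuracy on real maps.
* Symmetry support is limited to applying operator lists on compatible
  grids; the synthesis is cubic P1 only.
* The combination thresholds are sensible defaults, not fitted values;
  they are exposed precisely so users can audit and adjust them.
* `MatthewsPrediction` requires strictly increasing candidates and at
  least one positive probability; empty candidate lists are represented by
  passing `None`, which yields the pure segmentation estimate.
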