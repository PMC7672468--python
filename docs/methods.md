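# Methods

This document describes the models and numerical choices behind cytosom:
what each component computes, which assumptions it makes, why the defaults
are what they are, and where the known limitations lie.

## Problem setting

Flow and mass cytometry experiments produce matrices of 10⁵–10⁸ events
(cells) × 10–50 markers, stored across many FCS files. The analysis goal
is to group events into cell populations and visualize the result. cytosom
implements the batch self-organizing map (SOM) approach: a small codebook
of `m` prototype vectors arranged on a 2D grid is fitted to the data, each
event is assigned to its nearest prototype, and grid structure is reused
for a linear-time 2D embedding. Because every per-event computation is
independent given the codebook, the whole pipeline parallelizes over row
shards with only O(m·d)-sized messages.

## FCS input and preprocessing

### File format

`cytosom.fcs` reads FCS 3.0/3.1 files directly: the 58-byte version/offset
header, the delimiter-framed TEXT segment (with doubled-delimiter
escaping), and the DATA segment for `$DATATYPE` F (float32) and D
(float64) with `$BYTEORD` little/big endian. Integer and ASCII data types
are rejected explicitly rather than mis-read. Header scans
(`read_fcs_header`) never touch the DATA segment, so planning over huge
files is cheap; `read_fcs_events(path, first, last)` reads a contiguous
event range by offset without loading the rest of the file. The writer
emits FCS 3.1 float32 files, which round-trip bit-exactly at float32
precision.

### Compensation

Spillover correction solves `compensated · S = raw` for the compensated
matrix (right division by the spillover matrix S), matching the standard
convention in which row i of S describes how fluorochrome i bleeds into
each detector. S is read from the `$SPILLOVER` keyword or a CSV file.
Markers absent from S pass through untouched. A singular S raises instead
of producing a least-squares guess.

### Transformations

- **asinh, cofactor 500** (`transform_asinh`): the standard variance-
  stabilizing transform for fluorescence intensities; 500 is the
  conventional cofactor for flow data (mass cytometry typically uses 5 —
  pass `cofactor=5`). asinh is linear near zero and logarithmic for large
  values, and unlike log it accepts negative compensated values.
- **z-scaling** (`scale_columns` / `apply_scaling`): per-column
  standardization to mean 0, sample (n−1) standard deviation 1, so that
  Euclidean distances weight markers equally. The fit returns a parameter
  object so the *same* affine map can be applied to every shard — scaling
  shards independently would make shards incomparable. Constant columns
  are centered but not divided (with a warning).

## Batch SOM

### Model

A codebook `W ∈ ℝ^{m×d}` lives on an x×y rectangular grid (row-major node
numbering; node i sits at integer grid coordinates). One batch epoch:

1. assign every event to its nearest codebook row (exact Euclidean BMU,
   lowest index on ties);
2. form per-node sums `S_i = Σ_{x∈node i} x` and counts `c_i`;
3. smooth both through the row-stochastic neighborhood matrix Ĥ and
   update `W_i = (Ĥ·S)_i / (Ĥ·c)_i`, keeping the old `W_i` where the
   denominator is zero.

This count-normalized form makes each new prototype a convex combination
of event vectors, so the update is unconditionally stable — no learning
rate. With Ĥ = I the epoch is exactly one Lloyd k-means step, which the
test suite checks against an independent oracle. A `literal_update` debug
flag computes the unnormalized textbook form `W = Ĥ·N·X` instead
(assignment-matrix N), useful only for verifying the algebra.

The neighborhood kernel is Gaussian `exp(−g²/2r²)` over grid distances g
(or a hard-bubble variant), row-normalized. The radius anneals linearly
from `max(x, y)/2` to `radius_end` over the epochs.

### Defaults and why

- `epochs=10`: batch SOM converges in few passes because every epoch uses
  all data; 10 is enough for the F1 plateau on separated mixtures.
- `radius_end=1.0`: keeps mild smoothing at the end, which preserves grid
  topology for the embedding. For prototype-accuracy tasks (e.g. matching
  true component means with a tiny grid) `radius_end=0.2` ends training in
  a nearly pure Lloyd regime and is what the recovery tests use.
- Initialization samples `m` distinct events uniformly without
  replacement (seeded), the cheapest scheme that cannot produce duplicate
  prototypes.
- The online Kohonen rule (`train_online_som`) is included as a reference
  implementation only; it is sequential by construction and serves as a
  quality baseline (the tests check batch training is not worse).

### Nearest-neighbor backends

BMU search dominates runtime. `cytosom.neighbors` provides three exact
backends behind one interface: brute force (BLAS inner-product
expansion), kd-tree, and ball tree (scikit-learn trees). The trees only
*propose* candidates (k + 16 padding); candidates are re-ranked with the
same arithmetic as the brute path and ties are broken toward the lowest
node index, so all backends return identical (index, distance) results —
a property the tests enforce on adversarial tie cases. Selected distances
are recomputed as `‖q−p‖` directly rather than via the inner-product
expansion, which can leave ~1e-8 residuals at exact matches. `auto`
picks brute force for small codebooks or d > 16, a kd-tree otherwise.
A `dtype=np.float32` fast path gives ~7× faster assignment on one core;
labels can differ from float64 only for events almost exactly equidistant
between nodes.

## Distributed execution

### Slice planning

`plan_slices(event_counts, n)` treats the concatenation of all files as
one global event stream and cuts it into n contiguous slices whose sizes
differ by at most one (the ⌈N/n⌉-sized slices come first). A slice is
described by four integers (first file, first event, last file, last
event-exclusive) — enough for a worker to read *only* its byte range via
partial FCS reads. Planning therefore needs only header scans.

### Training loop

`distributed_train_epoch` broadcasts the codebook (m·d floats), has each
worker compute its shard's per-node sums and counts, reduces the replies
by addition, and applies Ĥ-smoothing centrally. Worker replies are
O(m·d) regardless of shard size (the tests assert the exact byte count).
Addition of partial updates is associative up to float rounding, so the
trained codebook is independent of the shard count to ~1e-15 relative;
within-shard sums use chunked Kahan summation to keep that bound tight on
10⁶-event shards. Worker failures surface with the shard index named.

## SOM-guided embedding

Each event is embedded into grid coordinates using only its k nearest
codebook vectors: neighbor distances become scores through a truncated
Gaussian of the rank-scaled distance (scale = distance of the (k+1)-th
neighbor, so scores reach exactly 0 at the neighborhood boundary — this
makes placement continuous as points cross neighbor-set boundaries), and
for every neighbor pair the event's projection onto the data-space segment
is transferred to the grid segment; the score-weighted least-squares
position is a closed-form 2×2 solve per event.

Defaults: `k=16` (captures local manifold curvature without washing out
locality), `smooth=0.3` (keeps events near their BMU cell; the fixed-point
test requires node vectors to embed within 0.25 grid units of their own
node), `adjust=1.0`. When the scored neighbors are collinear in grid
space (always true for k=2 or 1-D grids) the 2×2 system is singular; such
events fall back to the score-weighted average of neighbor grid positions
and are counted and warned about.

Events embed independently, so the distributed version is bitwise equal
to the serial one.

## Rasterization

Low-alpha additive scatter plots of 10⁶⁺ embedded events. Contributions
are accumulated as int64 fixed-point values (value × 2²⁰, one rounding
per point), which makes partition merges exact and associative — a merged
distributed render is bit-identical to a serial one. Binning is half-open
per pixel; out-of-bounds points are counted, not clamped. `develop`
tone-maps linearly by maximum coverage (optional gamma) and
un-premultiplies color; the map is monotone in coverage and an empty
canvas develops transparent. `marker_mix_colors` maps up to three marker
intensities to RGB via per-channel percentile normalization (p5–p95 by
default, robust to outliers).

## Evaluation

`contingency` cross-tabulates cluster labels against ground-truth
populations (optionally dropping an "ungated" label). `greedy_assign`
maps each non-empty cluster to its row-argmax population; clusters mapped
to the same population are aggregated. `mean_f1` is the unweighted mean
of per-population F1, with unmatched populations scoring 0 — the usual
convention for cytometry benchmarking, which penalizes missing rare
populations as much as missing large ones. A weighted variant is
available.

## Synthetic data

`simulate` draws labeled Gaussian mixtures. `well_separated_spec` places
component means near a sphere of radius `separation/√2` (random sphere
points in high dimension sit ≈ r√2 apart), redrawing with a growing
radius until all pairwise mean distances reach `separation`·σ (default
6σ — separated enough that nearest-prototype clustering can reach F1 ≈ 1,
so evaluation failures indicate algorithmic bugs rather than hard data).
`write_fixture_set` writes the mixture as deliberately uneven FCS files
(sizes ∝ 1, 2, …, n) plus `truth.csv`, optionally in raw intensity units
(`sinh(x)·cofactor`, the exact inverse of the asinh preprocessing). The
generator's scope is correctness testing and benchmarking, not realism:
no doublets, debris, spillover, batch effects, or heavy-tailed noise.

## Numerical choices, summarized

- float64 throughout by default; opt-in float32 for BMU search and
  embedding on huge data (affects only near-tie assignments, embedding
  coordinates to ~1e-5).
- Chunked Kahan summation in partial updates; associative reduction.
- Exact integer accumulation in the rasterizer.
- Ties broken deterministically (lowest index) in every nearest-neighbor
  path, so all backends and shard layouts agree exactly.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global RNG state.

## Limitations

- No FCS 2.0, integer (`$DATATYPE I`) or ASCII data, multi-dataset files,
  or `$NEXTDATA` chains.
- The distributed layer models a master/worker cluster in-process
  (thread pool); it demonstrates the communication contract but does not
  include a network transport.
- Grids are rectangular only (no hexagonal topology, no toroidal edges).
- The embedding is guided by the SOM: distortions of the trained map
  (twists, dead nodes) propagate into the picture.
- Greedy matching is not an optimal assignment (Hungarian); it follows
  the convention of maximizing per-cluster purity and can under-score
  pathological contingency tables.
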