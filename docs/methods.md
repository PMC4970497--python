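# Methods

## Problem setting

In a single-particle imaging (SPI) experiment, identical particles are
injected into a pulsed X-ray beam and each pulse yields one diffraction
snapshot of one particle at an unknown, uniformly random orientation.  At
biologically interesting resolutions the frames are extremely sparse —
tens to hundreds of photons each — so no single frame determines its own
orientation.  The package reconstructs the 3D diffraction volume
`W(q)` from such frames with the expand–maximize–compress (EMC)
algorithm, treating each pixel of each frame as an independent Poisson
sample.

## Geometry conventions

Spatial frequency follows the crystallographic convention `q = 2 sin(θ)/λ`.
The half-period resolution is defined from the detector *edge*,
`a = λ / (4 sin(φ_edge/2))` with `φ_edge = atan((d/2 · l_D) / z_D)` for a
`d`-pixel detector of pixel side `l_D` at distance `z_D`; the maximum
scattering angle `φ_max` is taken to the detector *corner*.  The full
field of view is `L = λ z_D / l_D`.  For a particle of radius `R_p`, the
dimensionless radius is `R̄ = R_p / a` and the speckle sampling
`σ = L / (2 R_p)`.

Each pixel at grid offset `(x, y)` (pixel units, sample at distance
`D = z_D / l_D`) maps onto the Ewald sphere via the unit direction
`s = (x, y, D)/|(x, y, D)|` and `q = (s − ẑ)/λ`.  Voxel units are fixed
so that the edge-center pixel lands at radius `d/2`, making adjacent
central pixels roughly one voxel apart and the model grid commensurate
with the detector.  The cubic model grid side is
`M = 2·ceil(max |q_vox|) + 3` — odd, so a center (zero-frequency) voxel
exists, with a one-voxel trilinear-interpolation margin.

Per-pixel corrections multiply a flat-detector solid-angle factor
(`cos³θ` for identical square pixels on a plane) and the Thomson
polarization factor (`1 − s_x²` for x-polarized beams, `1 − s_y²` for y,
`(1 + cos²2θ)/2` for unpolarized), normalized to unity on the beam axis.
The exact polygonal per-pixel solid angle is deliberately out of scope;
at SPI scattering angles the `cos³θ` approximation is accurate to far
better than the photon noise.

Pixel categories: 0 = good (used for orientation determination and
merged), 1 = merge-only (outside the inscribed circle, typically detector
corners — too few per-ring neighbours to help orient but still useful
signal), 2 = bad (beamstop or dead; never used).

## Rotation-group sampling

Orientations are sampled quasi-uniformly by refining the 600-cell, the
regular 4-polytope whose 120 vertices are unit quaternions.  At level
`n`, each of the 600 tetrahedral cells is subdivided with the barycentric
lattice `{(i,j,k,l)/n : i+j+k+l = n}`, points are projected to the unit
3-sphere, duplicates on shared faces removed, and antipodal pairs
(`q ≡ −q` as rotations) identified by keeping the representative whose
first nonzero component is positive.  The count is exactly
`M_rot = 10(5n³ + n)` and the covering radius shrinks like `1/n`.  Prior
weights are uniform (`w_r = 1/M_rot`), matching the uniform orientation
prior assumed by the diagnostics; the weight policy is a single switch so
a volume-based weighting can be added without touching callers.

## The EMC iteration

Let `K_dt` be the photon count of frame `d` at pixel `t` and `W_rt` the
model intensity sliced at orientation `r` (trilinear interpolation of the
grid at `R(q_r)·q_t`, times the pixel correction).  One iteration:

1. **Expand** — compute `W_rt` for all `r` in the rotation sampling.
2. **E-step** — Poisson log-likelihood
   `ln R_dr = Σ_t [K_dt ln(φ_d W_rt) − φ_d W_rt]` over category-0 pixels
   (frame-constant terms drop), annealed posterior
   `P_dr ∝ w_r exp(β ln R_dr)` normalized over `r`, computed in the log
   domain with per-frame max subtraction.  `W_rt` is floored at 1e−20
   inside logarithms so an observed photon against a zero-intensity model
   value stays finite.
3. **Scale update** (optional) — `φ'_d = Σ_t K_dt / Σ_r P_dr Σ_t W_rt`,
   the exact maximizer of the EM surrogate in `φ_d`, renormalized to
   mean 1 (the gauge freedom is absorbed by the model scale).
4. **M-step** — `W'_rt = Σ_d P_dr K_dt / Σ_d P_dr φ_d` over category-0/1
   pixels.  Orientations with zero posterior mass are flagged unobserved
   and skipped in the merge.
5. **Compress** — scatter-add each tomogram value (correction divided
   out) into its 8 neighbouring voxels with the same trilinear weights
   used by expand, accumulate the weights separately, and divide.
   Voxels receiving no weight keep the previous model (switchable);
   zeroing them would punch holes near the grid corners between sampled
   orientations.
6. **Friedel symmetrization** — `W ← (W(q) + W(−q))/2`, on by default
   since the diffraction intensities of a real density are
   centrosymmetric; switchable.

The initial model is uniform random in `(0, 2·mean photon density)`,
seeded from the configuration.  Convergence is by fixed iteration count,
matching the command-line contract; the diagnostics make the choice easy
to judge.  Orientation loops are chunked and independent, so any parallel
map yields the serial result up to summation order.

### Deterministic annealing

With very bright frames (≳10⁴ photons) the posterior at β = 1 is
essentially a delta function for every frame from the very first
iteration, and random starts lock in arbitrary hard assignments: the
update concentrates all posterior mass onto a small fraction of
orientations and the run converges to a stable but wrong model.
Annealing replaces `R_dr` by `R_dr^β`; at β ≪ 1 the posterior stays
broad (per-frame orientation entropy near `ln M_rot`), the model relaxes
to a rotationally blurred but consistent solution, and β is then
multiplied by `beta_jump` every `beta_period` iterations (capped at 1) to
sharpen the speckles.  β = 1 reproduces the unannealed path bit-for-bit.

### Diagnostics

Per iteration: r.m.s. per-voxel model change; mutual information
`I = ⟨Σ_r P_dr ln(P_dr / w_r)⟩_d` in nats per frame (0 for a uniform
posterior, `ln M_rot` when each frame fits one orientation — natural
logarithms throughout); the EM surrogate average log-likelihood
`Q = ⟨Σ_r P_dr ln R_dr⟩_d` (the reported likelihood diagnostic; the
marginal `⟨ln Σ_r w_r R_dr⟩_d` is also available); and each frame's most
likely orientation (argmax ties break to the lowest index, for
determinism).  The orientation history is rendered by sorting frames
within each constant-sampling block by the final column of that block,
stably, so converged runs show a smooth spectrum.

## Simulator

The synthetic phantom is a sum of Gaussian blobs with random centers
inside `0.8 R_p` and random weights, apodized by a raised-cosine window
vanishing at `R_p` — enough structure to produce an asymmetric speckle
pattern while keeping a compact, exactly known support.  (A PDB-backed
density builder is provided as a convenience for realistic molecules.)
Intensities are `|F[ρ]|²` on the odd model grid with a reciprocal-space
Gaussian low-pass (sd = half the edge frequency, configurable) standing
in for the atomic form-factor fall-off; the width only shapes the
high-`q` tail.

Frames are generated per the generative model the reconstruction assumes:
uniform random orientation (3-uniform-deviates quaternion construction),
per-pixel mean `φ_d · s · corr_t · W(R_d q_t)` with the global scale `s`
calibrated so the category-0/1 expectation equals the target mean count
`N` at unit fluence, Gaussian fluence jitter truncated at zero, a uniform
background of `background_mean / num_pix` per unmasked pixel, and Poisson
draws.  The correction factor is applied in both simulation and
reconstruction (symmetric, so it cancels in recovery tests).  Identical
seeds give byte-identical photon files.

What the simulator does *not* emulate — and hence what passing recovery
tests do not establish: structured (non-uniform) backgrounds, realistic
heavy-tailed fluence distributions, conformational heterogeneity,
detector artifacts beyond static masks, and non-Poisson noise.

## Experiment sizing

The planner reproduces the published scaling relations: refinement level
`n = round(R̄)`, `M_rot = 10(5n³+n)`, required frames
`M_data = S² M_rot / N` (S² is the average number of photons per
orientation; S ≈ 10 is modest fidelity, S ≈ 50 high fidelity), model
memory `(2σR̄)³` voxels at 8 bytes, probability matrix
`M_data · M_rot` entries at 8 bytes, sparse data ≤ `N · M_data` entries
at 8 bytes (index + count).  Binary MB/GB units.

## Problem sizes used in the test suite

The published full-scale reconstructions use 3–5×10⁵ frames and up to
2×10⁵ orientations; the package's end-to-end tests exercise the same code
paths at desk scale, chosen to leave comfortable signal margins rather
than sit at threshold:

* recovery run: 64² detector, level-4 sampling (3240 orientations), 3000
  frames at N ≈ 100 (S² ≈ 93 photons/orientation), 30 iterations; the
  recovered volume is compared to the ground truth by exhaustive
  best-rotation Pearson correlation on the 0.1–0.8 radial shell
  (criterion: > 0.9; measured ≈ 0.998).
* annealing runs: 32² detector, level-2 sampling (420 orientations), 400
  frames at N ≈ 10⁴; β = 1 collapse vs β = 0.001 entropy retention over
  5 iterations × 5 restarts, and a 0.001 → 1 doubling schedule (period
  10) run for 110 iterations.

## Numerical choices and degenerate inputs

* Trilinear interpolation for both slicing and merging; the pair is an
  exact adjoint, giving the weight-conservation identity
  `Σ(merged·weight) = Σ(tomogram values)`.
* E-step log-domain normalization with per-frame max subtraction; an
  all-zero row after exponentiation raises an error naming the frame.
* Empty frames, empty photon sets and all-masked detectors are legal
  (the last warns); a beamstop radius covering the whole detector is a
  warning, not an error, because hand-edited detector files may
  deliberately mask everything but a region of interest.
* Sparse photon files are native-endian 32-bit signed integers;
  truncation errors name the offending block.
* The 600-cell refinement deduplicates shared-face points by rounding to
  9 decimals — safe because distinct samples are separated by ≥ 0.6/n in
  quaternion space, ~10⁷ rounding units at any practical level.

## Known limitations

* No distributed-memory execution; the probability matrix is held dense
  in memory, so practical problem sizes are bounded by
  `M_data · M_rot · 8` bytes (the planner quantifies this).
* Uniform rotation weights only (see above).
* No multi-class (heterogeneous particle) reconstruction, no in-loop
  background learning, no Gaussian noise model for bright integrating
  detectors.
* Multi-panel detectors are supported only through hand-written detector
  files; there is no tiling geometry tool.
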