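# Methods

This note documents the models, estimators and numerical choices behind
helixbridge, and what its validation does and does not establish.

## Electrostatic contacts and distance pools

A salt bridge is operationalized purely geometrically. For an acidic
residue (Asp, Glu) and a basic residue (Arg, Lys) the charged side-chain
heavy atoms are fixed sets — Oδ1/Oδ2, Oε1/Oε2 and Nε/Nη1/Nη2, Nζ — and a
frame counts as a *contact* when the minimum O–N distance over all atom
pairs is ≤ the cutoff. The cutoff defaults to 3.5 Å and the boundary is
inclusive: "within 3.5 Å" is read as ≤, a choice that is irrelevant for
continuous distances but must be fixed for reproducibility. The contact
probability of a pair is `n_contact_frames / n_frames` with frames pooled
across replicas after the equilibration discard; per-replica counts are
retained so the pooled value can always be decomposed into the
frame-count-weighted mean of per-replica probabilities (an exact
identity, tested in rational arithmetic).

Distance *pools* answer a different question — the shape of the whole
O–N distance distribution — and therefore pool **all** O–N atom-pair
distances, not per-frame minima. Both summaries "fraction < 4 Å" and
"fraction in [2, 4) Å" are reported, because the two conventions differ
in how they treat sub-2 Å artifacts and both are in circulation;
conflating pools with the contact criterion is a common error the API
deliberately makes impossible. Histograms default to 0.2 Å bins
(configurable; the bin width is a presentation choice, not a model
parameter).

Residues with missing charged atoms (truncated side chains) are declared
unusable rather than analysed on the partial atom set, since a missing
Nη biases minima downward in an asymmetric, invisible way.

Periodic boundary images are not considered: trajectories are expected
to be imaged/whole on input, which holds for intra-domain side-chain
distances that are far smaller than any box dimension.

## Helix axes, inter-helix angles and bending

**Axis fit.** Each interior Cα yields a local helix-center estimate by
the bisector construction: the bisector of the two bond vectors at a Cα
points at the helix axis, and the local twist angle between consecutive
bisectors converts the Cα–Cα chord into a radius. For an ideal α-helix
(rise 1.5 Å/residue, twist 100°/residue, radius 2.3 Å) the construction
is exact. The principal line through these centers (total least squares
via SVD) initializes a Levenberg–Marquardt refinement of the cylinder
objective — minimizing the spread of Cα radial distances about a common
radius over axis point, direction and radius. The refinement step exists
because the bisector/principal-line estimate alone, while exact for
clean helices, carries ~1° of estimator noise for short (15-residue)
helices at coordinate noise σ ≈ 0.2–0.3 Å; refining against the radial
objective brings it into 0.5° agreement with an independent brute-force
cylinder optimizer across that whole regime. Axes are unit vectors
oriented N→C (sign fixed by the first-to-last Cα span), and inter-helix
angles are reported in [0°, 180°] without folding, so antiparallel
packing reads as ≈ 180°.

**Bending.** Local axis points are computed per sliding window of
`bendix_window` (default 4) consecutive Cα, step 1, as the mean of the
window's interior bisector centers. The per-frame maximum bend compares
axis chords of `spacing` points (default: the window) separated by a
`gap` (default: the window): the `window − 1` axis points whose windows
straddle a kink blend the two segment directions, and chords compared
across that blended region recover a localized kink at its full angle.
Comparing strictly consecutive local directions instead provably smears
an abrupt kink over ~window directions and reports only a fraction of
it; the consecutive directions remain available from `local_axes` for
curvature profiling. With the defaults, a helix must have at least
2·spacing + gap + window residues (16) for a bend value. No spline
smoothing is applied to axis points; the window size itself is the
smoothing scale.

Because the per-frame maximum of noisy local angles is a maximum, it
carries a small positive bias under coordinate noise (≈ +0.4° at σ =
0.1 Å for the default geometry, ≈ +2° for a straight helix where the
true value is 0). Recovery tests bound this bias; users comparing
conditions should compare like with like, where the bias cancels.

## Superposition

Structures are paired Cα-by-Cα on (chain, author residue number) — no
sequence alignment — and superposed by the closed-form Kabsch solution:
SVD of the covariance of centered coordinates with the determinant
correction that forbids reflections. The fit is unweighted over all
matched Cα with no outlier rejection by default; an optional iterative
mode re-fits after discarding pairs beyond a distance cutoff, for
structure pairs that are not isomorphous. RMSD symmetry, invariance to
pre-transforms, the lower bound against unfitted RMSD, and agreement
with both a numerical rotation-search optimizer (10⁻⁴ Å) and an
independent QCP implementation are all under test.

## Statistics

Bootstrap standard errors resample frames with replacement (default 1000
replicates) and report the standard deviation of resampled means; all
resampling is driven by explicit seeds through `numpy.random.Generator`,
so repeated runs are bit-identical. Frames are treated as independent
observations. They are not — consecutive MD frames are autocorrelated —
so these SEs are lower bounds and significance is overstated; a block
bootstrap that resamples whole replicas is provided for a conservative
alternative, and the two-state generator's autocorrelation is explicitly
accounted for (variance inflation (1+ρ)/(1−ρ)) wherever recovery tests
assert statistical tolerances. The two-sample test defaults to the
classic pooled-variance Student's t (Welch by flag). Formatted reports
floor p-values at 2.2×10⁻¹⁶; machine outputs keep raw values. No
multiple-testing correction is applied.

## Synthetic ensembles

The generator emulates the *statistical* structure of a replica MD study
of a helical domain, not its physics: no force field, solvent, or
thermodynamic consistency. Defaults mirror the emulated study design —
four replicas per condition, and observables centered on the wild-type
ensemble values of the system that motivated the package (two helices at
47.6°, a 17.2° kink in the longer one, one salt bridge with stationary
closed probability 0.6).

- **Geometry.** Ideal Cα helices; a kink rigidly rotates the C-terminal
  segment about a perpendicular axis through the kink point, so both
  segments remain ideal. Helix 1..n−1 are oriented so the angle between
  *fitted* axes of the noiseless geometry equals the configured pair
  angle exactly (relevant when the reference helix is kinked and its
  overall fitted axis differs from either segment).
- **Salt bridges.** Pseudo-residues (Asp OD1/OD2, Arg NE/NH1/NH2) whose
  minimum O–N distance tracks a simulated series exactly by
  construction: NE sits at the sampled distance from OD1 along a fixed
  direction and all other O–N pairs are strictly farther. The series is
  a two-state Markov chain (default stay probabilities 0.7 closed / 0.55
  open → stationary closed 0.6, lag-1 autocorrelation 0.25, i.e. a
  correlation time under 1 ns at the 0.2 ns frame spacing — a realistic
  regime for side-chain contacts and one where a 2000-frame ensemble
  pins the stationary probability to ~1.4%). Distances are
  state-conditional Gaussians (closed 2.8 ± 0.2 Å, open 6.0 ± 1.0 Å)
  truncated by redrawing at 0.5 Å — a generator artifact preventing
  unphysical near-zero distances, not a physical claim.
- **Noise and determinism.** Isotropic Gaussian coordinate noise
  (default σ = 0.1 Å) is applied to helix atoms only; the salt-bridge
  pseudo-atoms carry the sampled distance exactly, because the
  state-conditional Gaussian *is* the distance noise model and double
  noising would break the documented tracking contract. All randomness
  flows from the single config seed: `SeedSequence(seed)` spawns one
  child per replica; each replica child spawns one stream for coordinate
  noise plus one per salt-bridge model. Identical seeds give
  byte-identical datasets (PDB text at 10⁻³ Å precision).
- **Scale.** 500 frames × 4 replicas at 0.2 ns spacing keeps every
  recovery test and the acceptance script desk-scale (the full pipeline
  over two conditions runs in about a minute on one CPU) while
  preserving the replica structure of the emulated design. Synthetic
  frames start equilibrated, so generated datasets ship an analysis
  config with a zero equilibration discard; the 30 ns discard default
  applies to real trajectories.

**What passing recovery tests shows — and does not.** Recovery of
configured angles, kinks and stationary probabilities demonstrates that
the estimators are unbiased and correctly plumbed at realistic noise
levels. It does not validate the 3.5 Å cutoff as chemistry, the
independence assumptions on real correlated MD frames, or force-field
adequacy; published ensemble values from hundreds of nanoseconds of MD
per construct are not reproducible at this scale and are used only as
the *targets* the synthetic conditions mirror.

## Degenerate inputs and tie-breaks

Collinear Cα traces, vanishing local twist and parallel bisectors abort
the axis fit with explicit errors rather than returning an arbitrary
direction. Altloc resolution keeps the highest occupancy, ties broken by
altloc identifier order. Formats without time stamps (DCD, multi-model
PDB) require an explicit frame spacing so the equilibration cut is
unambiguous; XTC/TRR native times take precedence. Hydrogens, waters,
ions and ligands are retained in topologies but never analysed: every
observable here uses side-chain heavy atoms or Cα only.
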