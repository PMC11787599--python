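# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `trajcouple`. All lengths are Å, times ns, energies
kcal/mol, temperatures K; `k_B = 0.0019872041 kcal/(mol·K)` is the single
source of truth shared by the free-energy and entropy code.

## Geometry layer

**Centers and CCDs.** All center-to-center distances use geometric
(unweighted) centers of the selected atoms, never mass-weighted ones, and
this choice is applied uniformly. Region selections default to heavy atoms;
single-residue markers (e.g. the AHD and RD marker residues of Gα whose
separation defines the open/closed coordinate) default to the Cα atom when
one exists. Both are per-selection options because published analyses rarely
state the atom subset behind a "center".

**Superposition.** Rigid-body fits use the Kabsch algorithm: SVD of the
3×3 cross-covariance of the centered fit atoms, with the
determinant-correction convention (the singular direction belonging to the
smallest singular value is flipped when the raw solution would be a
reflection), so the returned rotation is always proper. Fewer than three fit
atoms, or a collinear fit set (second singular value ≤ 1e−9 of the first),
is a hard error: the rotation would be underdetermined. Tests cross-check
the rotation against an independent implementation
(`scipy.spatial.transform.Rotation.align_vectors`) and against random
rotation sampling.

**Pairwise RMSD matrix.** Entry (i, j) superposes frame j onto frame i via
the alignment selection, then measures the RMSD over the measured selection
(e.g. ligand atoms aligned on the receptor). Per-pair fits differ from their
transposes at the ~1e−6 Å level, so the matrix is symmetrized by averaging
with its transpose, restoring the exact symmetry the clustering stage
requires. Because each pair gets its own fit, the triangle inequality is
*not* guaranteed and is deliberately not asserted anywhere.

**Helix tilt.** The helix axis is the first principal component of the
helix's Cα coordinates, sign-oriented from the N- to the C-terminal Cα so
the angle to the reference-frame axis is meaningful over the full
[0°, 180°] range (an axis from PCA alone is sign-ambiguous). This is a
standard, parameter-free axis definition; kinks are averaged through, which
is adequate for rigid helices such as Gα α5 but not for strongly bent ones.

## Conformational clustering

The frame × frame RMSD matrix is agglomerated with Ward's
variance-minimizing linkage (`scipy.cluster.hierarchy`). Ward's objective
formally assumes Euclidean distances; feeding it a superposition RMSD
matrix is the standard distance-as-if-Euclidean approximation used by
common trajectory-clustering tools, and is documented here as such rather
than hidden.

The cluster count is chosen by the elbow rule on the within-cluster
dispersion curve `W(k)` = Σ over clusters of the mean squared distance of
members to the cluster medoid, for k = 1..k_max (default
`min(20, n_frames − 1)`): the selected k maximizes the perpendicular
distance of (k, W(k)) from the chord through (1, W(1)) and (k_max, W(k_max)),
ties going to the smallest k, and a flat curve (all frames identical)
yielding k = 1. Cutting the dendrogram renumbers labels by first appearance
along the trajectory, and each cluster's medoid minimizes the summed
intra-cluster distance with ties broken toward the lowest frame index — all
tie-breaks are deterministic so the whole pipeline is reproducible
bit-for-bit. A deterministic k-medoids (PAM BUILD + SWAP) on the same
matrix is exposed as a cross-check; it is not the default because the
hierarchical route needs no initialization choices at all.

## Key-lock coupling

Two components clustered over the same frames are compared by
cross-tabulating their assignments: each cluster pair (A_i, B_j) with at
least one common frame gets the overlap `|A_i ∩ B_j| / D`. The natural-
language rule "more than 50% of the common frames" does not pin down the
denominator D, so four readings are selectable — `min(|A_i|, |B_j|)`
(default: the most permissive symmetric reading under which calling a pair
"strong" is still meaningful), `union`, `a`, and `b` — and the mode used is
recorded in every report. The strong flag uses strict inequality
(overlap > 0.5), honoring "more than". Assignments over different frame
universes (e.g. different strides) are a hard error rather than a silent
intersection, because intersecting would silently change the denominator
semantics. No minimum cluster size is imposed by default; `min_cluster_size`
is available. Two exact invariants are asserted in code and tests: summed
`n_common` over all pairs equals the number of shared frames, and the
symmetric modes are invariant under swapping the components.

## State classification

Gα states from the AHD–RD CCD: open ≥ 55 Å, semi-open [45, 55) Å,
semi-closed (35, 45) Å, closed ≤ 35 Å. The published bin descriptions
overlap at 35, 45, and 55 Å; the convention here keeps "≥ 55 → open" and
"≤ 35 → closed" verbatim and assigns the interior edge 45.0 Å to the more
open bin, which makes the classifier a total, monotone function of the CCD
(verified by sweeping a 0.1 Å grid over [1, 100] Å). Ligand binding states:
bound < 12 Å, unbound > 40 Å, intermediate otherwise.

Whole-trajectory labels are reported under two named conventions, because
published figures use both without always saying which: the *dominant state*
(largest per-frame occupancy, ties toward the more open / more engaged
state) and the *mean-CCD state* (classify the time-averaged CCD). They can
legitimately disagree — a trajectory split 50/50 between 60 Å and 30 Å is
"open" by dominance but "semi-open" by its 45 Å mean — so outputs always
carry the convention name.

## Free-energy surfaces

`W = −k_B T ln(n_bin / n_max)` over uniform bins (default width 1.0 Å,
T = 310 K, the simulation temperature — never inferred from data). The
reference is the maximum-count bin, so the minimum over valid bins is 0 by
construction and all values are relative free energies. Bins holding fewer
than `min_count` samples (default 10, applied to 2D grids; 1D profiles
default to no cutoff) are masked with an infinity sentinel rather than
extrapolated. Axis ranges default to the data range aligned outward to the
bin width and are recorded in run metadata. No smoothing is applied to the
numeric grid; smoothing is a plotting concern only.

## Contacts and hotspots

A residue is in contact when the minimum heavy-atom–heavy-atom distance to
the ligand is ≤ 4.0 Å. The 4.0 Å heavy-atom cutoff is the common contact
convention, adopted because "interacting" is not defined numerically in the
source analyses; it is configurable and echoed into every report. Hydrogens
are excluded by default (toggleable); a residue whose atoms are all
hydrogens simply never contacts under the heavy-atom rule. A *hotspot* is a
residue in contact for strictly more than 20% of the full pathway duration
— fractions are computed over the whole timeline, not per binding phase,
and the per-phase summaries in the pathway report do not re-normalize.
Frames are unweighted by default; resampling-weighted ensembles can supply
a per-frame weight vector upstream. Geometric hotspot extraction carries no
interaction typing (no hydrogen-bond or salt-bridge criteria): published
ionic/aromatic annotations are interpretive labels, not computed rules.

## Series statistics

**Pearson r** is the standard sample product-moment coefficient; constant
input raises an error instead of returning 0, because an undefined
correlation must not masquerade as "uncorrelated".

**Block SEM** splits the series into `n_blocks` (default 5) equal contiguous
blocks, dropping the trailing remainder, and returns the sample standard
deviation (n − 1) of the block means divided by √n_blocks. Contiguous
blocks absorb the serial correlation of MD series; the block count is a
convention (no autocorrelation-time estimation is attempted), and with
n_blocks = n the estimator reduces exactly to the classic SEM.

**Interaction entropy** uses the exponential-average form
`−TΔS = k_B T ln⟨exp(β(E − ⟨E⟩))⟩`, evaluated with log-sum-exp. The source
analyses cite this method without printing the formula; the standard form
above is adopted and documented as such. The result is invariant under
energy offsets, non-negative by Jensen's inequality (clamped at 0 against
~1e−16 rounding on near-constant input), and guarded against arguments
beyond the evaluable exponential range. The enthalpy term of a full MM-PBSA
ΔG (Poisson–Boltzmann solver) is out of scope; ΔG assembly takes ΔH as a
user-supplied number.

## Synthetic data: what it emulates and what it does not

The generators produce the *inputs* each stage consumes, with ground truth
attached, so tests never re-derive truth from generated coordinates except
through declared independent oracles. They are deterministic given
(parameters, seed); no global random state is used.

- **Coupled ensembles** (`gen_coupled`): two bead components with k states
  each; A's states iid uniform, B matching A's partner state with
  probability f. Coordinates are state templates plus isotropic Gaussian
  noise; templates are random bead clouds rescaled so every pair is at
  least max(10·σ_noise, 1 Å) apart in superposed RMSD, which makes the
  planted partition recoverable whenever separation/noise ≥ 10.
- **Landscapes** (`gen_landscape`): mixtures of Gaussian basins sampled
  *directly* (not by Metropolis), so the stationary density — and hence the
  analytic W — is exact by construction; basin weights are Boltzmann
  factors of the planted depths.
- **Egress** (`gen_egress`): fully deterministic — a two-bead ligand moves
  monotonically along +x from a bound (< 12 Å) to an unbound (> 40 Å) CCD
  past residue beads whose contact windows are exact geometry; mirror
  dummy beads pin the receptor center at the origin so the CCD equals the
  ligand's x coordinate, and planted contact fractions are exact up to
  one-frame rounding. The seed parameter exists only for interface
  uniformity.
- **Schedules and energies** (`gen_ccd_schedule`, `gen_energies`):
  piecewise-constant CCD means with Gaussian noise; energy series with
  closed-form entropies (Gaussian: σ²/2k_BT; the two-point series is the
  balanced alternating ±a sequence so k_BT·ln cosh(a/k_BT) holds exactly
  for the finite sample).

These toys validate the *mathematics* of the pipeline — classification,
clustering, overlap statistics, Boltzmann inversion, contact counting — on
inputs with known answers. They do not emulate real receptor geometry,
membranes, force fields, kinetics, or resampling weights, so passing tests
certify correctness of the computations, not the biology of any particular
system.

## Problem sizes and determinism

Default study conditions used by the test suite and the acceptance script:
coupled-system checks at n = 2000 frames, k = 4, over 100 seeds
(statistic-level, using the generator's planted assignments — cluster
recovery is validated separately, so composing the two is equivalent and
keeps the matrix stage at n = 200 and n = 100 where it is exercised in
full); free-energy recovery at 2×10⁵ samples (single basin, tolerance 0.3
kcal/mol on bins with ≥ 100 counts) and 5×10⁵ (two basins, ΔW = 1.5 ± 0.2
kcal/mol); interaction entropy at 10⁶ Gaussian samples; elbow recovery over
100 seeds per planted k ∈ {2, 3, 5} at n = 100 frames with the default
k_max. Everything is seeded; CLI runs write a timestamp-free manifest
(config hash, package version, seed, effective parameters) and repeated
runs are byte-identical.

## Known limitations

- Ward-on-RMSD is an approximation (above); density-based or spectral
  clustering are out of scope.
- No hidden-Markov smoothing of state series and no kinetic rates from
  transition counts.
- No periodic-boundary handling: inputs are assumed whole-molecule imaged.
- No GaMD reweighting, WHAM/MBAR, or enhanced-sampling weight corrections
  in the free-energy module: surfaces are Boltzmann inversions of the
  supplied (assumed unbiased) samples.
- The coupling statistic reports counts and overlaps only; no significance
  test or mutual-information variant is provided.
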