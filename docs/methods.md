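# Methods

## Coarse-grained bundle model

Each transmembrane helix is an ideal α-helical Cα trace — 1.5 Å rise and
100° twist per residue on a 2.3 Å radius (standard α-helix values,
overridable per call) — treated as a rigid body in a fixed membrane
frame: z is the membrane normal, +z extracellular, membrane centred on
z = 0. A helix's degrees of freedom are an axial rotation about its own
axis, a tilt away from the membrane normal (stored as polar/azimuth, but
proposed in tilt-vector components so moves are symmetric about zero
tilt), and a translation restricted to the helix's allowed axes
(TM1 {z}, TM2 {y, z}, TM3 and TM4 {x, y, z}). Transforms always act on
the untransformed base placement, so repeated Monte Carlo moves cannot
accumulate numerical drift; rigidity holds to 1e-9 Å.

Topology is a per-helix config field (`n_term_side`), defaulting to an
alternating antiparallel bundle (TM1/TM3 N-termini extracellular,
TM2/TM4 cytoplasmic). The per-helix directionality is not established
experimentally; changing it flips individual traces but does not affect
the in-plane arrangement machinery.

The default helix set covers BTL residues TM1 Phe24–Asp48,
TM2 Phe75–Cys94, TM3 from Gly220, TM4 Pro254–Ser276. Two TM3 variants
ship because the available 18-letter sequence does not fill the
19-position range ending at Tyr238: the default `printed` variant uses
the 18-mer numbered 220–237, the `range` variant appends Tyr to reach
238. TM1 and TM4 have no published sequence: they are *synthetic
placeholder* sequences of the correct length with the functionally
referenced residues pinned (Phe24, His43, Asp48; Pro254, Pro258,
Ser276); analyses that depend on specific TM1/TM4 side-chain identities
beyond these anchors should not be trusted.

### Helix axis estimation

Helix axes (used for tilt, crossing angles and axis–axis distances) are
not taken from a plain principal-component fit: on a short trace with
incomplete turns the first principal component is biased by several
degrees (up to ~9° for an 8-residue trace). Instead we use the exact
identity that for points on a helix with per-residue twist Ω,
(c[i+1] + c[i−1] − 2 cos Ω · c[i]) / (2(1 − cos Ω)) lies on the axis;
a line fit through these derived points recovers the axis of an ideal
trace to machine precision and degrades gracefully under coordinate
noise. The plain PCA fit remains available (`twist=None`) and is the
fallback for degenerate inputs.

## Restraint score

The sampling energy is a weighted sum of six terms; the defaults are
all-1.0 weights because no published weighting exists, and every run
records its weights in the output metadata.

| term | form | defaults |
|---|---|---|
| diameter | w·max(0, D − D₀)², D = max in-plane midpoint distance + 2·2.3 Å | D₀ = 26 Å |
| excluded volume | Σ w·max(0, d_clash − d)² over inter-helix Cα pairs | d_clash = 4.0 Å |
| packing | −w · #{inter-helix Cα pairs with d ∈ window} | window [4.0, 6.5] Å |
| tilt | w·(θ − θ_max)² (radians) with θ_max = arccos(min(1, T/L)) | T = 30 Å |
| depth | w·Σ max(0, T/2 − z_top)² + max(0, z_bot + T/2)², axis extent z_center ± (L/2)cos θ | — |
| interactions | flat-bottom quadratics: axis–axis distance above 10.4 Å per predicted pair; certainty-weighted Cα–Cα distance above 8 Å per predicted contact | TM2–TM3, TM1–TM4; five contacts (certainties 1.00–0.79) |
| pair potential | Σ table[typeᵢ, typeⱼ] over inter-helix Cα pairs in the contact window | table[a,b] = −0.1·(KD(a) + KD(b)) |

Membrane thickness (30 Å), clash distance, contact window and the
axis-distance bound are literature-typical values and all
config-exposed. The depth term uses the *axis* z-extent
(L·cos θ centred on the helix midpoint) rather than the atom z-extent,
so a helix exactly as long as the membrane, centred and untilted, incurs
zero penalty; helices shorter than the membrane carry a small
irreducible deficit, which is a constant offset that does not bias
sampling. Every term is invariant under global rotation about z and
global in-plane translation.

The ranking term is deliberately transparent: a residue-type contact
potential whose 20×20 table defaults to pairwise sums of the
Kyte–Doolittle hydropathy scale (negative prefactor, so hydrophobic
contacts are rewarded) and is fully user-replaceable. It is a stand-in
for knowledge-based statistical potentials that are not publicly
available; ranking behaviour, not absolute energetics, is the supported
use.

A crossing-angle filter (default |Ω| ≤ 40°, configurable) is applied as
a hard filter at analysis time, not during sampling. The signed
crossing angle is computed from fitted axes folded into (−90°, 90°]
(axes are unsigned lines, so an antiparallel untilted pair crosses at
0°), with the sign given by the handedness of the rotation from axis i
to axis j about the midpoint-connection line.

## Monte Carlo sampling

Metropolis sampling with single-helix moves: one helix and one move
type (axial rotation / tilt / translation-on-an-allowed-axis) drawn
uniformly, perturbation uniform within ±amplitude (defaults 30°, 5°
tilt-vector, 1.0 Å). Acceptance is exp(−ΔE/T) with ΔE ≤ 0 always
accepted. "Varying temperatures" is realised as a geometric annealing
ladder, default 5.0 → 0.2 in 10 rungs (energy units of the restraint
score), repeated per restart; restarts beyond the first re-randomize
the starting transforms from the same seeded stream. Every
`record_stride`-th visited conformation is recorded, so an ensemble has
exactly ⌊n_steps/stride⌋ × n_restarts members. Seeds are mandatory and
runs are bit-reproducible from (seed, config); a non-finite energy
aborts with a diagnostic.

Initial configurations place the ideal helices on a 10 Å square with
randomized rotations/tilts/translations, since the upstream starting
structures the original workflow used are not available. Desk-scale
defaults (10 rungs × 1000 steps, stride 10–20) were chosen to make a
full sample–cluster–classify cycle a seconds-to-minutes interactive
operation; production-scale sampling only changes the step counts.

## Clustering and arrangement analysis

Pairwise Cα RMSD is computed **without superposition**: the membrane
frame is physically meaningful, and the in-plane arrangement is exactly
the signal — superposing first would erase it. A superposed (Kabsch)
variant exists behind a flag for sensitivity checks. Clustering is
agglomerative with complete linkage cut at the RMSD cutoff (default
2 Å), chosen because the cut then *guarantees* max intra-cluster
pairwise RMSD ≤ cutoff — a testable invariant. The centroid of a
cluster is the member minimising summed RMSD to its co-members, ties
broken toward the lowest index. Above 20 000 members, a greedy leader
pass at cutoff/2 pre-groups near-duplicates before the exact
hierarchical step (O(n²) memory otherwise); on well-separated data the
two routes agree.

Arrangement classification projects the four helix midpoints onto the
membrane plane and reads their clockwise order around the centroid as
seen from +z (extracellular view, y up — this convention fixes the
chirality of the six labels), anchored at TM1 (= A). Coincident or
collinear midpoints yield the explicit label `unclassifiable` rather
than an arbitrary assignment. Arrangement tables count labels over all
centroids and over the top-K (lowest-score) centroids, with the
top-3-share summaries recomputed from the counts at report time.

## Model-free relaxation analysis

Isotropic Lipari–Szabo spectral density with a single internal
timescale; no conformational-exchange (R_ex) contribution to R₂ — data
with exchange broadening will bias S² upward. Constants: r_NH = 1.02 Å,
Δσ(¹⁵N) = −160 ppm, standard gyromagnetic ratios; all collected in an
overridable `NMRConstants` record. Field default 18.8 T, with
frequencies derived from γB (ν_H ≈ 800 MHz, ν_N ≈ 81 MHz).

The shared overall correlation time is first extracted residue-by-
residue from R₂/R₁ ratios (rigid-limit inversion by bracketed root
finding on τₘ ∈ [0.5, 50] ns; out-of-range ratios fail explicitly),
then the mean initialises a joint bounded least-squares refinement of
(τₘ, {S²ᵢ, τₑᵢ}) against all rates, weighted by the experimental errors
when present. The refinement matters: the ratio inversion assumes
S² = 1, τₑ → 0, and the τₑ ≈ 50 ps contribution biases it by a fraction
of a percent, which the joint fit removes — noiseless round trips are
then exact to the optimiser tolerance. τₘ is shared per dataset
(species), matching one-τ-per-species reporting; internal
parametrisation is ns/ps to keep the optimiser well-conditioned, S² is
bounded to [0, 1].

## Titration and DOSY

Binding is a 1:1 association evaluated with the exact quadratic
isotherm (no weak-binding approximation); homo-dimer titrations reuse
the same functional form on the labelled/unlabelled pools. The
observable is linear in the bound-donor fraction between r_free and
r_bound. Fitting is nonlinear least squares over (Kd, r_free, r_bound),
multi-started over Kd ∈ {1, 10, 100, 1000} µM to avoid local minima,
with Gauss–Newton standard errors; < 4 points or a flat response raise
explicit errors (the latter as a non-identifiability error rather than
returning an arbitrary Kd).

A 12-point 0–1000 µM titration at 3% multiplicative noise carries an
intrinsic (Cramér–Rao) relative SD on Kd of ~13–21% across the
71.85–346.1 µM range — the fitted standard error reports this honestly,
and expectations for single-titration accuracy should be set
accordingly.

Stokes–Einstein converts D_tr to R_h = k_BT/(6πηD_tr). Viscosity is a
required-in-practice input: the default (water, 298 K, 0.890 mPa·s)
triggers a warning because micellar D₂O buffers are substantially more
viscous and R_h scales inversely with η.

## Synthetic data

Generators emulate each stage's input with planted truth and mandatory
seeds; identical (generator, seed, parameters) reproduce bit-identical
output, and file writers place the truth in a JSON sidecar.

* **Bundle ensembles** place the four helices on a square (side drawn
  uniformly from 9–11 Å) in the cyclic order of a drawn arrangement
  label, with uniformly random axial rotations (as sampling would
  produce) and Gaussian coordinate jitter. By construction, adjacent
  TM2/TM3 arrangements have shorter Pro85–Pro231 distances than
  diagonal ones. What these ensembles do *not* emulate: tilt
  distributions, correlated (collective) motions, non-square packings —
  so passing classification/clustering tests demonstrates correctness
  of the geometry pipeline, not realism of any particular ensemble.
* **Planted clusters** are rigid x-shifts of a reference bundle
  (pairwise RMSD = shift distance) with per-coordinate jitter of
  spread/√3, giving member-to-reference RMSD ≈ spread.
* **Relaxation tables** come from `predict_rates` at stated
  (S², τₑ, τₘ); **titrations** from the quadratic isotherm. Noise is
  multiplicative Gaussian (typical for NMR/fluorescence error
  reporting; switchable to additive), with nominal errors recorded in
  the `*_err` columns.

## Numerical choices and edge cases

* Flat-bottom penalties are exactly zero inside their allowed regions;
  score breakdowns sum to the total to 1e-9.
* Tilt-limit hard bounds are *not* imposed on transforms (only
  tilt ≥ 0); the tilt limit acts as a soft restraint, since a hard
  bound would freeze tilting entirely for helices shorter than the
  membrane.
* Zero-temperature Metropolis accepts ΔE ≤ 0 only in exact arithmetic;
  with continuous scores, uphill steps smaller than ~T remain
  acceptable, so monotonicity checks use gapped (discrete-level)
  landscapes.
* The Boltzmann occupancy check estimates its standard error by block
  averaging (50 blocks) to absorb the walk's autocorrelation.
* PDB I/O is a strict CA-only multi-model subset: fixed-format ATOM
  records, chains A–D, MODEL/ENDMDL; the parser reports the offending
  line number and round-trips coordinates at PDB precision (1e-3 Å).
  Configs reject unknown keys outright.

## Known limitations

* Cα-only models: no backbone N/C/O, side chains, or proline-kink
  geometry — the proline positions are tracked, their kinks are not
  modelled.
* The ranking potential is a hydropathy-sum surrogate; absolute
  energies and cross-potential comparisons are meaningless.
* Isotropic tumbling and single-timescale internal motion only; no
  anisotropic diffusion tensors, no extended model-free, no R_ex.
* The binding model ignores FRET photophysics (Förster radius, direct
  acceptor excitation, micelle partitioning); it fits proximity-derived
  ratios, nothing more.
* TM1/TM4 placeholder sequences (above) constrain what sequence-level
  conclusions the bundle stages can support.
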