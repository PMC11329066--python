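# Methods

`atrialdt` is a desk-scale reimplementation of the digital-twin workflow used
to characterize the arrhythmogenic propensity of fibrotic atrial substrate:
simulate rotor induction on fibrotic tissue, classify rotor-attracting
locations into independent (LIR) and contingent (LCR) types by guided-search
virtual ablation, screen lesions for iatrogenic atrial tachycardia (iAT), and
relate outcomes to fibrosis-density/entropy and electrogram-fractionation
metrics. Patient imaging and electroanatomical data are replaced throughout
by synthetic substrates with known ground truth.

## Synthetic substrates

Fibrosis fields are binary label fields on a regular 2D lattice (0.3 mm
spacing, the tetrahedral-mesh target edge length of the full-scale pipeline).
Three textures are generated from thresholded Gaussian random fields with a
controllable correlation length (default 2.5 mm, on the order of the LGE-MRI
resolution):

- **diffuse** — thresholded GRF; scattered patchy fibrosis;
- **compact** — one connected island grown from a GRF-roughened radial score
  (region growing guarantees a single component at any burden);
- **interdigitated_border** — a lateral two-phase gradient plus GRF
  perturbation, yielding a dense side grading into healthy tissue through an
  interdigitated border zone.

Thresholds are chosen by exact count, so the achieved burden matches the
target up to one lattice cell. All generators are bit-reproducible under a
seed.

LGE phantoms are nested-shell 3D volumes (spherical blood pool, atrial-wall
shell, and a separate aorta-wall tube) with Gaussian per-tissue intensities.
The 2D fibrosis map is projected onto the wall shell through spherical
coordinates; fibrotic wall voxels take a brighter intensity distribution. The
defaults (blood 100, healthy wall 80, fibrotic wall 150, aorta 100 arbitrary
units, SDs 8-10) put the healthy and fibrotic wall modes on either side of
the conventional image-intensity-ratio threshold so segmentation accuracy is
a meaningful test. The phantom does not model MRI artifacts (bias field,
motion, partial volume); segmentation results on it bound what thresholding
can do on ideal data, not on clinical scans.

Electrograms are trains of antisymmetric (derivative-of-Gaussian) biphasic
deflections with scheduled times, amplitudes (peak-to-peak) and optional
extra deflections at 2-8 ms spacing emulating fractionation; sampled at
2 kHz by default.

Rotor-dependency scripts encode, for every ablation subset, which rotors the
substrate can still sustain. The three worked patient cases are encoded
exactly as reported; subsets the narratives do not mention are completed by a
monotone-suppression convention (a rotor suppressed by some ablation set
stays suppressed in every superset; an emergent rotor appears only once its
triggering set is ablated), flagged in fixture metadata. Random scripts for
property testing are monotone by construction: each contingent rotor carries
a suppressor set, each emergent rotor a trigger set over native rotors.

## LGE segmentation (IIR / PIIR)

IIR divides intensity by the mean blood-pool intensity; PIIR further divides
by the mean aorta-wall IIR, the aorta wall serving as an internal
all-fibrous reference. A wall voxel is fibrotic iff PIIR is strictly above
the base constant `k` (ties non-fibrotic). The default `k = 1.22` reproduces
the widely used conventional IIR threshold when the mean aorta IIR is 1; the
per-patient constant of the original historical-cohort calibration is not
public, so `k` is configuration. PIIR is invariant to global gain and to
contrast-clearance shifts that move wall and aorta together, which is the
property the phantom pair test exercises.

## Fibrosis density and entropy

FD over a footprint is the fibrotic element percentage. FE is the binary
Shannon entropy (bits) of the fibrotic occupancy fraction inside a Euclidean
disc kernel of 2.5 mm radius (the imaging resolution), computed in-plane on
the 2D sheet; boundary kernels renormalize over the in-domain part. FE is
zero on homogeneous tissue, maximal (1 bit) at 50% occupancy, symmetric
under label swap, high at interdigitated border zones and low inside compact
islands — the qualitative contrasts that matter downstream. The original
method's "%" axis normalization is not published; an output scale factor
(default 1.0) is exposed and all FE acceptance checks are property-based.
Footprints at rotor locations are the ablation-lesion footprint (12-mm disc,
or the meander-covering ellipse), for FD and FE alike.

## Electrogram features

Deflections are local extrema of either polarity with amplitude between
0.1 mV and the atrium-wide maximum; extrema closer than a 1-ms refractory
merge (so one biphasic deflection counts once). The ICL counts
consecutive-deflection intervals in (0, 10] ms per point; a location's ICL
is the maximum point count within a 6-mm footprint (configurable to the
mean), and ICL% normalizes by the atrium-wide maximum count. Zero-length
intervals are treated as double-detection artifacts. Points flagged poor
quality are excluded from fractionation analysis but keep their voltage.

## Monodomain simulator

The solver is explicit forward-Euler monodomain on the 0.3-mm lattice with
operator-split reaction, face-based heterogeneous anisotropic fluxes
(harmonic face conductivities; zero flux across lesions, barriers and the
domain boundary) and a CFL-checked timestep (safety factor 0.8, typically
~0.05 ms).

The membrane is the Aliev-Panfilov two-variable excitable model. This
package's parameterization is pinned to the emergent operating points of the
full-scale atrial twins rather than to ionic detail:

| parameter | non-fibrotic | fibrotic | meaning |
|---|---|---|---|
| gain k | 8 | 8 | excitability gain |
| threshold a | 0.15 | 0.19 | activation threshold |
| eps0 | 0.006 | 0.0004 | baseline recovery rate |
| mu1 / mu2 | 0.2 / 0.3 | 0.2 / 0.3 | recovery kinetics |
| time scale | 6 ms | 6 ms | physical ms per model time unit |
| D (longitudinal) | 0.599 mm²/ms | 0.161 mm²/ms | calibrated conductivity |
| anisotropy | 5:1 | 8:1 | conductivity-tensor ratio |

The fibrotic set represents remodeling by parameter scaling: the raised
threshold is the analog of reduced sodium-channel availability (slower CV at
matched conductivity), the reduced eps0 the analog of action-potential
prolongation under remodeled calcium/potassium currents (APD ≈ 155 ms vs
≈ 115 ms non-fibrotic at matched conductivity). The steep APD contrast is
what lets incremental burst pacing produce conduction block and reentry at
fibrosis border zones in 2D, standing in for the geometric complexity of
real bi-atrial anatomy.

Calibration:

- `calibrate_conductivity` bisects (secant on the sqrt-conductivity law) the
  longitudinal conductivity until planar CV on a 60 x 15 mm slab matches the
  target (43.39 cm/s non-fibrotic, 20 cm/s fibrotic; default tolerance 2%).
  Activation times are probe crossings of V = 0.5 with sub-step
  interpolation, probes >= 20 mm apart and 5 mm from the edges.
- `calibrate_rotor_frequency` adjusts the membrane time constant until the
  dominant frequency of the reference rotor is 3.6 +- 0.4 Hz. The rotation
  period of an Aliev-Panfilov spiral in this regime is set by the kinetic
  time scale (it proved insensitive to eps0 and unstable under mu1 changes),
  and co-scaling conductivity proportionally to the time constant holds
  planar CV fixed while the period moves — so the search is monotone and
  converges in one or two evaluations.
- The anisotropy ratios are interpreted as conductivity-tensor ratios
  (velocity ratios are then their square roots); the source description is
  ambiguous between conductivity and velocity.

The reference rotor induction is cross-field S1-S2: a plane wave from the
left edge, then a half-field stimulus timed into the repolarization tail
(base timing measured from the sheet center's recovery, scanned over a small
deterministic offset list until the induced activity outlives the check
window). Stimulus amplitudes are expressed as multiples of the numerically
measured diastolic threshold (bisection on a small patch, 2-ms pulse).

Incremental burst pacing defaults to 10-beat trains at cycle lengths
300 -> 200 ms in 20-ms decrements, 2-ms stimuli at twice diastolic
threshold from a 1.5-mm-radius site, with a 6-s post-pacing observation
window; the end-to-end pipeline uses a shortened schedule (6-beat trains at
200/180/160 ms) that drives the fibrotic border into block at desk-scale
cost. Pacing-site distribution is greedy farthest-point sampling over
conductive tissue, seeded. Observation terminates early once all activity
has died out.

## Rotor analysis

Phase is computed per node by time-delay embedding
`atan2(V(t - tau) - Vbar, V(t) - Vbar)` with a sliding 1-s mean. The
embedding delay must lie within the action-potential pulse width, otherwise
the embedded loop collapses and no topological defect exists; the default
tau = 50 ms is about 40% of the calibrated APD. Phase singularities are
plaquette winding numbers (sum of wrapped phase differences around every
2 x 2 cell loop equal to +-2 pi); the detector is exactly equivalent to
brute-force winding computation. Trajectories are greedy nearest-neighbour
links (same charge, 2-mm per-frame gate, 20-ms gap closing); rotors are
tracks persisting > 5 s. Rotor location is the trajectory centroid; meander
extent is the maximum pairwise trajectory distance, and extents > 12 mm flag
a wide meander (the lesion then becomes a covering ellipse with 12-mm minor
axis along the principal meander axis). Dominant frequency is the spectral
peak (0.25-Hz resolution by zero padding, Hann window, 1-15 Hz band) of the
mean probe signal over the final 3 s. Rotor identity across simulations is
greedy mutual-nearest centroid matching within 6 mm (half the lesion
diameter: a rotor reappearing inside a would-be lesion footprint is the same
target); unmatched new centroids are emergent.

## Ablation planning

The inducibility oracle abstracts "apply these lesions, burst-pace from
every site, report which rotor locations still sustain rotors". It is
memoized; the scripted backend answers from an exhaustive dependency table,
the simulator backend runs the pacing sweep and matches rotor centroids
against its registry.

Classification probes single lesions first: a rotor suppressed by ablating
some other single location is contingent (LCR), one that survives every
probe independent (LIR). When no single-lesion probe suppresses anything
(mutual independence at the single-lesion level, as in the second worked
patient case), probing escalates to pairs. The published operation
description stops at single-lesion probes, but its own worked example
requires the pair information, so the escalation is included; full subset
enumeration remains reserved for the brute-force verifier.

The guided search loop: classify, ablate all LIRs, re-test; when rotors
remain but none is independent, ablate one LCR (highest regional fibrosis
density, ties to lowest id); stop at non-inducibility. Termination is
guaranteed on consistent oracles (every iteration ablates at least one rotor
from a finite universe); a suppressed rotor reappearing raises a
contract-violation error. The all-at-once comparator ablates every induced
rotor, re-tests, ablates emergents, and repeats.

iAT screening: a lesion whose boundary touches a non-conductive barrier
cannot support macro-reentry around itself and is excluded outright.
Otherwise the pacing protocol runs on the lesioned substrate and iAT is
declared when the phase sampled on a closed contour 2 mm outside the lesion
boundary carries a net winding of +-2 pi for a contiguous span longer than
5 s covering at least 3 cycles, with no sustained phase singularity in bulk
tissue (macro-reentry around the lesion rather than a rotor). The 2-mm
offset and 3-cycle minimum are this package's operationalization of a
visually diagnosed phenomenon; both are configurable. Connecting lines run
straight from the lesion boundary to the nearest barrier point (Euclidean
boundary-to-boundary; the geodesic alternative is not meaningful on a flat
sheet), with width defaulting to the 7.5-mm band width.

The brute-force verifier enumerates all ablation subsets (refusing above 8
rotors), iterates each subset's closure (ablate, re-query, ablate emergent),
and reports all minimal sufficient subsets plus the essential rotors
(members of every minimal sufficient subset). Guided-search guarantees
checked by property tests: never misses an essential rotor, never exceeds
the all-at-once plan size, stays within an n^2 + 3n memoized query budget.

## Statistics layer

Mann-Whitney U (exact enumeration when n1*n2 <= 200 and tie-free, otherwise
tie-corrected normal approximation; reported as min(U1, U2)); ROC with AUC
as concordance probability and the cutoff maximizing sensitivity +
specificity (ties to the lower cutoff), AUC CI by seeded stratified
bootstrap (2,000 resamples — the original analysis does not name its CI
method); Spearman rank correlation; a regression screen that admits
univariate predictors at P < 0.1 into one multivariate linear fit and
ln-transforms the response after a failed Shapiro-Wilk residual-normality
check (alpha = 0.05, requires positivity). Accuracy at the cutoff is
(TP + TN)/N. The cohort report assembles LIR-vs-LCR and iAT-vs-free
comparisons, ROC cutoffs and burden correlations into CSV/JSON plus figures,
deterministically under a fixed seed.

## Problem sizes and numerical choices

Desk-scale defaults: 50 x 50 mm sheets (167 x 167 cells), 12 pacing sites,
6-beat trains at three cycle lengths, 6-s observation, 5-ms recording
interval, 8-s reference rotor runs. These sizes keep a full pipeline run in
the tens of minutes on one CPU while leaving every qualitative contrast
intact. Degenerate inputs are handled explicitly: burden 0/100 shortcut the
generator; flat signals are flagged undefined for phase and frequency;
empty footprints, masks and groups raise informative errors; the solver
aborts on CFL violation or non-finite voltages, naming the step.

## What passing tests do and do not show

The synthetic substrates reproduce the structural regimes the method
distinguishes (border zones vs compact islands, fractionated vs clean
electrograms, contingent vs independent rotor dependency) with exact ground
truth, so the pipeline's logic — segmentation, metrics, detection, planning,
statistics — is tested end to end. They do not emulate bi-atrial anatomy,
fiber architecture, MRI artifacts, far-field electrogram contamination, or
the ionic detail of remodeled human atrial myocytes; quantitative results on
real patient data (cohort statistics, published thresholds and AUCs) are
out of scope by design, and the cohort-statistics machinery is validated on
synthetic cohorts with known effects instead.

## Known limitations

- 2D sheets only; no surface meshes or volumetric solvers.
- The membrane model reproduces emergent propagation constants, not ionic
  currents; its action potentials are shorter than human atrial ones and
  the time constant doubles as the frequency-calibration knob.
- Reentry induction by pacing relies on the steep APD contrast between
  fibrotic and normal tissue; substrates without fibrotic border zones
  rarely induce (matching the method's premise, but worth noting).
- The iAT criterion is a contour-winding operationalization of a visual
  diagnosis; near-threshold episodes (slow conduction around small lesions)
  may be classified either way.
- The exhaustive verifier is exponential and refuses above 8 rotors.
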