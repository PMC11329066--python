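# atrialdt

Desk-scale digital-twin pipeline for assessing the arrhythmogenic propensity
of fibrotic atrial substrate, written for computational electrophysiologists
and methodologists who want the full workflow — substrate, simulation, rotor
mapping, ablation planning, statistics — runnable on a laptop with fully
synthetic, ground-truthed inputs.

In patients with persistent atrial fibrillation, fibrotic remodeling creates
substrate locations that attract sustained reentrant drivers (rotors).
Ablating every rotor location is over-treatment: some locations are
*contingent* (LCR) — they lose inducibility once another location is ablated
— while others are *independent* (LIR) and must be ablated. This package
implements the guided-search classification and the lesion-minimizing
planner around a monodomain reaction-diffusion simulator, plus the imaging
and electrogram analyses that look for clinical signatures of those types:

- **synthetic_substrate** — fibrosis fields (diffuse / compact islands /
  interdigitated border zones), 3D LGE phantoms, fractionated bipolar
  electrograms, and scripted rotor-dependency fixtures with exact ground
  truth, including the three worked patient cases.
- **lge_segmentation** — image-intensity-ratio (IIR) and personalized IIR
  (PIIR) fibrosis segmentation: voxels with IIR above `k ·` (mean aorta IIR)
  are fibrotic; gain- and contrast-clearance-invariant.
- **fibrosis_metrics** — fibrosis density FD (%) and fibrosis entropy FE
  (binary Shannon entropy of 2.5-mm-kernel occupancy, bits) with regional
  values over lesion footprints; 12-region assignment.
- **ep_simulator** — monodomain solver (0.3-mm lattice, two-variable
  membrane model) calibrated to planar CV 43.39 / 20 cm s⁻¹ (non-fibrotic /
  fibrotic, anisotropy 5:1 / 8:1) and a 3.6-Hz reference rotor; burst-pacing
  protocols, lesions, barriers.
- **rotor_analysis** — time-delay-embedding phase maps, phase-singularity
  detection (plaquette winding numbers) and tracking, the 5-s persistence
  rule, meander, dominant frequency, rotor-location matching.
- **ablation_planner** — memoized inducibility oracles (scripted and
  simulator-backed), LIR/LCR classification, guided lesion-minimizing
  search, all-at-once comparator, iAT (macro-reentry around a lesion)
  detection, connecting lines to barriers, and a brute-force verifier.
- **egm_features** — bipolar voltage statistics and FAAM/ICL fractionation
  (deflections 0.1 mV to atrium max; intervals ≤ 10 ms; ICL% relative to
  the atrium-wide maximum).
- **stats_reporting** — Mann-Whitney U, ROC with the
  sensitivity+specificity-maximizing cutoff, Spearman, a P < 0.1 univariate
  regression screen with ln-transform fallback, and the cohort report.
- **pipeline** — end-to-end orchestration on a synthetic sheet.

## Worked example

Classify the second worked patient case and plan its ablation:

```python
from atrialdt.synthetic_substrate import builtin_patient_fixture
from atrialdt.ablation_planner import script_oracle, guided_search, all_at_once

script = builtin_patient_fixture(2)
plan = guided_search(script_oracle(script))
print(plan.lesion_ids, plan.classification, plan.final_inducible)
comparator = all_at_once(script_oracle(script))
print(comparator.n_lesions)
```

prints

```
['A', 'C'] {'A': 'LIR', 'B': 'LCR', 'C': 'LIR', 'D': 'emergent-LCR'} False
4
```

The guided search recognizes that rotor B is contingent on the two
independent locations A and C, reaches non-inducibility with two lesions,
and records the emergent location D (uncovered when probing {B, C}) without
ablating it — whereas the type-blind all-at-once strategy needs four
lesions (A, B, C, then the emergent D).

Simulate and measure the calibrated reference rotor:

```python
from atrialdt import ep_simulator as ep
from atrialdt.rotor_analysis import analyze_recording

params, d_long, freq = ep.calibrate_rotor_frequency()
print(round(freq, 2))                   # 3.52  (Hz, target 3.6 +- 0.4)
sheet = ep.fibrotic_reference_sheet(50.0, membrane=params, d_long=d_long)
rec = ep.induce_rotor_s1s2(sheet, duration_s=8.0)
rotor = analyze_recording(rec, persistence_s=5.0)[0]
print(round(rotor.lifetime_s, 1), rotor.chirality)   # 7.7 1
```

Run the full pipeline on a synthetic interdigitated-border sheet (tens of
minutes on one CPU: every inducibility query is a 12-site pacing sweep):

```python
from atrialdt.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=0))
print(result.plan.lesion_ids, result.plan.final_inducible)
print(result.cohort_table[["location_id", "type", "fd", "fe"]])
```

See `docs/methods.md` for the model, its calibration, and all numerical
choices.

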