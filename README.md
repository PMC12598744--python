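# ocugaze

Automated gaze-angle optimization for ocular proton therapy (OPT) treatment
planning, with toxicity-risk (NTCP) evaluation.

In OPT the patient fixates a gaze target during irradiation; the gaze
direction determines the eye's orientation and hence which healthy ocular
structures — macula, optic disc, cornea, retina, ciliary body, lens — the
proton beam traverses. Target coverage is guaranteed by the spread-out Bragg
peak (SOBP) extent and a patient-specific aperture, so organ-at-risk sparing
is achieved *only* through the choice of gaze angle. `ocugaze` automates that
choice for planners and medical physicists: it predicts a promising fixation
point from the patient's geometry with a random forest, explores the feasible
gaze space with a two-density Poisson-disk sampler, scores every candidate
orientation with a simplified passive-scattering dose model, and presents the
results as continuous 2D cost and NTCP maps of the fixation plane.

## The optimization

A candidate orientation `O` is a fixation point on the plane 132.5 mm
upstream of the isocentre, inside the clinical polar-angle limit of 25°. The
planner's objective is

    minimize over O:   C(O)

with the healthy-tissue penalty (target coverage is deliberately absent)

    C = Σᵢ (wᵢ/M) Σⱼ V_dⱼ(OARᵢ)                      M = 20 levels V5 … V100
      + w_mac·D2%(macula)  + w_od·D20%(optic disc) + w_cor·D20%(cornea)
      + w_ret·V55GyRBE(retina) + w_cil·V27GyRBE(ciliary body) + w_lens·D5%(lens)

where Dx% is the minimum dose to the hottest x% of a structure and V_D the
volume fraction receiving ≥ D. The macula and optic disc carry weight 3, all
other OARs weight 1. The six named dose-volume points are the published
predictors of maculopathy, optic neuropathy, neovascular glaucoma, secondary
ischemic retinal detachment and cataract; each is additionally mapped to a
toxicity probability through a two-parameter logistic NTCP curve
`NTCP(m) = 1/(1+exp(−(m−m50)/k))`. Fractionation differences are handled with
the biologically effective dose `BED = n·d·(1 + d/(α/β))`, α/β = 1 for ocular
tissue (4×15 GyRBE gives 960 GyRBE).

Candidate sampling follows five steps: (1) the forest prediction defines a
denser region of 50 mm radius; (2) dart-throwing samples with ≥ 9 mm spacing
fill it and enter a FIFO queue nearest-to-prediction first; (3) the remaining
disk is sampled at ≥ 25 mm spacing and appended; (4) each candidate is
oriented, checked against the 35 mm range and aperture limits, and scored;
(5) the scattered evaluations are interpolated into continuous cost/NTCP
maps. A full run evaluates roughly 35 fixation points instead of a
400-point exhaustive sweep. Automated and reference plans are compared
per-endpoint with a 1-percentage-point NTCP threshold and classified as
improved / neutral / trade-off / inferior.

## Worked example

```
$ ocugaze synthesize -n 3 --seed 7 --out cohort
wrote 3 patients to cohort
$ ocugaze optimize cohort/patient_000.json --seed 1 --map cost --out run
best fixation (-55.2, 20.1) mm, polar 23.9 deg, cost 104.23 (34 candidates)
```

The synthetic patient has a dome-shaped tumor on the inner eye wall; the
optimizer evaluated 34 candidate gaze directions and recommends fixating at
(−55.2, 20.1) mm on the fixation plane — a 23.9° polar gaze that rotates the
tumor toward the beam while moving the anterior segments and the
macula/optic-disc complex out of it. `run/records.csv` holds one row per
candidate (plane coordinates, treatability, cost, the six dose-volume points
and the five NTCP values); `run/map_cost.csv` is the interpolated cost map on
a regular raster; `run/manifest.yaml` records the seed, counts and best
candidate so the run can be replayed exactly.

The same operations are available as a library:

```python
from ocugaze import synthesize_cohort, run_optimization, plane_from_angles

model, spec = synthesize_cohort(1, seed=7)[0]
result = run_optimization(model, prediction=plane_from_angles(22, 160))
print(result.best.cost, result.best.ntcp)
```

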