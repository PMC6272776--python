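# hostguest

Profiling toolkit for host–guest inclusion complexes: molecular
lipophilicity potential (MLP) fields, binding-pocket polarity scoring,
docking-energy post-processing, and Transwell blood–brain-barrier
permeability analysis.

The motivating problem is a drug-delivery one: a volatile, highly
lipophilic anesthetic (a fluorinated ether, logP ≈ 2.4) cannot be injected
intravenously on its own, but forms a reversible inclusion complex inside
the hydrophobic cavity of an amphiphilic sulfobutylether-β-cyclodextrin
host.  Three quantitative questions decide whether such a formulation
works, and this package computes all three:

1. **How polar is the binding cavity?**  The MLP at a point *k* is
   MLP(k) = Σᵢ fᵢ·fct(d_ik) — a distance-weighted sum of atomic lipophilic
   constants.  Fitting points placed in the pocket give the lipophilicity
   index LI = |Σ⁺|/(|Σ⁺|+|Σ⁻|)×100 %, with LI < 10 % marking a polar
   site; the same sums back-calculate logP_MLP = Σ⁺w⁺ + Σ⁻w⁻ + C after
   calibration against experimental logP values.
2. **How tightly is the guest held?**  Docking poses are clustered at 2 Å
   RMSD, the top-3 energies summarized, and ΔG_bind converted to a
   dissociation-scale binding constant K = exp(ΔG/RT).  ΔG ≤ −6.0
   kcal·mol⁻¹ counts as high affinity; millimolar K means weak binding and
   rapid drug liberation — desirable for an anesthetic that must escape
   its carrier.
3. **Does the complex cross the barrier?**  From basolateral time-courses
   (with correction for aliquot sampling and medium replacement), the
   initial slope of the cumulative concentration gives
   P_app = (dQ/dt)·V_b/(A·C₀); P_app > 1×10⁻⁶ cm·s⁻¹ is high permeation
   potential, > 2×10⁻⁶ cm·s⁻¹ indicates > 90 % bioavailability.

A seeded synthetic-data module generates cage hosts of tunable cavity
polarity, Transwell time-courses (linear sink or two-compartment
saturating), and docking-pose ensembles, so the full pipeline runs and is
tested without any external downloads.

## Worked example

```bash
$ hostguest simulate --seed 7 --outdir synthetic
wrote host.xyz, poses.csv, timecourse.csv to synthetic

$ hostguest affinity synthetic/poses.csv
{
  "affinity_class": "low",
  "mean_dg": -1.8184358992952996,
  "mean_k_mM": 46.51570558436412,
  "n_poses": 3,
  "sd_dg": 0.035902853975385146,
  "sd_k_mM": 2.767847231318624,
  "temperature_K": 298.15
}

$ hostguest papp synthetic/timecourse.csv --c0 1e5
{
  "fit_coefficients": [
    -5.500505978185333,
    0.44334741952255485,
    6.742664814924341e-06
  ],
  "n_points_used": 5,
  "papp_cm_s": 1.1875377308639863e-05,
  "permeation_class": "high_bioavailable",
  "slope": 0.44334741952255485
}
```

Reading the numbers: the pose ensemble was generated around
−1.727 kcal·mol⁻¹, and the mean of its three best energies
(−1.82 kcal·mol⁻¹) converts to a 46.5 mM dissociation constant — far above
the −6.0 kcal·mol⁻¹ high-affinity cutoff, i.e. the guest is held loosely
and will liberate quickly.  The time-course was simulated at a true
P_app of 12.32×10⁻⁶ cm·s⁻¹ with 5 % measurement noise; the estimator
recovers 11.88×10⁻⁶ cm·s⁻¹ (≈4 % off) and classifies the complex in the
>90 %-bioavailability band.  The `slope` is the initial rise of the
cumulative basolateral concentration in µg·mL⁻¹·s⁻¹.

The same stages are available as library calls (`hostguest.binding`,
`hostguest.transwell`, `hostguest.pocket`, `hostguest.mlp`,
`hostguest.synthetic`), and `hostguest profile config.yaml` runs
everything end-to-end into one JSON report.

See `docs/methods.md` for the models, defaults and their rationale.

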