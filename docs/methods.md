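# Methods

`hostguest` profiles host–guest inclusion complexes — the motivating system
is a volatile anesthetic guest inside a sulfobutylether-β-cyclodextrin-like
cage — along three computational axes: lipophilicity fields around and
inside the host, post-processing of docking energies into binding
constants, and apparent permeability from Transwell barrier assays.  This
note records the models, the defaults and the design choices behind them.

## Molecular lipophilicity potential

The MLP at a spatial point *k* is a distance-weighted sum of per-fragment
lipophilic constants,

    MLP(k) = Σ_i f_i · fct(d_ik),

where *i* runs over the molecule's fragments (here: heavy atoms), f_i is
the fragment's lipophilic constant and d_ik the fragment–point distance in
Å.  Positive MLP marks hydrophobic space, negative MLP polar space.

Choices:

* **Distance function.** Default `exponential`, fct(d) = exp(−d/2), with a
  10 Å cutoff; a `hyperbolic` form 1/(1+d) is available for sensitivity
  analysis.  Both are classical choices in the MLP literature; neither is
  privileged by theory, so the cutoff-free brute-force evaluation is kept
  as a test oracle and the two forms can be swapped via configuration.
* **Fragment system.** The packaged `default.tsv` is an element-level table
  in the lineage of the published atomic fragmental systems (Broto,
  Ghose–Crippen): carbon and the heavier halogens positive, N/O/F negative.
  Hydrogen contributions are folded into the heavy-atom constants, since
  the pipeline operates on heavy atoms; explicit-H tables can be supplied
  as user TSVs (2 columns, `#` comments).  The table is deliberately
  coarse — it fixes signs and magnitudes at the "element chemistry" level
  and makes no claim to reproduce any specific program's calibrated
  per-atom-type values.
* **Surface sampling.** Solvent-accessible surface points come from
  deterministic Shrake–Rupley-style sampling: a golden-spiral lattice of
  `points_per_atom` (default 100) points per atom on the probe-inflated
  sphere (probe 1.4 Å), with points buried inside any other inflated
  sphere removed.  The lattice is expressed in the molecule's principal-
  axes frame (axis signs fixed by coordinate skewness), which makes the
  point set rigid-motion covariant for generic molecules; perfectly
  symmetric coordinate sets fall back to a deterministic but arbitrary
  orientation.  A point lying exactly on another atom's sphere (within
  1e-9 Å) is kept only for the lowest-index atom, so exactly duplicated
  atoms contribute a single sphere.

## logP back-calculation and its calibration

Splitting a field into its hydrophobic and polar sums, Σ⁺ = Σ max(MLP, 0)
and Σ⁻ = Σ min(MLP, 0), the partition coefficient is back-calculated as

    logP_MLP = Σ⁺·w⁺ + Σ⁻·w⁻ + C.

(w⁺, w⁻, C) are fitted by ordinary least squares on the design (Σ⁺, Σ⁻, 1)
against experimental logP values; no regularisation is used because the
intended training sets are small and synthetic, and the fit refuses
rank-deficient designs (e.g. all-hydrophobic training fields).  **No
calibrated weights are shipped**: the defaults (1, 1, 0) produce relative
values only, and the library warns when they are used.  Consequently the
package asserts only sign and ordering behaviour of logP_MLP (a
hydrophilic host below the intercept, a lipophilic guest above), never
absolute literature values.

## Pocket lipophilicity index

Fitting points for a binding pocket are cubic-grid nodes (default spacing
1 Å) inside a sphere (default radius 5 Å), minus nodes buried in the
host's van der Waals volume, ordered lexicographically by (x, y, z).  The
pocket's polarity score is the lipophilicity index

    LI = |Σ⁺| / (|Σ⁺| + |Σ⁻|) × 100 %,

with LI < 10 % read as a polar site.  The 10 % boundary itself is assigned
to non-polar because the polar class is defined by a strict inequality.
An all-negative field gives LI = 0 (well defined); only an all-zero field
makes LI undefined and raises.  Where a pocket center is not supplied, the
profile pipeline centers on the molecule's centroid; the docking-box
convention (56.49, 12.97, 9.29) Å is retained as the default
`PocketDefinition` center for workflows that reuse receptor-frame
coordinates.

## Binding affinity post-processing

Docking poses are clustered greedily in energy order: the lowest-ΔG
unassigned pose seeds a cluster and absorbs all poses within 2 Å RMSD of
it.  RMSD is computed **without** superposition — poses share the receptor
frame, and Kabsch alignment would cancel the translational differences the
threshold is meant to separate.

The top-k (default 3) lowest-energy poses are summarized as mean ± sample
standard deviation of ΔG_bind; each pose's energy is also converted to a
dissociation-scale constant

    K = exp(ΔG / RT),   R = 1.9872 × 10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K,

and the per-pose constants are averaged on the mM scale.  This
dissociation-scale convention is the one under which a ΔG of
−1.727 kcal·mol⁻¹ maps to ≈54 mM — i.e. weak binding and fast guest
liberation; the inverse-association reading would give meaningless
sub-molar⁻¹ magnitudes for such shallow minima.  ΔG_bind ≤ −6.0
kcal·mol⁻¹ is classed as high affinity (boundary inclusive).

Note that averaging per-pose constants is not the same as converting the
mean energy: the exponential is convex, so the mean constant from a spread
of energies exceeds the constant of the mean energy. Both numbers are
derivable from a `BindingSummary`; reports should state which they quote.

## Transwell apparent permeability

The assay geometry defaults to a 0.336 cm² filter, 0.9 mL basolateral
chamber, 0.3 mL apical chamber and 100 µL sampling aliquots.  The apical
volume is not prescribed by the assay conventions the defaults follow; 0.3
mL is the standard fill of a 24-well insert of this membrane area and only
enters the two-compartment simulation rate constant, not the P_app
estimator.

Each drawn aliquot is replaced by drug-free medium, so measured
concentrations under-count transport.  The correction assumes the
concentration is measured at draw time and reconstructs cumulative
transported mass as

    Q_i = V_b·C_i + V_sample·Σ_{j<i} C_j   (µg);

an uncorrected mode (`correct_sampling=False`) is available for
comparison.  The cumulative concentration Q/V_b is fitted with a quadratic
in time (internally seconds; the fit is computed on scaled time and
back-transformed, keeping the normal equations well conditioned), the
initial slope is extracted — default: the fit's derivative at t = 0;
alternative: a linear refit through the first k (default 3) points — and

    P_app = (dQ/dt) · V_b / (A · C_0)   (cm·s⁻¹).

Classification: P_app > 1×10⁻⁶ cm·s⁻¹ high permeation potential,
> 2×10⁻⁶ cm·s⁻¹ consistent with > 90 % bioavailability, boundaries
assigned downward (the rules are strict >).  Flux reversal (late-time
concentration decline) only warns; late points can be excluded with
`max_time_min`.  `dose_equivalent(c, f) = c/f` converts a free-drug target
concentration into the complex concentration at drug mass fraction f.

## Synthetic data

The generators produce inputs with the statistical and geometric structure
the pipeline assumes, with every draw controlled by a single seed
(independent child streams per generator).

* **Cage host** — two concentric coplanar rings of pseudo-atoms (default 8
  per ring at radii 6.0 and 10.8 Å, vdW 1.5 Å), inner ring typed
  `cage_interior`, outer `cage_exterior`; the central cavity of radius
  half the ring radius is guaranteed atom-free.  This caricatures an
  amphiphilic torus: the interior/exterior constants are free parameters,
  so polar-pocket and hydrophobic-pocket regimes are both one spec away.
  It does not model glycosidic geometry, substituent flexibility, or any
  specific cyclodextrin.
* **Transwell time-courses** — `sink_linear` transports mass at the
  constant sink-condition flux P·A·C₀ (default truth 12.32×10⁻⁶ cm·s⁻¹ at
  C₀ = 100 mg·mL⁻¹); `two_compartment` relaxes exponentially toward the
  mixing equilibrium with rate k = P·A·(1/V_a + 1/V_b), which reproduces
  the early linear rise and later flattening seen in real acceptor
  curves.  Sampling times default to 5/15/30/60/120 min; the aliquot
  draw/replacement bookkeeping is simulated explicitly, so the analysis
  correction inverts it exactly.  Measurement noise is multiplicative
  Gaussian (default sd 5 %), concentration-proportional as LC-MS-style
  quantification behaves near its floor; an optional censoring flag zeroes
  readings below 2.5 µg·mL⁻¹.  Volatility losses and serum-protein binding
  are not modelled — recovery results on synthetic data therefore bound
  estimator error, not assay error.
* **Pose ensembles** — energies i.i.d. Normal(mean_dg, sd_dg) (defaults
  −1.727 ± 0.042 kcal·mol⁻¹, n = 100 matching a typical genetic-algorithm
  docking run count), coordinates a fixed guest template (the packaged
  12-heavy-atom fluorinated-ether conformer) plus isotropic per-atom
  Gaussian jitter.  Real docking energies are neither independent nor
  Gaussian; the generator only reproduces the summary structure the
  post-processing consumes.

## Problem sizes and tolerances

The test suite and the acceptance script run the pipeline at small,
self-contained sizes chosen to exercise every code path: 50 random
molecules of up to 50 atoms for the brute-force MLP cross-check (agreement
demanded at 1e-9), 200 seeded replicates for noisy permeability recovery
(median relative error required < 10 %; observed ≈ 7 %), 10 training
records for calibration recovery (1e-9), and noiseless permeability round
trips at truths of 1, 5 and 12 ×10⁻⁶ cm·s⁻¹ (1e-6 relative; observed at
machine precision).  Everything completes in seconds on one CPU.

## Known limitations

* The packaged fragment table is element-level; typed tables (aromatic vs
  aliphatic carbon, etc.) must be user-supplied.
* Absolute logP_MLP values require a user calibration; none is shipped.
* The guest conformer fixture is a generated, minimized geometry, not an
  experimental structure.
* The surface sampler's rigid-motion covariance degrades for exactly
  symmetric atom arrangements (frame degeneracy); determinism is retained.
* Pose clustering is greedy and threshold-based; it is not a substitute
  for density-based conformational clustering on large ensembles.
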