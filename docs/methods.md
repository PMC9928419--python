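# Methods

This note records the models implemented in `rpitriage`, the defaults and
why, what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## 1. MD filter score (`rpitriage.energetics`)

A docked, MD-refined ligand pose is scored from two observables:

* **ΔΔH = H_LP − H_LW** — the per-frame difference between ligand–protein
  and ligand–water interaction enthalpies over a short trajectory.
  `delta_delta_H` returns the time average and the n−1 sample SD of the
  per-frame values.  A negative average means the ligand prefers the pocket
  over the solvent.  No autocorrelation correction is applied to the SD:
  trajectory frames are correlated, so the SD describes the fluctuation
  scale (typically 2–7 kcal/mol for drug-like ligands), not a standard
  error of the mean.  This is a documented limitation, accepted because the
  score is a coarse triage filter, not an estimator with error bars.
* **c** — unique interatomic ligand–pocket contacts per interacting ligand
  atom, counted once on the refined structure (not averaged over frames).
  c ≥ 1 whenever the contact set is non-empty; an empty set flags an
  effectively unbound ligand (c = 0 with a warning).

The weighted score is `S = w_c·c + w_ΔΔH·⟨ΔΔH⟩` with defaults `w_c = 4`,
`w_ΔΔH = −1`, chosen so a well-packed ligand (c ≈ 2–3) outweighs a modest
solvent preference.  Classification: `hit` if S > 0; `possible` if S ≤ 0 but
S + σ_ΔΔH > 0 (the sign is within statistical error); `rejected` otherwise;
`left_pocket` when the upstream short-MD retention check failed.  An
alternative "possible" policy (σ_ΔΔH > |⟨ΔΔH⟩|) exists in the literature on
this filter; both are implemented, the error-adjusted rule is the default
because it is the one applied at the decision step.  Internal energy unit is
kcal/mol; traces tagged kJ/mol are converted on read (÷4.184), which
commutes with averaging.

Pocket retention is accepted as an upstream boolean because trajectory
geometry processing is out of scope; the module consumes tables any MD
engine can export.

## 2. Absolute binding free energies (`rpitriage.free_energy`)

### BAR

Each λ window stores bidirectional energy differences
ΔU = U(λ_{i+1}) − U(λ_i), sampled at λ_i (forward) and λ_{i+1} (reverse).
`bar_window` solves the Bennett self-consistency equation

    Σ_f 1/(1 + exp(M + β(W_f − ΔF))) = Σ_r 1/(1 + exp(−M + β(W_r + ΔF)))

with forward work W_f = ΔU_f, reverse work W_r = −ΔU_r and
M = ln(n_f/n_r), by bracketed Brent root finding to 1e−8 kcal/mol.  The
error is the asymptotic variance at the solution,

    β²·var(ΔF) = (⟨a²⟩/⟨a⟩² − 1)/n_f + (⟨b²⟩/⟨b⟩² − 1)/n_r ,

with a, b the Fermi weights of the two sides.  Overlap is diagnosed from
those weights: a window is flagged when the effective sample size
(Σa)²/Σa² falls below 1.5 on either side *or* the mean weight collapses
below 1e−6 (all samples far from the crossover region — there the variance
formula is meaningless, so the error is replaced by a finite sentinel,
999 kcal/mol, and a warning).  Window totals add linearly; errors add in
quadrature assuming independent windows.

### Restraint correction

Decoupling in the complex runs under one distance, two angle and three
dihedral harmonic restraints (U = K/2·(ξ−ξ0)²; defaults K_r = 1000
kcal·mol⁻¹·nm⁻², angular/dihedral K = 10 kcal·mol⁻¹·rad⁻²).  Releasing the
restrained, decoupled ligand to the 1 M standard state costs

    ΔG_r = −RT ln[ 8π² V0 / (r0² sinθ_A0 sinθ_B0) · (K_r K_θA K_θB K_φA K_φB K_φC)^½ / (2πRT)³ ]

with V0 = 1.6606 nm³.  This closed form is the stiff-restraint
(stationary-phase) evaluation of the restrained configurational integral:
the Jacobian r² sinθ_A sinθ_B is held at the reference geometry.
`restraint_correction_quadrature` integrates that same model numerically
(our correctness oracle for every factor of the formula), and with
`full_jacobian=True` integrates the exact Jacobian instead; the difference
measures the stiff-spring approximation error, ≈0.034 kcal/mol at the
default angular stiffness (each angle contributes ≈ RT·σ²/2 with
σ² = RT/K_θ), shrinking as 1/K.  This error is inherent to the analytical
formula, well below the 0.3–1.0 kcal/mol statistical errors of the windows,
and is deliberately not "corrected".

### Cycle, thresholds, Kd

Sign convention, fixed in `assemble_cycle`:
ΔG_bind = −ΔG_decouple,complex + ΔG_decouple,solvent + ΔG_r.  Hit
thresholds compare magnitudes — |ΔG| ≥ 5.5 kcal/mol, or ≥ 6.5 for ligands
that only passed the MD filter as "possible" — because computed binding
free energies are negative by construction and the triage literature quotes
them both ways.  Kd = exp(ΔG/RT)·1 M with R = 1.98720425×10⁻³
kcal·mol⁻¹·K⁻¹ and default T = 298.15 K.  `kd_interval` propagates a ΔG
error multiplicatively (×/÷ exp(err/RT), a factor ≈2.3 per 0.5 kcal/mol);
published error bands quoted as ±50% for ±0.5 kcal/mol are looser than
this exact propagation, and we do not force agreement.

### ITC

`fit_one_site` fits the single-site (Wiseman) isotherm with the standard
perfusion-cell bookkeeping: after cumulative injection v into cell volume
V0, active concentrations are M = M0(1 − v/2V0)/(1 + v/2V0) and
X = X_s(v/V0)/(1 + v/2V0), and the heat of injection i is
Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2.  The instrument software's
exact displacement correction is unpublished; this standard model agrees
with it to well under the fit's statistical error at c-values near 2
(c = n·M0/Kd ≈ 2.3 for the reference design: 14 µM cell, 26 × 1.5 µL of
200 µM).  Parameters (log Kd, ΔH, n) are estimated by Levenberg–Marquardt
least squares; a flat heat curve is flagged non-identifiable, a negative
fitted stoichiometry warns.

## 3. NMR analytics (`rpitriage.nmr`)

### CSP

Default form Δδ = √(0.5·[ΔδH² + (0.14·ΔδN)²]).  The convention this
weighting comes from includes the square root, and the ~0.03 ppm pocket
averages reported for flavonoid binders are only consistent with the √
form; the no-root variant is retained as `form="literal"` because the
source equation is printed without it.  Residues present in only one
condition are warned about, never silently dropped.  Side-chain peaks
(e.g. W65sc) are independent rows with their own IDs.

A ligand is called a binder when its pocket-average CSP exceeds the mean +
1 SD of the non-pocket residues (threshold multiplier configurable; no
universal significance threshold exists for CSPs, so the background of the
same spectrum is the reference).  The default pocket set is the eight
flavonoid-pocket residues W65, V84, F85, V86, G116, K118, G119, A120.

### PCA mining

The ligand × residue CSP matrix (reference size 15 × 20) is column-mean
centered without variance scaling (all cells share ppm units; scaling is
optional).  PCA scores feed three diagnostics:

* **SPE** (squared residual off the retained subspace) with the
  Jackson–Mudholkar χ²-approximate (1−α) limit from the residual
  eigenvalues;
* **Hotelling's T²** within the subspace.  The limit uses the Phase-I beta
  form (n−1)²/n · B(1−α; k/2, (n−k−1)/2).  The more familiar Phase-II
  F form k(n−1)(n+1)/(n(n−k))·F applies to *future* samples; at n = 15,
  k = 6 it exceeds (n−1)²/n ≈ 13.07, the mathematical maximum of an
  internally studentized T², so it can never flag a sample that helped
  build the model.  Same-sample outlier mining therefore requires the
  Phase-I limit.
* **k-means** on the retained scores with k = 5 and 50 restarts under a
  fixed seed (five clusters is the reference analysis on both the matrix
  and its transpose); hierarchical clustering is the conventional
  alternative and can be run on the same scores.

### RNA-competition scalar product

For each residue, u, v, w are the peak displacements from apo induced by
ligand, RNA, and RNA+ligand, in scaled (¹H, 0.14·¹⁵N) coordinates.  The
statistic SP = (v − w)·(u − w) is negative when the ligand pulls the
RNA-complex peak back between the single-condition positions (competition
for the shared surface) and positive when the two perturbations add.
Geometry worth noting: exact additivity w = u + v gives SP = u·v, so the
additive regime presumes perturbations in compatible directions (u·v > 0);
near-orthogonal perturbations are genuinely indeterminate, which the ±ε
band (default 1e−6) absorbs only at zero — interpretation of small |SP| is
left to the caller.  SP is symmetric in u and v and scales quadratically,
so positive rescaling (e.g. normalised vectors) never changes a regime
call; raw vectors are used.  Published figures for these data disagree
internally about two residues' regime labels (V84/G119); this package
computes SP from the inputs and takes no side beyond the arithmetic.

### STD and titrations

A_STD = (I_off − I_on)/I_off per proton; STD_AF = A_STD·[L]_T/[E]_T
(reference design: 50-fold ligand excess, 500 µM vs 10 µM); relative
percentages normalise against the largest A_STD (exactly 100 whenever any
transfer occurred).  Titration trajectories (≥4 points; reference design
16 points, 10–1000 µM ligand on 50 µM protein) are tested for straightness
by total least squares in the scaled shift plane: R² is the fraction of
in-plane variance on the first principal axis, single-mode if R² ≥ 0.98.
In 1:1 fast exchange the observed shift is δ_free + f_bound·Δδ_bound with
f_bound from the quadratic binding equation, so the path is exactly
straight; curvature indicates a second site or mode.  Residues moving less
than 0.005 scaled ppm are 'not-shifting' rather than fitted.

## 4. MT-bench plate scoring (`rpitriage.mtbench`)

Spots are detected on the bait channel at background mean + 3 SD (one
sigma-clipping pass to estimate the background), connected components with
8-connectivity and ≥4 px.  Shape comes from the pixel second-moment
matrix: length = 4√λ₁, width = 4√λ₂ (the equal-moment ellipse axes; the
1/12 px² quantisation term makes a discrete 3×20 bar measure exactly
width/length = 0.15).  Microtubule-shaped spots must satisfy width/length
< 0.22 (strict) and, when a cytoplasm bait level is available, bait
enrichment > 2× cytoplasm (the enrichment cutoff is unstated in the
reference protocol; 2× is this package's default).

Per well, mRNA enrichment (spot/cytoplasm mean) is regressed on bait
intensity by OLS; the 95% CI uses the t-distribution.  Wells need ≥30
usable spots (guards synthetic edge cases; real wells carry >500 cells at
10–50 spots each).  Plate normalisation maps the bait-free (GFP) control
mean to 0 and the DMSO-bait mean to 1 — the reference figures plot those
two anchors at ≈0 and ≈1 but state no formula, so the affine map is this
package's choice.  SSMD defaults to (μ⁺−μ⁻)/√(σ⁺²+σ⁻²); the pooled-SD
variant (√2 larger at equal SDs) is available because the prose
("divided by the standard deviation") does not pick one.  With SSMD β,
slope decreases smaller than 1/β of the positive control are below the
assay's detection floor.

Hits are compounds whose normalised slopes, paired with DMSO wells by
replicate index (the pairing is not defined in the reference protocol),
give p < 0.05 in a two-tailed paired t-test *and* decrease the slope.  No
multiple-testing correction by default (matching a 40-compound screen
called at raw p < 0.05); Benjamini–Hochberg is available.  Dose series
(≥5 concentrations spanning ≥1.5 log units; reference design 0.098–50 µM
twofold) are fitted with a four-parameter logistic on log₁₀ concentration;
`fit_ok` is false for flat responses or an EC50 outside the tested range.

## 5. Synthetic generators (`rpitriage.synthetic`)

Every generator draws from a stream keyed on (seed, stage) via a crc32
stage hash — bit-reproducible across processes, and adding a stage never
perturbs another's output.  All planted truth is returned beside the data
(and written to a `truth.json` sidecar by the CLI).

Defaults mirror the study conditions: OU energy noise with SD 3 kcal/mol
inside the reported 2–7 range and correlation time 5 frames; 40 λ windows
× 5000 bidirectional samples with Gaussian work pairs satisfying the
Crooks relation (W_f ~ N(ΔF + σ²/2RT, σ²), W_r ~ N(−ΔF + σ²/2RT, σ²),
σ = 0.5 kcal/mol so window errors land in the reported 0.34–0.97 kcal/mol
total range); 15 × 20 CSP matrices with 4 planted clusters + 1 outlier at
the ~0.04 ppm effect scale; competition triplets with blend factor α = 0.5
(additive residues drawn with u·v above a margin, competitive with |u−v|²
above it, so planted regimes are geometrically well-defined — see §3);
titrations with 16 points, 10–1000 µM on 50 µM protein; ITC at the 26 ×
1.5 µL / 200 µM / 14 µM schedule with 1% noise; plates with 10–50 spots
per cell, enrichment noise SD 0.15 and per-well slope jitter set from the
target SSMD (β = 8 for the 48+48 control plate).  The image mode renders
elongated bars (and the test fixtures add disks) on flat background — only
the statistical structure the estimators assume, not microscope optics,
cell morphology, or spectra.

What passing the round-trip suites shows, and what it does not: the
estimators are unbiased and correctly calibrated *under their own model
assumptions* (Gaussian noise, linear enrichment, 1:1 exchange, harmonic
restraints).  Real data violate these in known ways — autocorrelated MD
frames, anisotropic peak overlap, segmentation errors, non-Gaussian well
effects — so the suites validate the arithmetic and the statistics, not
instrument-level robustness.

## 6. Problem sizes in the default test run

The test suite and acceptance script run everything at the study's stated
sizes where those are small (40 × 5000 BAR samples, 15 × 20 matrices,
26-injection ITC, 48+48-well control plates, 100-run CI coverage and
200-run SSMD recovery studies).  The end-to-end image check uses a
16-well plate of 160 × 160 px wells with ~60 bars each — the package's own
default smoke scale for the full detect → filter → slope → normalise →
hit-call chain; the per-well statistics are identical at larger frame
sizes because every step is intensity- and count-based, not
field-of-view-based.

## 7. Known limitations

* The filter SD carries no autocorrelation correction (§1).
* BAR assumes independent samples within a window; correlated trajectories
  underestimate the asymptotic error.
* The restraint correction inherits the stiff-spring approximation (§2).
* The ITC model assumes a single site class and the standard displacement
  bookkeeping; low-c designs (<1) will not identify Kd regardless.
* The competition statistic is a per-residue geometric classifier; it does
  not model exchange kinetics or fit a competitive-binding isotherm.
* Plate hit calling assumes replicate-index pairing and exchangeable DMSO
  wells; plate-position (edge) effects and multi-plate batch effects are
  out of scope.
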