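# rpitriage

Tools for triaging small-molecule inhibitors of RNA:protein interactions —
the computational stack behind a screen against an RNA-binding protein's
cold-shock domain, reusable for any campaign with the same shape:

1. **MD filter score** (`rpitriage.energetics`) — from short-MD tables,
   score a docked ligand by `S = w_c·c + w_ΔΔH·⟨ΔΔH⟩` where
   ΔΔH = H_LP − H_LW is the ligand's enthalpic preference for the pocket
   over water and c is the number of unique interatomic contacts per
   interacting ligand atom (defaults w_c = 4, w_ΔΔH = −1).  S > 0 is a
   hit; S ≤ 0 within statistical error is "possible".
2. **Absolute binding free energies** (`rpitriage.free_energy`) — Bennett
   Acceptance Ratio estimates per λ window with asymptotic errors, the
   analytical correction for releasing six harmonic restraints to the 1 M
   standard state,

   ΔG_r = −RT ln[ 8π²V₀ (ΠK)^½ / (r₀² sinθ_A sinθ_B (2πRT)³) ],

   cycle assembly, Kd = exp(ΔG/RT)·1 M, magnitude-based hit thresholds
   (5.5 / 6.5 kcal/mol), and one-site Wiseman fits of ITC injection heats.
3. **NMR chemical-shift analytics** (`rpitriage.nmr`) — weighted CSPs
   Δδ = √(0.5·[ΔδH² + (0.14·ΔδN)²]), pocket averages and binder calls,
   PCA mining of ligand × residue CSP matrices with SPE / Hotelling-T²
   outlier tests and k-means clustering, per-residue RNA-competition
   classification via SP = (v−w)·(u−w), STD fractions and amplification
   factors, and straight-line tests of titration trajectories.
4. **MT-bench high-content scoring** (`rpitriage.mtbench`) — detect
   elongated bait-rich spots on two-channel images, filter by shape
   (width/length < 0.22) and bait enrichment, regress mRNA enrichment on
   bait intensity per well, normalise plates (bait-free → 0, DMSO → 1),
   summarise assay quality by SSMD, call hits against DMSO by paired
   t-test, and fit four-parameter logistic dose–response curves.

`rpitriage.synthetic` provides seeded generators for every input —
Ornstein–Uhlenbeck energy traces, fluctuation-theorem work pairs,
clustered CSP matrices, fast-exchange titrations, Wiseman heats, spot
tables and rendered well images — each returning its planted ground truth,
so the whole pipeline is testable without any instrument data.

## Worked example

Estimate a binding free energy from 40 bidirectional λ windows and check a
plate's quality, all on synthetic inputs:

```python
from rpitriage import synthetic, mtbench, free_energy as fe

windows, truth = synthetic.gen_bar_windows(7, n_windows=40, n_samples=5000,
                                           total_dg=-7.24, sigma=0.5)
dg, err = fe.sum_windows([fe.bar_window(w) for w in windows])
dg_r = fe.restraint_correction(fe.RestraintSpec(temperature=298.0))
kd = fe.dg_to_kd(dg, 298.15)
print(f"decoupling total: {dg:+.2f} +/- {err:.2f} kcal/mol")
print(f"restraint correction: {dg_r:+.2f} kcal/mol")
print(f"Kd at 298.15 K: {kd*1e6:.1f} uM")

spots, ptruth = synthetic.gen_control_plate(7, beta=8.0, n_cells=25)
fits = mtbench.slopes_by_well(spots)
lay = ptruth.layout.set_index("well")
pos = fits.loc[lay.index[lay.role == "positive"], "slope"]
neg = fits.loc[lay.index[lay.role == "negative"], "slope"]
print(f"plate SSMD (48+48 wells): {mtbench.ssmd(pos, neg):.1f}")
```

prints

```
decoupling total: -7.21 +/- 0.03 kcal/mol
restraint correction: -6.83 kcal/mol
Kd at 298.15 K: 5.2 uM
plate SSMD (48+48 wells): 7.6
```

The 40-window BAR total recovers the planted −7.24 kcal/mol within its
error; that free energy corresponds to a low-micromolar dissociation
constant; and a 48+48-well control plate simulated at a standardized mean
difference of 8 measures back an SSMD near 8 — an assay able to detect
compounds that cut the enrichment slope by more than 1/8 of the positive
control.

Every stage is also a CLI subcommand (`score-md`, `abfe`, `itc-fit`,
`csp`, `csp-mine`, `competition`, `std`, `mtbench detect|score|dose`,
`simulate`), e.g.:

```sh
rpitriage simulate --stage plate --seed 7 --out demo/
rpitriage mtbench score --spots demo/spots.csv --layout demo/layout.csv
```

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.

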