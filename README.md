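# synucalc

Quantitative analysis toolkit for calcium-dependent interactions of
alpha-synuclein with synaptic vesicles. It packages, as tested and reusable
Python, the computations needed to characterise this system end to end:

- **NMR titrations** (`synucalc.nmr_csp`) — weighted chemical-shift
  perturbations, Δδ = √(½(δ_H² + 0.15 δ_N²)), and a global multi-ligand
  binding fit. L calcium ions bind one protein molecule as a unit
  (P + Ca_L ⇌ P·Ca_L), and solving the mass-action system gives the bound
  fraction
  χ_B = (P + C/L + K_D − √((P + C/L + K_D)² − 4·P·C/L)) / (2P),
  fitted jointly over residues for K_D, L and per-residue saturation shifts.
- **CEST profiles** (`synucalc.cest`) — normalisation of saturation-transfer
  intensity tables against a −100 kHz reference, a per-residue transfer
  score, and region-wise (N-terminus / NAC / C-terminus) condition
  comparisons with bootstrap confidence intervals.
- **Localisation-microscopy cluster analysis** (`synucalc.smlm`) — ROI
  segmentation, pairwise-distance histograms normalised by a Monte-Carlo
  complete-spatial-randomness expectation, a Ripley-style cluster-radius
  estimate per ROI, and Welch t-tests between conditions.
- **Vesicle clustering** (`synucalc.vesicles`) — classification of vesicle
  coordinates into singles, pairs and larger clusters by 250 nm linkage,
  with ANOVA + Tukey comparisons across incubation conditions.
- **Aggregation kinetics** (`synucalc.tht`) — Finke–Watzky two-step fits
  B(t) = A₀ − (k₁/k₂ + A₀)/(1 + (k₁/(k₂A₀))·e^((k₁+k₂A₀)t)),
  tangent-method lag times, rate fold-changes, and SEC-calibrated residual
  monomer concentrations.
- **Native MS stoichiometry** (`synucalc.ms`) — theoretical m/z of
  protein–calcium adducts (each Ca²⁺ displaces two protons; +38.063 Da per
  ion), charge deconvolution over the 9+–19+ envelope, and maximum
  stoichiometry counting.
- **Synthetic data** (`synucalc.simulate`) — seeded generators for all six
  input kinds with ground-truth sidecars, so every estimator is testable
  without instrument data.

## Worked example

Simulate a calcium titration of 200 µM protein (ground truth K_D = 21 µM,
L = 7.8, 1% shift noise) and run the global binding fit:

```bash
$ synucalc simulate titration --seed 7 --out demo
wrote titration data to demo
$ synucalc titrate fit --in demo/titration.csv --out demo/fit
K_D = 21.55 uM, L = 7.77
```

`demo/fit.json` holds the machine-readable summary — the fitted
dissociation constant (µM), ligand number, standard errors from the fit
Jacobian, and the residues whose perturbations entered the global fit:

```json
{
  "K_D_uM": 21.546033037585033,
  "L": 7.766848516650626,
  "se": {"K_D": 0.6347959373370105, "L": 0.03132961908768105},
  "residues_used": [104, 107, 119, 123, 124, 126, 127, 130, 135, 136, 137]
}
```

The fitted K_D of ~21.5 µM means half-saturation of the C-terminal calcium
sites at physiological tens-of-µM presynaptic calcium transients; L ≈ 7.8
is the effective number of calcium ions bound per protein. Similarly,

```bash
$ synucalc simulate ms --seed 7 --out demo_ms
$ synucalc ms stoich --in demo_ms/spectrum.csv --mass 14460 --out demo_ms/stoich.json
max stoichiometry: 6
```

deconvolves a synthetic electrospray envelope and counts up to six calcium
adducts. Other subcommands: `cest score`, `storm clusters`,
`sted vesicles`, `tht fit`, and `run` for a TOML-configured multi-stage
pipeline. The library API mirrors the CLI one-to-one; see module
docstrings and `docs/methods.md`.

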