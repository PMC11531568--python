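# fretarch

Quantitative inference of the in-situ architecture of a membrane-receptor
dimer from single-molecule FRET, for structural biologists and
single-molecule microscopists who need to decide *which* of several
crystallographic assemblies a receptor complex adopts in the cell
membrane.

The motivating system is the 2:2 complex of the MET receptor tyrosine
kinase with the bacterial invasion protein InlB₃₂₁, which crystallises in
two competing arrangements ("form I", PDB 2UZX, and "form II", PDB 2UZY).
Single-cysteine InlB variants labelled at residue 64 ("H") or 280 ("T")
give three inter-dye distances (H-H, T-H/H-T, T-T) whose pattern differs
sharply between the two forms; comparing measured and structure-predicted
distances identifies the assembly.

## What the package computes

**ALEX-FRET correction.** Camera traces from alternating laser excitation
carry three channels, I_DD, I_DA, I_AA.  After selecting single-pair
traces by single-step photobleaching and donor/acceptor anticorrelation,
the corrected FRET efficiency and stoichiometry are

    F_corr = I_DA − α·I_DD − δ·I_AA
    E = F_corr / (γ·I_DD + F_corr)
    S = (γ·I_DD + F_corr) / (γ·I_DD + F_corr + I_AA/β)

with leakage α, direct excitation δ, detection factor γ (from the
intensity steps across acceptor bleaching) and excitation balance
β = avg(I_AA)/(γ·avg(I_DD)).  Population efficiencies come from a
Gaussian fit of the E histogram inside a stoichiometry window.

**Förster conversion.** R = R₀·(1/E − 1)^{1/6}, with
R₀ = 0.211·(κ²·n⁻⁴·φ_D·J)^{1/6} (Å) and φ_D = k_F·τ_L.  Bundled presets
for Cy3B/ATTO 647N give R₀ = 6.35 nm (T variant, τ_L = 2.6 ns) and
6.31 nm (H variant, τ_L = 2.5 ns).

**Accessible-volume (AV) prediction.** A dye on its flexible linker is a
cylinder-tethered ellipsoid (3AV model); a grid flood fill around the
labelling site yields the cloud of sterically allowed dye positions, and
averaging the Förster efficiency over two clouds gives the predicted
FRET-averaged distance R_E for each candidate structure.

**Photon distribution analysis (PDA).** The shot-noise-limited histogram
of the proximity ratio expected from a single narrow distance state is
computed by exact binomial enumeration; comparing it with the measured
histogram (Pearson χ²) tests whether the complex is conformationally
homogeneous.

**SMLM cluster density.** dSTORM localization tables are processed with
NeNA (nearest-neighbour localization precision), temporal linking
(6×NeNA radius, 5 dark frames), DBSCAN (2×NeNA radius, ≥10 localizations)
and clusters-per-area, the criterion used to select a cell line with
receptor densities compatible with single-molecule imaging.

**Model discrimination.** Measured distances (with censored lower bounds
for undetectable FRET) are scored against per-form predictions by χ²,
ranking the candidate assemblies.

A synthetic-data module generates every input with known ground truth —
ALEX traces, localization fields, toy PDB structures — so the entire
chain is testable offline.

## Worked example

```python
from fretarch.photophysics import efficiency_to_distance
from fretarch.pipeline import analyze_cohort
from fretarch.presets import fluorophore_pair
from fretarch.simulate import TraceSimParams, simulate_trace_cohort

pair = fluorophore_pair("cy3b_T")
params = TraceSimParams(true_distance=4.8, alpha=0.06, delta=0.05,
                        gamma=1.1, beta=1.2, seed=900)
cohort = simulate_trace_cohort(400, params, 0.15, 0.15)
result = analyze_cohort(cohort)
```

prints, via the accessors shown in `fretarch.pipeline`:

```
Forster radius (T variant): 6.35 nm
estimated factors: alpha=0.060 delta=0.050 gamma=1.100 beta=1.193
population: E = 0.841 +/- 0.005 (n = 169)
distance: 4.81 nm
```

The cohort was simulated at a true distance of 4.8 nm (E ≈ 0.843); the
pipeline re-estimates all four correction factors from the traces
themselves and recovers the efficiency and distance to within the fitted
population width.

A command-line interface mirrors the library
(`fretarch simulate|analyze-traces|pda|av-predict|metrics|density|discriminate|run`);
`fretarch run --config <yaml>` executes a staged
simulate → analyze → pda → discriminate pipeline and writes a manifest
with per-stage seeds and output digests.

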