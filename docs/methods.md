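# Methods

## Scope and model

The package implements the analysis chain by which a two-fold symmetric
receptor–ligand assembly is assigned to one of several candidate
structures from in-situ single-molecule FRET: trace correction, distance
conversion, accessible-volume prediction on candidate structures,
shot-noise (PDA) modelling, structural descriptors, localization-based
receptor densities and a χ² model ranking.  Everything operates on plain
text inputs (CSV traces and localization tables, PDB structures, YAML
configs) and all randomness flows from explicit seeds.

## ALEX trace model and correction chain

A simulated trace has one row per excitation-alternation cycle with
channels I_DD, I_DA, I_AA.  With donor photon budget N_D per frame, true
efficiency E (from the Förster relation at the set distance), and factors
α, δ, γ, β, the pre-bleach channel expectations are

    I_DD = (1−E)·N_D + bg
    I_DA = γ·E·N_D + α·(1−E)·N_D + δ·I_AA,exp + bg
    I_AA = β·γ·N_D + bg

Each channel is Poisson-distributed about its expectation (optional
Gaussian read noise); the EMCCD excess-noise factor is deliberately
omitted, so simulated variances slightly understate EM-amplified cameras.
Photobleaching is single-step per fluorophore with geometric waiting
times; FRET traces contain no blinking.  Direct-excitation photons are
generated as δ·I_AA,exp so that the correction convention inverts the
generator exactly (verified to machine precision in the tests).

Step detection is binary segmentation on a two-window mean-shift
statistic (window = `min_dwell` = 5 frames).  Because shot noise is
level-dependent, significance is judged against a *local* noise scale
(robust MAD of first differences in the flanking regions); the default
threshold is 5 standard errors of the window-mean difference, chosen so
that an 800-frame flat segment produces a false step in well under 1 % of
traces.

Trace selection requires exactly one downward acceptor step and donor
anticorrelation at that frame.  A detected donor *rise* confirms the
pair; a donor *drop* there rejects the trace.  When the expected rise
(E·N_D) sinks below the detection threshold — unavoidable for low-E
pairs, which are exactly the ones establishing large distances — the
absence of any donor change is accepted.  The strict rise-mandatory rule
is available via `require_rise=True`.

Backgrounds are estimated per trace from the window after both
fluorophores have bleached, falling back to a caller-supplied value.
γ is estimated trace-wise across the acceptor bleach and averaged (median
optional); β uses the *unquenched* donor level, i.e. the
post-acceptor-bleach donor mean where available.  For cohorts whose own
bleach steps cannot resolve γ (very low E), `fit_population_with_factors`
applies mean factors calibrated on a well-resolved cohort — the same
convention as applying dataset-mean correction factors across conditions.

The E histogram of points inside the stoichiometry window (default
S ∈ [0.3, 0.7]; the simulated 1:1 species sits at S = 0.5 after
correction) is fitted with a Gaussian.  The histogram range adapts to the
sample (mean ± 8 sd, 40 bins) so narrow populations are resolved.

Generator defaults emulate TIRF camera measurements: 300 donor
photons/frame, background 10 photons/frame/channel, bleach rates
0.002 (donor) and 0.004 (acceptor) per frame over 800 frames, and
instrument factors α = 0.06, δ = 0.05, γ = 1.1, β = 1.2 in the recovery
experiments.  Published trace data do not state photon budgets or
backgrounds, so these are package choices exposed in the config.  The
synthetic populations are narrower than measured ones (σ_E ≈ 0.005 vs
≈ 0.06) because the generator contains no cell-to-cell or photophysical
heterogeneity; passing recovery tests therefore demonstrates correctness
of the correction algebra and estimators, not realism of population
widths.

## Förster conversion

φ_D = k_F·τ_L; R₀ = 0.211·(κ²·n⁻⁴·φ_D·J)^{1/6} in Å (J in
M⁻¹cm⁻¹nm⁴), returned in nm; R = R₀·(1/E − 1)^{1/6}.  Recomputing the
bundled Cy3B/ATTO 647N presets gives 6.353 and 6.312 nm against the
published 6.34/6.30 nm — a ≤ 0.5 % residual attributable to lifetime
rounding, absorbed by the 1 % tolerance used throughout.  Distance
uncertainty is first-order propagation with
∂R/∂E = −(R₀/6)(1/E−1)^{−5/6}/E², plus a relative R₀ term
(default 3 %, the scale adopted by multi-laboratory benchmark
conventions).  For mixed-orientation pairs (T-H/H-T) the donor-T radius
is the default, configurable.  Lengths are nm on the FRET side and Å on
the structure side, with conversions centralised in `fretarch.units`.

## Accessible volumes

The linker is a cylinder (length L, width w), the dye an ellipsoid
approximated by three radii (3AV).  On a cubic grid (default 1 Å) centred
at the attachment atom — Cβ of the labelled residue by default, whose
side chain beyond Cβ is removed as the dye replaces it — a voxel is
*traversable* if it clears every atom's vdW surface by w/2, and the
linker path length is the 26-neighbour grid geodesic (Dijkstra), the
standard AV construction, so the linker can bend around obstacles.  A
voxel belongs to the sub-AV of radius R_i if its geodesic is ≤ L and a
sphere of radius R_i there clears all atoms.  When the anchor voxel
itself falls inside a clearance zone (surface sites), the fill starts
from the nearest free voxel and that offset counts against the linker
length.  The three sub-AVs combine with equal 1/3 weights, uniform within
each sub-AV; no contact-surface reweighting is applied (no such
parameters are published for these dyes).  Pair statistics average over
the product measure of two clouds — exhaustively when feasible, else by
seeded weighted subsampling — using static isotropic (κ² = 2/3)
averaging: mean_R = ⟨r⟩, mean_E = ⟨1/(1+(r/R₀)⁶)⟩, and the FRET-averaged
distance R_E = R₀(1/mean_E − 1)^{1/6}.  Both mean_R and R_E are reported,
since published AV distances do not always state which is quoted.  Grid
statistics agree with a rejection-sampling Monte-Carlo oracle to within
the grid spacing on toy obstacles, and predictions are invariant under
rigid transforms up to grid discretisation (≈0.1 nm).

## Photon distribution analysis

Per observation window (a trace's pre-bleach aggregate), the total
photon count N is drawn from the empirical distribution; given distance
r, the acceptor count is Binomial(N, ε(r)) with the apparent efficiency
ε(r) = (γE + α(1−E) + δ·s_AA)/(γE + α(1−E) + δ·s_AA + (1−E)), where s_AA
is the direct-excitation brightness scale (0 by default).  Backgrounds
enter as truncated-Poisson enumerations per channel.  A "limited-width"
state is a Gaussian distance distribution (truncated at r > 0) handled by
33-node quadrature.  Predictions are exact binned binomial mixtures for
width 0 and no background (checked against enumeration to 1e−12); when
the empirical N support exceeds 64 distinct values it is compressed to 64
representatives for the fit, preserving exactness on small supports.
The single-state fit minimises Pearson χ² over 40 ratio bins (bins with
expected counts < 4 pooled out; dof = bins − 2 − 1); observed ratios are
binned with the identical edge rule as predictions because ratios land
exactly on bin boundaries.  Only one state is fit — dynamic multi-state
PDA is out of scope — so heterogeneity shows up as χ²/dof ≫ 1.

## Structural metrics

The inter-domain angle θ is the angle between two centre-of-mass
difference vectors; the default residue ranges are 182–200/464–479 and
561–657/655–657 in structure numbering.  The second pair overlaps as
printed in its source definition — implemented as given, flagged with a
warning, fully configurable.  Centres of mass are mass-weighted with
unit-mass fallback.  Rg uses Cα atoms with unit masses by default;
conformations are extended iff Rg > 45 Å (strict).  RMSD superimposes by
least squares (Kabsch) first.  SASA is Shrake–Rupley with 960
points/atom, probe 1.4 Å, and a bundled Bondi vdW table; the interface
between two chain groups is (SASA(A)+SASA(B)−SASA(A∪B))/2, the
buried-surface-per-side convention, with whole-protomer groups assumed
when a finer grouping is not specified.

## Localization analysis

NeNA fits the histogram of nearest-neighbour distances between
consecutive-frame localizations with p(d) = (d/2σ²)·exp(−d²/4σ²) plus a
linear background term and returns σ.  Linking joins localizations
within a radius when their frame indices differ by at most
`max_dark_frames` (a value of 5 admits up to 4 intervening dark frames),
transitively, merging groups to their mean position; the radius is
6×NeNA capped at 0.45 px and the DBSCAN radius 2×NeNA capped at 0.15 px
(157 nm/px), ceilings applied in nm.  DBSCAN is implemented in-package
with documented determinism: a core point has ≥ min_pts neighbours
within eps *including itself*; clusters grow by neighbourhood expansion
in scan order and border points join the first core cluster reaching
them.  Density is cluster count over a supplied cell area (µm²); image
segmentation is out of scope.  The field generator places cluster
centres by a homogeneous Poisson process, emits ~25 blinking events per
cluster (geometric event lengths, mean 3 frames) jittered by the
localization precision, plus uniform noise — enough occupancy that the
min-10-localization rule keeps genuine clusters, which is the regime of
antibody-labelled receptor clusters.  It does not model drift,
overcounting heterogeneity or sample-dependent blinking kinetics.

## Model discrimination

Undetectable-FRET pairs are censored at the distance corresponding to a
detection threshold E_detect = 0.1 (a package choice; no published
threshold exists).  χ² sums squared residuals over uncensored pairs;
censored pairs contribute only when the prediction violates the bound,
scaled by σ_floor (default: mean uncensored σ_R).  Rankings are reported
with Δχ² and an explicit tie flag; a best χ²/pair above 3 is flagged as
qualitative-only agreement.  The χ² statistic itself is this package's
formalisation of what is otherwise a qualitative comparison, and reports
label it as such.  Bootstrap uncertainties resample a distance or
efficiency series with replacement (default 1000 resamples) and return
the sd of resample means; efficiency series can be converted to distance
before resampling or after averaging, both orders being in use.

## Reproducibility and problem sizes

Every stochastic stage draws from `derive_seed(global_seed, stage_name)`
(deterministic, < 2³¹).  The recovery experiments use 400-trace cohorts
(≈170 surviving selection), PDA fits use 1000 windows, localization
fields cover 100 µm² at 2.8–3 clusters/µm², and AV oracle comparisons
use ≥10⁶ Monte-Carlo samples — sizes at which every check completes on a
single CPU in seconds to a couple of minutes while keeping statistical
errors well inside the asserted tolerances.

## Known limitations

No EMCCD excess noise, gain calibration or PSF/optics simulation; no
dynamic (interconverting) PDA states; no rotamer-library dye models or
dye-surface stacking corrections in the AV engine; no drift correction
or raw-movie localization for SMLM; trajectory formats beyond
multi-model PDB are not parsed.  Comparisons against reference crystal
structures require downloading the public PDB entries.
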