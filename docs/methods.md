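# Methods

This note documents the models, conventions and numerical choices behind
`plumezoo`, and what the synthetic-data tests do and do not establish.

## Cast gridding

Raw casts are averaged into half-open 1-m bins [k, k+1) addressed by their
centres k+0.5; everything above 1 m is discarded (wave action, stray
light, bubbles). Empty bins propagate as NaN — no interpolation is ever
applied at this stage, so every downstream operation declares its own
missing-data handling (N² stencils touching a missing bin are missing;
summaries drop missing bins). Binning is a plain arithmetic mean and is
therefore invariant to sample order and to down-/up-cast mixing; down-cast
selection, if wanted, must happen before ingestion.

The daytime filter keeps a closed 06:00–19:00 local-time window. Stations
outside the window are *flagged*, never dropped, mirroring survey practice
of retaining late stations with an asterisk.

## Turbidity regimes

The depth of turbidity change is operationalised as the lower bin edge of
the deepest bin whose running-median-smoothed turbidity still reaches the
threshold τ = 0.04 FTU, with 0 m when no bin reaches it. The "deepest
exceedance" reading (rather than first downward crossing) is chosen
because surface-only plume stations report small nonzero depths and
never-exceeding stations report 0 under it, matching the reference survey
table; single-bin spikes at depth are suppressed by the 5-bin running
median (≈ 5 m), which is robust to isolated sensor hits but cannot move a
10-m-scale plume boundary. Both the threshold and the window are
parameters. Regime bands: S < 10 m ≤ I ≤ 40 m < D — boundaries resolve to
I per the band phrasing "10–40 m".

## Hydrography

Density uses the published EOS-80 one-atmosphere polynomial (σ_t =
ρ(S, T, 0) − 1000). Adiabatic compressibility is neglected: over the
< 350 m depths involved its contribution to metre-scale density
*differences* is orders of magnitude below the stratification-class
thresholds. Different published EOS variants differ by up to ~0.05
kg m⁻³ in absolute σ_t; tests use that tolerance. N² is a centred
difference on adjacent bins, reported at midpoints, positive = stable.
The stratification class applies the 2·10⁻⁵ / 5·10⁻⁵ rad² s⁻²
thresholds to whatever N² value the caller supplies — per-bin by default;
an upper-layer mean is a caller-side choice (the averaging depth for the
class is not standardised).

## Euphotic depth

z_eu is where PAR falls to 1% of the surface value. Because the top metre
of every cast is discarded, the surface reference is obtained by
log-linear extrapolation of the two shallowest valid bins to z = 0 —
still purely in-water information (a deck sensor is out of scope). On an
exact exponential profile this makes z_eu = ln(100)/K_d to machine
precision, the closed form the implementation is tested against; using
the shallowest bin *value* as reference would bias z_eu deep by the bin
depth (~1.5 m), which is why the extrapolated reference was chosen.
Profiles that never attenuate to 1% return the deepest valid depth with a
truncation flag.

## Chlorophyll-a

chl a = 10³·ΔOD·V_E/(83·V_W·l), with ΔOD the 665-nm extract absorbance
corrected at 750 nm, volumes in mL and path length in cm, yielding
mg m⁻³ (the unit convention that reproduces observed coastal
concentrations of order 0.01–1 mg m⁻³). Negative ΔOD — turbid blanks —
clips to zero with a warning rather than failing, so noisy synthetic or
field batches run through.

## Plankton metrics

The *Calanus* particle class is the calibrated window ESD ∈ [1, 2.5] mm
(closed) and attenuance index strictly > 0.4; the attenuance index is
consumed as a per-particle input, its instrument-level definition being
out of scope. Concentrations are counts over sampled volume per bin; LOPC
quantities stay in ind m⁻³ and UVP quantities in ind dm⁻³, conversions
always explicit. Weighted mean depth uses bin centres (bin tops would
shift every WMD by −0.5 m uniformly; centres are the unbiased choice for
bin-averaged data). Layer means assign bins by centre with boundaries
going to the shallower layer; the conservation identity mean × (bins in
layer) = Σ abundance holds exactly under this convention. Net hauls are
assumed 100% filtration-efficient.

## Statistics

Kruskal–Wallis uses the tie-corrected H (all-tied data defines H = 0) and
the χ² approximation (df = k − 1); the implementation is verified against
the tie-robust variance-ratio identity H = (N−1)·SS_between/SS_total on
rank data and against exhaustive label-permutation enumeration at small
n. Dunn z-statistics use rank means with tie-corrected pooled variance;
p-values are unadjusted by default (matching classic reporting practice),
Holm available by flag. PERMANOVA partitions squared distances
(pseudo-F = (SS_A/(a−1))/(SS_W/(N−a))) with unrestricted permutation of
raw labels and p = (b+1)/(m+1); it requires an explicit seed for
reproducibility and is cross-checked against an independent
implementation. Variation partitioning computes RDA R² of every union of
predictor sets by multivariate least squares and applies
inclusion–exclusion; raw fractions sum exactly to the full-model R², and
Ezekiel-adjusted fractions (default) may be negative and are reported
as-is. Whether raw or adjusted R² matches any given published percentage
is generally unknowable without the source data, so no numeric target is
asserted on real-data partitions.

## Synthetic stations

The generator states one fixed world per regime:

| quantity | S | I | D |
|---|---|---|---|
| turbidity-change depth (m) | U(2, 9) | U(12, 35) | U(45, 75) |
| plume surface turbidity (FTU) | 0.05–0.10 | 0.10–0.20 | 0.20–0.50 |
| fluorescence peak depth (m) | 15–25 | 8–15 | 2–8 |
| *Calanus* vertical law (0–50 m) | exp, e-fold 12 m | exp, e-fold 12 m | uniform |
| gelatinous scaling | tracks *Calanus* | tracks *Calanus* | ≈ 0 |

plus, for every regime, a near-bottom Gaussian maximum (diapausing stock,
centre 0.9 × bottom depth, σ = 8 m). The plume is logistic in depth
(width 3 m — a smooth stand-in for observed sharp inflections) and is
*anchored so its noise-free 0.04-FTU crossing sits exactly at the drawn
change depth*, which is what makes regime-recovery tests meaningful.
Plumes cool (≤ 2 °C) and freshen (≤ 5 units) the column; K_d = 0.15 +
1.45 × turbidity m⁻¹ was tuned once so euphotic depths emerge near 25 m
(S) and 7 m (D). Abundance scales: *Calanus* surface peak 5000 ind m⁻³,
Deep-regime column level 300 ind m⁻³, gelatinous peak 20 ind dm⁻³.
Observation noise, where no value is stated anywhere, was set once to
realistic instrument levels: 5% multiplicative lognormal on turbidity
(a Seapoint-class sensor after 1-m averaging), 2–5% on PAR/fluorescence,
20% lognormal on net hauls (typical WP2 replicate CV). Particle streams
are Poisson with intensity abundance × sampled volume (LOPC 0.005 m³ per
bin); flour/snow particles (small ESD, low attenuance) scale with
turbidity and are almost entirely rejected by the *Calanus* filter.

What a green synthetic test establishes: the pipeline's operations invert
the generating laws (regime recovery ≥ 95%, WMD offset recovered within a
few percent, euphotic closed forms, null calibration of the tests). What
it does not establish: fidelity to real plume physics (no advection,
upwelling or estuarine circulation), real zooplankton behaviour (the
vertical laws are qualitative stand-ins), or real instrument artefacts.
Effect-recovery runs fix bottom depth at 150 m so the bottom peak lies
below the 0–50 m analysis layer and the generating WMD offset has a
closed form on the bin grid.

## Degenerate inputs and tie-breaks

Turbidity/fluorescence maxima resolve ties to the shallowest depth. WMD
of a zero-abundance layer, and surface ratios with a zero denominator,
return NaN with flagging semantics rather than raising, since both occur
legitimately (gelatinous zooplankton absent from Deep-regime stations).
All-tied rank data give H = 0. Collinear predictor sets in RDA fall back
to the effective rank with a warning.
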