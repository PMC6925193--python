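# Methods

## Scope and model

The package analyses molecular-level DOM data of a river transect at
the level of elemental stoichiometry: a molecular formula, not a
structure, is the unit of observation, and a sample is a set of
formulae with sum-normalized peak intensities.  Everything downstream —
class densities, common/unique subsets, correlation maps — operates on
that representation.

## Formula assignment

Ions are assumed to be even-electron [M−H]⁻ species: the proton mass
(1.007276467 Da) is subtracted per charge, and only integer,
non-negative DBE (= C + 1 − (H − N)/2, P ≡ 0) compositions are
admitted.  Isotope masses come from one fixed table (¹²C = 12 exactly,
¹H 1.00782503, ¹⁴N 14.00307400, ¹⁶O 15.99491462, ³²S 31.97207100 Da).

*Charge and isotopologues.*  Charge is read from the spacing to the
first ¹³C satellite (1.0033548/z, matched within 0.8 mDa with a
plausible intensity ratio).  The satellite itself is flagged and
excluded from assignment; peaks with no detectable satellite default to
the majority charge of the resolved peaks and carry a flag.  The full
total-mass-differences machinery of dedicated FTICR software is
deliberately reduced to this satellite rule — it is what the synthetic
data exercise and what the downstream statistics need.

*Recalibration.*  Internal calibration bootstraps its own reference
set: the most abundant singly-charged peaks are coarsely assigned to
CHO-only formulae at 3 ppm, unambiguous hits are grouped into
CH₂-homologous series (constant O and DBE), and series of ≥ 4 members
become calibrants.  A ppm-error model linear in m/z is least-squares
fitted to the matched calibrants and applied to all peaks; with an
intercept in the model the calibrant RMS cannot increase.  Fewer than
five matches refuses calibration and returns the list unchanged.

*Candidate search.*  Compositions (c, o, n, s) of the constraint box
are enumerated once and sorted by their hydrogen-free partial mass; a
binary search restricts each query to the mass slab reachable with
0–200 hydrogens, and the hydrogen count is the nearest integer of the
mass residual with even-electron parity enforced (at ≤ 1 ppm a
competing hydrogen count is ~1 Da away).  The test suite checks this
search against a plain nested-loop enumeration of the whole box.

*Ambiguity.*  Competing in-tolerance candidates are ranked by fewest
heteroatoms (N+S), then smallest |error|; a residual tie marks the peak
ambiguous and it is excluded from statistics.  A known cost of the
heteroatom-minimal rule: S + 12 H + 13 O differs from 21 C by only
0.139 mDa, so above ~280 Da an oxygen-rich CHOS formula always has a
CHO twin inside a 0.5 ppm window and the twin wins even at zero error.
This is documented in a dedicated test; in count terms it slightly
inflates CHO shares (well below a percentage point of the totals seen
here).

## Compound classes

The seven Van Krevelen regions use left-closed/right-open boundaries
exactly as conventionally printed.  Two deliberate precedence choices
where regions overlap: the N-saturated region (defined by N ≥ 1) is
tested first for nitrogen-bearing formulae, and the oxidized-lignin
region precedes carbohydrates in their shared O/C ∈ [0.65, 1),
H/C ∈ [1.3, 1.6) corner.  Everything outside the seven regions is an
explicit eighth label so densities always form a partition of unity —
which also explains why seven-class tables sum to slightly less than
one.  "Number-averaged" descriptors are unweighted means over distinct
formulae; an intensity-weighted variant sits behind a flag.

## Optics

Absorption uses the decadic optical density with the conventional
rounded factor 2.303 and a path length in metres.  Spectral slopes are
ordinary least squares of ln a on λ (non-positive a dropped; ≥ 10
points required); a non-linear fit was considered and rejected as the
default because the log-linear form is the field convention and is
exactly invertible in tests.

The trilinear EEM model is fitted by alternating least squares with
non-negativity on all three modes, implemented directly on the
Khatri–Rao normal equations (3×3 Cholesky + NNLS only for rows whose
unconstrained solution goes negative).  First- and second-order
Rayleigh bands (±10 nm) are masked as missing and imputed with the
current reconstruction each sweep (expectation–maximisation style), so
they exert no pull.  Defaults: 10 random multistarts keeping the
lowest reconstruction error, convergence when the relative error change
drops below 1e-8, cap 2,500 sweeps.  Loadings are reported unit-norm
and non-negative with all scale in the sample scores, components
ordered by ascending emission maximum (so C1 is the protein-like
~350 nm component).  Inter-component Tucker congruence > 0.98 flags a
degenerate solution.

Model order: walking the candidate range upward, an order is accepted
while its explained-variance gain over the previous order exceeds half
a percentage point *and* its split-half (even/odd samples) loadings
replicate with Tucker congruence > 0.95; the last accepted order is
returned, since the first negligible gain marks the onset of
overfitting.  If nothing is accepted the range floor is reported with a
warning.  These two thresholds are this package's policy; they are
deliberately conservative for small (≈ 20-sample) EEM stacks.

## Correlation mapping

Spearman rho uses average ranks for ties.  p-values: the
t-approximation for n ≥ 10 stations, an exact permutation null
(respecting observed tie structures) below that — the exact path is
vectorized over formula columns and chunked to bound memory.  No
multiple-testing correction is applied by default, matching the raw
p < 0.05 screen plus the > 200-significant-correlations parameter
filter; a Benjamini–Hochberg option exists for sensitivity analysis.
Constant vectors leave rho undefined; such cells are NaN and counted.
Outlier-station exclusion is configuration, not policy.

## Synthetic transect generator

The generator is the package's study design, not a tuning knob.  It
emulates an 18-station south→north transect with a confluence step at
station 10: a shared core of 1,600 formulae present at every station,
class mixture weights interpolating from a southern regime
(hydrolysable tannins 0.198, low-oxidized lignins 0.277, amino-sugars
0.060) to a northern one (0.445 / 0.114 / ~0), 50 station-unique
lignin/amino-sugar formulae per southern station (2% of intensity),
and heteroatom families allocated deterministically per class
(86% CHO / 6% CHON / 7% CHOS / 1% CHNOS) so that CHO exceeds 80% of
assignments.  Within-class intensity shares are fixed log-normal
(σ = 1) shapes with σ = 0.25 station jitter, while class totals follow
the designed weights exactly — so realized class densities track the
design and are recorded as ground truth.

Peak lists add a systematic ppm offset (default +1.5), optional linear
drift, iid Gaussian ppm noise (default 0.3), ¹³C satellites at natural
abundance, and uniform noise peaks at S/N ≤ 6; analyte S/N is anchored
so every analyte survives the S/N > 6 screen.  Hydrochemistry is
generated as monotone functions of the realized oxidized-tannin
density (organic carbon stepping 0.2 → 1.1 mM at the confluence,
carbonate-system parameters inter-correlating at ρ > 0.7) plus scaled
noise; temperature declines with the station index.  Absorption uses a
two-exponential model whose shallow-slope fraction falls northward, so
the slope ratio is higher in the south; EEMs are exact trilinear
mixtures of three Gaussian-band fluorophores whose protein-like score
falls northward.

What the generator does *not* emulate: ionization-efficiency and
matrix effects, correlated (non-iid) mass-error structure within a
spectrum, isotope fine structure, inner-filter effects, or chemically
realistic intensity distributions beyond log-normal shape.  Passing
tests therefore certify the statistical machinery under the designed
gradient, not instrument-level fidelity.  One measurable consequence of
the iid mass noise: with a 0.5 ppm window about 9% of peaks per
station fall outside it at 0.3 ppm noise, so the formula set common to
all 18 stations after the noisy peak pipeline is much smaller than the
designed core; correlation analyses in the examples therefore run on
the generated ensembles, where the common core is exact.

## Numerical choices and problem sizes

Deterministic outputs: every source of randomness takes an explicit
seed, generator output is bit-identical under a fixed seed, and
pipeline tables are written with fixed precision (3 decimals for
densities, 2 for ratios) stamped with a configuration hash that
excludes the output path.  Formula identity is the neutral CHNOS tuple.
Ties in candidate ranking break on the formula's field order; ALS
ridge regularisation is 1e-12·tr(G)/r.  Test and acceptance workloads
use scaled problem sizes chosen to exercise every code path at
desk scale: 12–20 samples and ~100-point emission grids for trilinear
fits, 50 seeds for recovery rates, 1,000 replicates for the Spearman
null calibration, 200 random masses for the enumeration equivalence
sweep, and the full default 18-station transect for the end-to-end
pipeline checks.

## Known limitations

No vendor raw-file parsing, transient processing or phasing; no
isotope fine structure; no aromaticity indices; no inner-filter or
Raman normalisation of fluorescence; no carbonate-system speciation.
The charge algorithm handles z ∈ {1, 2} satellites only.  Exact
permutation p-values are limited to n ≤ 9 stations by factorial
growth.
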