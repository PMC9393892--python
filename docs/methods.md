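# Methods

This note documents the models, conventions, and numerical choices
behind `vcdkit`, and what its synthetic tests do and do not demonstrate.

## Scope and data model

The package consumes per-conformer quantum-chemistry results and
produces ensemble spectra and comparisons; it never runs sampling or
electronic-structure calculations.  Coordinates are stored in Å,
energies in Hartree (converted with 1 Hartree = 627.509474 kcal/mol),
frequencies in cm⁻¹, dipole strengths in 10⁻⁴⁰ esu²cm², rotational
strengths in 10⁻⁴⁴ esu²cm².  Atom order is treated as significant and
fixed: no atom-mapping or permutation search is attempted, because the
workflow this package supports preserves atom order from sampling
through optimization.  Symmetry-equivalent permutations (e.g. methyl
rotors) are therefore not recognized as duplicates — a known limitation.

The genetic-crossing helper implements the published Cartesian form
R_new = R_ref + (R_i − R_j).  Samplers that perform this crossing in
internal (Z-matrix) coordinates will produce different children; the
Cartesian form is the one implemented and documented here, and crossed
structures carry no energy record until re-evaluated.

## Duplicate criteria

A pair is a duplicate when all three criteria hold:

* |ΔE| ≤ 0.05 kcal/mol (selected energy field; electronic by default,
  since post-optimization pruning normally precedes thermochemistry),
* Kabsch RMSD ≤ 0.125 Å — plain Cartesian RMSD by default (a flag
  enables mass weighting), computed with the Kabsch/Wahba optimal
  rotation after centering,
* max over the three rotational constants of |ΔB| / mean(B) ≤ 0.01.
  The symmetric relative form is scale-free; for linear molecules the
  vanishing principal moment (below 10⁻¹⁰ amu·Å²) maps to an infinite
  constant that is excluded from the comparison.

Thresholds default to the CREST conformer-sorting defaults and are
user-configurable.  Rotational constants use B = h/(8π²cI) with
most-abundant-isotope masses; isotopic labelling of solvents affects
experiment only, not these gas-phase-model fingerprints.

Pruning is a greedy sweep in ascending energy: a conformer is removed
iff it is a duplicate of an already-kept (hence lower-energy) conformer.
Greedy sweeping rather than clustering resolves non-transitive duplicate
relations deterministically and matches the keep-the-most-stable
convention; it is idempotent, and on fixtures whose duplicate graph is
transitively closed it recovers exactly the connected components.

## Selection and weighting

The energy window (default 2.5 kcal/mol, inclusive — "at most" is read
inclusively) is applied to single-point ΔE before duplicate removal, so
the bookkeeping found ≥ within-window ≥ unique ≥ significant holds by
construction.  Boltzmann weights use R = 1.987204×10⁻³ kcal/(mol·K) and
T = 298.15 K by default (the temperature at which thermochemistry
outputs are customarily reported; configurable), computed from shifted
relative energies for numerical stability.  Gibbs free energies are the
default weighting field; enthalpies or electronic energies are
selectable for sensitivity analyses.

Conformers with weight strictly above 5% are reported as "significant",
but the ensemble average runs over *all* retained unique conformers by
default; an option restricts averaging to the significant set (with
renormalized weights).  Note a subtlety the tests pin down: with a
single energy field, window-then-weight is identical to
weight-then-truncate-and-renormalize for any window; the two routes
differ precisely because the window uses single-point energies while
weighting uses Gibbs energies, which rank conformers differently.

## Spectrum synthesis

Broadening uses unit-area Lorentzians L(x; Γ) = (Γ/2π)/(x² + (Γ/2)²)
with Γ = FWHM = 10 cm⁻¹ by default (16 cm⁻¹ is appropriate for broader
condensed-phase bands and is selectable).  The intensity convention is

ε(ν) = ν Σᵢ Dᵢ L(ν − νᵢ) / 2.296×10⁻³⁹,  Δε(ν) = 4 ν Σᵢ Rᵢ L(ν − νᵢ) / 2.296×10⁻³⁹,

i.e. the ν prefactor multiplies the Lorentzian sum.  Whether the ν
prefactor sits inside or outside the sum is a convention choice that
different spectrum-drawing tools make differently; because the overlap
estimate is normalized, the prefactor and both conversion constants
cancel out of S_ab, affecting only absolute-axis plots.  A regression
test covers the (weak) sensitivity of S to this choice via the
band-integral oracle.  The default grid has a 1 cm⁻¹ step padded
100 cm⁻¹ beyond the extreme sticks; a warning (not an error) is logged
when a user grid fails to cover all sticks ± 5·FWHM.

Frequency scaling multiplies stick positions only — band widths stay at
Γ.  Intensity matching against an experimental spectrum rescales the
calculated spectrum so its strongest band (largest |I|, relevant for
signed VCD) matches the corresponding experimental maximum.

Sign patterns are extracted as local extrema of the broadened spectrum
within a region, discarding extrema below 5% of the region's absolute
maximum, and reported from high to low frequency (the spectroscopic
reading direction).  Shoulders that never become extrema of the
broadened curve are not reported; the stick output exists for reading
those.

## Overlap and scaling optimization

S_ab is evaluated by trapezoid integration on a common uniform grid:
both spectra are linearly resampled to the finer of their two steps,
restricted to the comparison region.  Linear resampling is adequate
because the spectra are smooth at 1 cm⁻¹ relative to 10–16 cm⁻¹ band
widths; natively refining both grids from 1.0 to 0.5 cm⁻¹ changes S by
~10⁻¹⁰ on amide-band fixtures.  S is clipped to [−1, 1] to absorb
floating-point excursions past the Cauchy–Schwarz bound.  A spectrum
identically zero in the region raises an error rather than returning a
conventional value.

The scaling search is a dense grid scan (default 0.94–1.01, step 0.001,
covering the factors typical of harmonic DFT frequencies in the mid-IR);
at each f the ensemble spectra are rebuilt from f-scaled sticks, and the
*unweighted* sum S_IR + S_VCD is maximized — equal weighting is the
least-assumptive combination, and a weight option is exposed.  Exact
ties are broken toward the f closest to 1.  Experimental spectra are
compared as read; an optional linear-baseline subtraction exists but is
off by default.

## Synthetic fixtures

The generator emulates only the statistical structure the protocol
relies on: clusters of near-identical rotamers (sub-threshold coordinate
noise plus a random rigid motion and ≤ half the energy threshold of
energy jitter), distinct conformers separated by supra-threshold noise
and kcal-scale energy gaps, signed bands at chosen centers (default
1673/1668/1650/1643 cm⁻¹ with a −/+/+/− pattern, an amide-I-like
arrangement), and a pseudo-experiment whose frequency axis is multiplied
by a planted factor (0.975 by default) with optional Gaussian intensity
noise.  Because a raw coordinate jitter can perturb rotational constants
past the 1% criterion even when the RMSD is tiny, the planted jitter is
deterministically shrunk until the pair sits inside all duplicate
criteria with a 2× margin — the planted partition is then recoverable by
construction, which is what makes it a ground truth.

Geometries are perturbed rings, not valid peptides.  Passing tests
therefore demonstrate the correctness of the bookkeeping, geometry,
statistics, and spectral numerics — not that any particular chemical
system is well described; fixtures carry none of the anharmonicity,
solvent structure, baseline drift, or mode-mixing of real spectra.
Default fixture sizes (≤ 8 conformers, ≤ 12 atoms, 4 bands) keep the
full suite fast while exercising every code path; all generators are
pure functions of a mandatory seed, with module-local streams so new
generators never perturb existing fixtures.

## Degenerate inputs and tie-breaks

Empty ensembles, heterogeneous atom identities, duplicate labels,
missing energy fields, imaginary frequencies, all-zero spectra, and
non-overlapping regions all raise typed errors rather than coercing.
The energy-window filter always keeps the minimum-energy conformer;
`prune_duplicates` output order is ascending energy with stable sorting;
reversed region bounds are normalized.  Pipeline runs write a manifest
with sorted keys so reruns are byte-identical, and any stage failure
removes partial artifacts.

## Known limitations

Gaussian/Voigt line shapes and anharmonic corrections are out of scope;
the frequency-table TSV is an artifact-defined interchange format (no
community standard exists for per-mode VCD tables); the qm_log parser
targets one widely used frequency-job text layout ("Frequencies",
"Dip. str.", "Rot. str." lines) and is versioned behind a dialect flag
so other engines can be added.
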