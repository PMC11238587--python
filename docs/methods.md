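# Methods

`lamella` analyses lamellar stacks of stratum-corneum lipids — ceramides
(CER NS with a sphingosine base, CER NP with a phytosphingosine base),
cholesterol (CHOL) and free fatty acid C24 (FFA) — along three
complementary routes: lamellar diffraction, FTIR band analysis, and
structural/hydrogen-bond metrics on labeled coordinate snapshots.  A
synthetic-data module generates every input with known ground truth, so
the full chain is exercised without laboratory data or molecular
dynamics.

## Diffraction

**Indexing.** A lamellar phase with repeat distance *d* produces Bragg
peaks at q_n = 2πn/d.  Given peak positions and order assignments, *d*
is obtained by least squares on q; because the model is linear in 1/d
the minimiser has the closed form d = 2π Σn² / Σ(n·q_n).  Peaks not
matching the series within a fractional tolerance of the first-order
spacing (default 0.1) are reported unassigned — e.g. phase-separated
crystalline CHOL at q = 1.8 nm⁻¹, whose single-reflection spacing is
reported as 2π/q.  A peak exactly between two orders (possible only at
the tolerance bound 0.5) is resolved to the lower order and flagged
ambiguous.  Two-phase overlap (a *d* and a 2*d* phase share every even
order) is handled by indexing against each candidate *d* separately and
comparing unassigned sets.

**Corrections.** Bragg intensities are converted to structure-factor
amplitudes by |F_n| = sqrt(I_n·L/A_n).  For highly oriented lamellae the
Lorentz factor is L = q_n.  The absorption factor uses the symmetric-
reflection transmission form A_n = [sinθ/(2μl)]·(1 − e^(−2μl/sinθ)) with
sample thickness *l* and attenuation coefficient μ; A_n = 1 when μ = 0
(the default when μ is unknown).  Both are conventional choices for this
geometry; they are configuration inputs, not fitted.

**Phasing by contrast variation.** For a centrosymmetric unit cell the
phases are signs.  Measuring at several D2O/H2O ratios f makes the
signed F_n linear in f.  Per order, the unsigned amplitudes are fitted
to |a + b·f| by exhaustively assigning relative signs to the data points
(≤ 2^(m−1) combinations for m contrasts) and regressing; the global sign
of the line is anchored by the position of water: water resides at the
unit-cell border (x = ±d/2), where cos(2πnx/d) = (−1)^n, so the slope b
carries the sign (−1)^n.  The reported sign of each order is the sign of
the fitted line at the reference contrast (default: the lowest fraction,
conventionally 8% D2O, near the water match point).  For a
border-headgroup/border-water system with four orders this produces the
alternating pattern − + − +.  An alternative `water_slope="positive"`
convention is available for systems phased against a positive water
slope per order.

**Reconstruction.** The scattering-length-density profile is the
truncated cosine series ρ(x) = F₀ + (2/d)·Σ s_n|F_n|·cos(2πnx/d) on a
symmetric grid over [−d/2, d/2] (512 points by default), centrosymmetric
by construction.  F₀, the mean scattering density, is computed from the
molecular composition and mass density (`composition_f0`, one water per
lipid by convention) and only shifts the profile baseline.  The
deuterated-minus-protiated difference profile (both at the same
contrast) localises a deuterium label: for a CER NS with the last three
sphingosine carbons deuterated (NSd7, 7 deuteriums), the difference
peaks mark the sphingosine chain ends.

**Relative-absolute scaling.** The difference-profile label peak is
fitted (area SLD_a, height SLD_h); the scale factor k =
(known excess scattering length of the label)/SLD_a calibrates the
arbitrary units, with SLD_correct = k·SLD_h.  k is applied to the
structure factors.  This area-matching form is this package's
convention; linearity in the expected scattering and self-consistency
(k = 1 when the expected value equals the fitted area) hold by
construction.

## FTIR

**Thermotropic transitions.** The symmetric methylene stretch (νsCH₂)
sits below 2849 cm⁻¹ for conformationally ordered chains and above
2853 cm⁻¹ in the melted state, rising sigmoidally through each phase
transition (orthorhombic→hexagonal near 32 °C, hexagonal→liquid near
71–75 °C for these systems).  T_m is computed by a three-segment
piecewise-linear fit — breakpoints chosen to minimise total squared
error, T_m the temperature where the transition segment crosses halfway
between the plateau levels at the breakpoints — with a four-parameter
logistic fit as a cross-check (the two agree to ≲0.3 °C on synthetic
sigmoids).  A total rise under 0.5 cm⁻¹ is flagged as no transition
rather than fitted.

**Scissoring bands.** The δCH₂ band (1462–1473 cm⁻¹; δCD₂ 1085–1095
cm⁻¹) splits into an orthorhombic doublet with a central hexagonal
component.  Up to three Lorentzians are fitted in the band window; a
central candidate is always offered between the outer components and
declared absent if its fitted height collapses below 2% of the outer
mean.  Splitting is the outer-peak separation; OR/MID is the mean outer
height over the central height (undefined for a pure doublet).  OR/MID
is invariant to y-scaling of the spectrum.

**Amide bands.** Peak centers in 1500–1680 cm⁻¹ (amide I ~1650 cm⁻¹,
amide II ~1550 cm⁻¹) are fitted after anchoring a linear baseline on the
spectrum just outside the window; a split amide I reports both
components.

**Fourier self-deconvolution.** Lorentzian line narrowing: the
interferogram is multiplied by exp(2πγ|t|) (γ the assumed Lorentzian
half-width at half maximum, cm⁻¹; default 2.2) and re-apodized with a
Bessel-type window (1 − (t/T)²)², where the cutoff T is the
`smoothing` parameter (vendor-style 0–100 scale, default 76.7) as a
percentage of the transform length.  The linear trend joining the
spectrum endpoints is removed before the FFT and restored afterwards so
the implicit periodic extension has no step (a step's slowly decaying
transform would be amplified exponentially).  The t = 0 component is
untouched, so the band integral is preserved; γ = 0 returns the input
unchanged.  Edge ringing within a few linewidths of the window
boundaries is inherent to the method; resolvability claims are evaluated
in the band interior.

**Peak model.** All fitting uses the amplitude/FWHM parameterisation.
Pearson VII is h·[1 + 4(2^(1/m) − 1)((x−c)/w)²]^(−m): m = 1 is exactly a
Lorentzian, m → ∞ a Gaussian.  Areas are analytic per shape (e.g.
(π/2)·h·w for a Lorentzian).  Optimisation is bounded least squares with
centers confined to the window and widths positive, which prevents peak
swapping; user initials are rescaled to the data range so fits are
equivariant under y-scaling; peaks converging to one center are merged
with a warning; non-convergence is flagged on the result, never
silently ignored.

## Coordinate-snapshot analysis

The membrane normal is z.  Systems carry per-atom labels: molecule
class, chain (acyl/sphingoid/sterol/ffa chain), hydrogen-bonding site,
a 1-based carbon index along each chain, and a per-molecule headgroup
reference atom (amide N for CERs, hydroxyl O for CHOL, carboxyl C for
FFA — declared, not inferred).

- **Leaflets**: headgroup z values are sorted and split at the largest
  gaps — exact whenever plane separation exceeds plane width.  In a
  six-leaflet (three-bilayer) stack the four inner leaflets (no bulk
  water contact) form the analysis region for APL and hydrogen bonds.
- **APL**: box cross-section / mean headgroup count of the inner
  leaflets.
- **Bilayer thickness**: separation of the two most prominent headgroup
  maxima of the mass density profile inside the central-bilayer window
  (the middle two leaflets' planes ± 0.6 nm; the window choice matters
  only when bilayer headgroup peaks would otherwise be confused).
- **Density/SLD profiles**: z-histograms (0.05 nm bins, half-open
  [z, z+Δ)) weighted by atomic mass or bound coherent scattering length
  (b_H = −3.739 fm < 0 < b_D = 6.671 fm, the sign contrast that makes
  H→D substitution visible).  The protiated reference profile excludes
  water.  The bin sum equals the summed weights exactly.
- **Tilt and order**: the chain director is the eigenvector of the
  minimum eigenvalue of the chain's inertia tensor (unit masses,
  carbons only); tilt is its angle to z folded to [0°, 90°], undefined
  (raised) for an isotropically degenerate tensor.  S₂ is the largest
  eigenvalue of Q = ⟨(3/2)uuᵀ − (1/2)I⟩ over directors; directors are
  z-aligned in sign before averaging.
- **CER conformation**: directors oriented head→tail; an acyl/sphingoid
  inter-director angle above 90° is the linear (extended) conformation,
  otherwise hairpin.  Fractions are reported over a molecule selection
  (typically the inner leaflets).
- **In-silico deuteration**: a spec (class, chain, number of terminal
  carbons) flips H→D on the matching chain-terminal hydrogens; the NSd7
  label (CER NS, sphingoid, 3 terminal carbons) replaces exactly 7
  hydrogens per molecule.  Difference profiles are symmetrized,
  ρ'(x) = (ρ(x)+ρ(−x))/2 about the unit-cell center, and affinely mapped
  to [0, 100] (constant profiles have no scale and raise).

## Hydrogen bonds

Eight lipid sites: CER amide N–H (donor and acceptor), CER carbonyl C=O
(acceptor only), CER hydroxyls O1–H and O3–H, the CER NP-specific O88–H,
FFA carbonyl (acceptor only), FFA O–H, CHOL O–H; plus water as donor and
acceptor.  Pair-type enumeration counts unordered site pairs (self-pairs
allowed) in which one member donates and the other accepts: 33
lipid–lipid pairs, and with water 8 lipid–water plus 1 water–water, 42
in total.

A bond requires donor–acceptor distance < 0.35 nm (minimum image) and a
donor-centered deviation angle (between D→H and D→A) < 30°; the phrase
"angle formed by donor, acceptor and hydrogen" is mapped to this
donor-centered convention, the one the ~30° cutoff presumes, and both
cutoffs are configurable.  Intramolecular pairs are skipped.  Bonds are
counted once per donor-H/acceptor pair per frame, so bifurcated bonds
each count.  Neighbor search is a periodic k-d tree; correctness is
pinned to an all-pairs brute-force oracle in the test suite, not to the
search structure.

The census classifies each pair type: pairs touching the CER carbonyl
→ amide I; pairs touching the CER amide N–H → amide II; the CER–CER
N–H···O=C pair belongs to both and is subtracted once from the combined
amide I+II total.  With `inner_only`, both bond partners must lie in the
region: lipids of the inner leaflets plus waters within 0.5 nm (z) of
the inner headgroup planes' extent, which keeps bulk water out.
Per-molecule normalizations divide by the molecule counts actually
inside the region (CER lumping NS and NP); a class absent from the
region reports NaN.  Replicate statistics report mean ± SD and one- and
two-tailed unpaired t-tests, with zero-variance comparisons flagged
undefined.

## Synthetic data

**Stacks** are geometric constructions, not simulations: per-leaflet
square lattices whose cross-section realises the requested area per
lipid exactly; all-trans zigzag chains (0.125 nm axial C–C projection,
0.05 nm lateral offsets, explicit chain hydrogens) tilted by the
requested angle with seeded random azimuths; headgroup sites placed with
plausible sub-Å geometry at the unit-cell borders; linear ceramides
spread evenly so the requested fraction is realised exactly in count;
inner-leaflet water at the interior borders at the requested
waters-per-lipid; optional bulk water slabs outside the stack.  Defaults
are the studied conditions: three bilayers (six leaflets), d = 5.4 nm,
APL 0.334 nm², CER:CHOL:FFA 1:0.5:1 with CER NS:NP 2:1, 35% linear
ceramides, 12° tilt, 0.4 inner waters per lipid, 60 lipids per leaflet
(a lateral size that keeps all recoveries exercised while building in
under a second; tests use 16–60).  The builder rejects APL below
0.25 nm² as unable to pack two chains.

What the stacks do *not* emulate: thermal disorder, gauche defects,
chain interdigitation statistics, realistic headgroup conformers, or
self-assembly.  Passing recovery tests therefore demonstrates that the
*analysis* is correct on structures with known answers — not that real
membranes have those answers.

**Diffraction forward model**: a band-limited cosine unit cell (signed
coefficients per order) plus a border water Gaussian whose amplitude
grows linearly with D2O fraction and vanishes at the 8% match point, so
order n acquires a slope of sign (−1)^n.  Intensities are
I_n = F_n²·A_n/L with seeded multiplicative Gaussian noise; true signs
are stored.  Round trips through phasing and reconstruction are exact to
1e-9 at matched truncation by construction.

**FTIR generators**: Lorentzian band spectra (scissoring triplets/
doublets, amide bands) and logistic thermotropic curves with plateaus
below 2849 and above 2853 cm⁻¹, additive seeded Gaussian noise, ground
truth stored alongside.

## Numerical choices and limitations

- All generators are bit-reproducible for a fixed seed.
- Phasing with two contrasts is exactly determined up to the global sign
  convention; three or more contrasts add redundancy (R² reported).
  Orders whose signed F crosses zero near the reference contrast are the
  intrinsically hard case; the linear fit, not a per-point heuristic,
  decides them.
- The piecewise-linear T_m search is O(n²) in curve length — fine for
  typical thermotropic scans (≤ ~200 points).
- `symmetrize_and_scale` interpolates ρ(−x) linearly onto the grid, so
  asymmetric grids lose one bin of accuracy at most.
- The GRO/PDB label encoding (residue and atom names) is this package's
  own convention; arbitrary third-party topologies would need a mapping
  step naming their headgroup reference atoms and bonding sites.
- Tilt is computed per chain; per-lipid aggregation is left to the
  caller (the pipeline averages per-chain values over the central
  bilayer).
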