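# Methods

This note records the models, conventions and numerical choices behind
`crysvib`, in the order the pipeline uses them.  Nothing here states an
empirical result; every number quoted as a default is a choice, and every
check described is computed by the test suite or `scripts/acceptance.py`.

## Crystal model and torsion geometry

A `Crystal` is a P1 periodic cell: a 3×3 row-vector lattice matrix (Å),
fractional coordinates wrapped into [0, 1), element symbols from a fixed
periodic-table set, and a partition of sites into molecules.  No symmetry
beyond P1 is handled — disorder models and supercells are intrinsically
symmetry-free, and treating everything as P1 keeps one code path.

Bonds come from covalent radii (Cordero single-bond values) with a 1.2×
radius-sum tolerance; molecules are the connected components of that
graph, overridable by a user-supplied partition.  All distances are
Cartesian through the cell matrix with the minimum-image convention; a
molecule straddling a boundary is made whole by breadth-first traversal
that places each atom at its minimum-image position relative to an
already-placed neighbour.  This is valid while cells are much larger than
bond lengths, which holds for every structure this package targets.

Dihedrals use the IUPAC sign convention (right-hand rule about B→C,
cis = 0°), reported in (−180°, 180°]; the implementation is
cross-checked in the tests against an independent plane-normal oracle and
against `mdtraj`'s convention.  `set_torsion` rotates the
C-side connected component of the bond graph (with the B–C edge removed)
rigidly about the axis, so every internal coordinate not involving the
rotation is preserved exactly; attempting to rotate a ring bond raises.

Hydrogen-bond motif classification is nearest-eligible-acceptor: the S or
O closest to the donor thiol hydrogen over all periodic images within a
cutoff, excluding the specific covalently bonded image of the donor's own
sulfur.  The default cutoff is **3.0 Å** (H-to-acceptor) — chosen to
separate ~2 Å hydrogen-bond contacts from next-shell contacts; it is a
package choice, not a literature value, and is configurable.  An exact
distance tie between an S and an O acceptor resolves to S (logged); ties
are a measure-zero event only reachable in constructed geometries.

The dispersed-disorder generator assigns `round-half-up(fraction·N)`
torsions to the first motif angle and the rest to the second, drawing the
flipped subset uniformly without replacement from
`numpy.random.default_rng(seed)`.  The half-up rounding rule matters only
for odd torsion counts; the conventional use is exact halves at
(−78.4°, 87.0°).  Seeds are explicit arguments everywhere; the package
never touches global random state.

## File formats

CIF is parsed with `gemmi`'s CIF reader (cell parameters plus the
`_atom_site` fractional-coordinate loop; s.u. parentheses stripped) and
written as minimal P1 CIF.  VASP POSCAR (direct or Cartesian) and
extended XYZ (`Lattice="…"` row-major cell records, optional per-frame
`dipole="Mx My Mz"` and `time_fs` fields) use small dedicated
readers/writers, since no installed library reads the lattice record of
extended XYZ.  Force constants are plain-text row-major 3N×3N arrays
(eV Å⁻²); Born charges are one row of 9 per site.

## Γ-point phonons

The dynamical matrix is D = M^{−1/2} K M^{−1/2} with K Cartesian force
constants (eV Å⁻², symmetric within 1e-8 relative, else rejected).
Eigenvalues λ (eV Å⁻² amu⁻¹) convert to wavenumbers as
ν̃ = 521.47 √λ cm⁻¹, the conversion being derived from CODATA constants
via `scipy.constants` (one conversion table, `constants.py`, tested
against closed forms).  Negative eigenvalues are reported as
imaginary-flagged modes with negative ν̃, counted in a log warning, and
excluded from free energies and spectra — never silently dropped.

The acoustic sum rule is enforced by replacing self-blocks,
K_ii ← −Σ_{j≠i} K_ij, which touches no interatomic coupling.  For force
constants assembled from pair springs (symmetric 3×3 pair blocks — the
physical class) this leaves a symmetric matrix with exactly three
acoustic modes.  The acoustic tolerance is **0.5 cm⁻¹** by default,
configurable per `PhononModes`.

Mode character (translation/rotation/internal) is the squared projection
of each mass-weighted eigenvector onto a per-molecule rigid-body basis:
3 centre-of-mass translations plus up to 3 rotations about the centre of
mass (rank-deficient for linear molecules, empty for single atoms),
mass-weighted and QR-orthonormalized.  Percentages sum to 100 by
construction; completeness (Σ translational % = 100 × number of
translational basis vectors) is a test invariant.

## Free energies and stability

F_vib(T) = Σ_k [ħω_k/2 + k_B T ln(1 − e^{−ħω_k/k_BT})] over real,
non-acoustic modes; at T = 0 it is exactly the zero-point energy.
Relative stability on a pressure grid is
ΔG(P) = Δ[E + P·V(P) + F_vib(T)], normalized per molecule and reported in
kJ mol⁻¹.  V(P) is supplied per pressure by the caller (optimized volumes
from whatever engine produced E); no equation of state is fitted.  The
P·V term can be switched off (`include_pv=False`) to compare Helmholtz
energies at fixed optimized volumes — both conventions appear in the
literature for pressure-ranked polymorph plots, so the caller chooses;
crossovers are sign changes located by linear interpolation between grid
points.  Per-molecule (not per-cell) normalization is the default because
polymorphs of one compound differ in molecules per cell.

Torsion-profile analysis takes a periodic uniform grid (closure at ±180°
required within tolerance), finds all local minima under periodic
neighbour comparison (plateaus collapse to their first point), and
reports, for each ordered pair of angularly adjacent minima and each
connecting arc, the maximum energy along that arc above the departing
minimum.  These are **along-the-scan path barriers**, not transition-state
heights — the scanned dihedral is the only relaxed coordinate's
constraint, and the true saddle generally lies off the path.

## Static spectra (phonons → powder absorption)

Oscillator strengths: S_k = C·(Σ_a Z*_a·e_{k,a}/√m_a)⊗(same)/V with
C = e²/(ε₀·amu·Å³) expressed in cm⁻², so the Lorentz sum
ε(ω) = ε∞ + Σ_k S_k/(ω_k² − ω² − iγω) is dimensionless with everything in
cm⁻¹.  Acoustic modes of a sum-rule-enforced, charge-neutral cell have
zero strength (tested).  The default broadening is **γ = 5 cm⁻¹**.

Powder orientation averaging is tensor trace/3 *before* effective-medium
mixing.  The alternative order (mix each orientation, then average) is a
physically defensible variant for strongly anisotropic crystals; it is
rejected here for simplicity and single-path clarity, and users comparing
anisotropic systems should be aware the two orders differ at strong
oscillator strength.

Maxwell–Garnett for spherical inclusions:
ε_eff = ε_m[ε_i(1+2f) + 2ε_m(1−f)]/[ε_i(1−f) + ε_m(2+f)], default
**f = 0.10**, host **ε_m = 2.0** real (a PTFE-like value; the host is
configurable since published powder spectra rarely state it).  Only
spheres are implemented; Bruggeman mixing, ellipsoids, ATR and
air-void scattering corrections are out of scope.

Absorption is α(ω̃) = 4π ω̃ κ with κ = Im √ε_eff on the principal branch
clipped to κ ≥ 0, ω̃ in cm⁻¹, so α is cm⁻¹ per effective path length;
any molar conversion is a constant post-factor left to the caller and
recorded as such in the output provenance.  Kramers–Kronig consistency of
the Lorentz ε is verified numerically in the tests on a wide grid
(truncation documented there, < 2% relative error).

## Dynamic spectra (MD dipole → powder absorption)

The autocorrelation C(l) = (N−l)⁻¹ Σ_i δM_i·δM_{i+l} of the mean-removed
cell dipole is computed by zero-padded FFT; equality with the direct
double sum to ~1e-15 relative is an acceptance check.  The classical
linear-response permittivity is

  ε(ω) = ε∞ + β/(3Vε₀) [C(0) + iω ∫₀^L C(t) e^{iωt} dt]

with the integral trapezoid-discretized and evaluated by a
frequency-chunked phase matrix; V is the NVT cell volume or the NPT
trajectory mean, caller-declared.  Im ε is clipped at 0 (passivity;
clipping only ever acts on noise).  ε∞ defaults to 1 — a classical dipole
trajectory carries no electronic polarizability — and can be set to match
a static calculation.  The optional quantum correction multiplies Im ε by
the harmonic factor βħω/(1 − e^{−βħω}) and is off by default; both the
choice and the window are recorded in the spectrum provenance.

Windows (Hann, Gaussian, exponential, rectangular; all equal 1 at zero
lag) impose the line shape: with finite trajectories, peak widths are a
processing choice, not phonon lifetimes.  Two Hann presets mirror common
practice — a wide 2000 fs window for sharp THz features, a 400 fs window
for the congested region above 400 cm⁻¹.  `WindowSpec.lorentzian_match`
builds the exponential window that makes thermostat friction plus window
equal a target Lorentzian FWHM, which is how the dynamic route is
compared like-for-like with a static γ = 5 cm⁻¹ spectrum (the window is
truncated at 5 decay constants; the residual < 0.7% causes negligible
ringing).  The same Maxwell–Garnett step can be applied to the MD
permittivity (`powder_mix=`), which matters when comparing routes:
effective-medium mixing shifts resonances slightly above the bare TO
positions, so only identically mixed spectra should be compared
peak-to-peak.

A note on sampling: resolving features at 3000 cm⁻¹ needs a dipole
sampling interval below ~5 fs (Nyquist).  Intervals quoted in units of
picoseconds in MD protocols are incompatible with that band; this package
therefore requires the caller to state dt explicitly and defaults its own
synthetic trajectories to 0.5 fs.

`compare_spectra` resamples both spectra to the finer grid over a band
and reports the integrated-absorption ratio, per-peak position deltas
(nearest-peak matching above a 5% prominence floor) and cosine
similarity.

## Trajectory analysis

Torsion series are measured per frame with the same minimum-image
dihedral code, then unwrapped with minimal angular steps (period 360°);
inter-frame motion above 90° would flag undersampling.  Distributions are
histograms on (−180°, 180°] whose integrated area is normalized to
exactly 100 — a convention, kept exact so areas of sub-ranges read as
percentages.

Flip detection is a committed-state automaton.  Basins default to
SH···S-like τ ∈ [30°, 150°] and SH···O-like τ ∈ [−150°, −30°] (centred
near the +87°/−78° motif angles); everything else, including the region
around ±180°, is metastable and can never commit.  A flip is recorded
when a torsion committed to one basin resides continuously in a different
basin for at least the dwell time (default **0.5 ps**, anchored to the
observation that metastable ±180° visits of about that length precede
committed motif changes).  The automaton makes ambiguous flip-and-return
episodes deterministic: an excursion shorter than the dwell is no flip;
one longer is two.  Because "a flip" has no unique operational definition
in the literature, absolute flip counts from other workflows are
comparable only after matching basin edges and dwell.

`average_cell` reports arithmetic means and standard deviations of
(a, b, c, α, β, γ, V) over frames carrying cells.

## Synthetic generators — what they emulate, and what they do not

The toy crystal is a periodic cell of four-site polar bead chains with a
C–C–S–H-like connectivity: per-bond longitudinal springs (scaled
1.0/0.55/0.30 of `k_intra` to spread the optical modes), angle-like
second-neighbour springs, 0.3k transverse constants, nearest-contact
inter-molecular springs, a weak 0.02 eV Å⁻² all-pair floor that removes
the accidental zero modes of sparse spring networks, and acoustic-sum-rule
enforcement.  Born charges are isotropic, per-molecule charge-neutral
(pattern 0.35/0.15/−0.70/0.20 × scale), so at least one optical mode is
IR-active; ε∞ = 2.5.  What this emulates is the *structure* of the
problem — three acoustic modes, external modes below internal ones,
IR-active optical modes, two torsion basins near +87°/−78.4° with
~1 kJ/mol offset and ~6 kJ/mol path barriers.  What it does not emulate:
chemical realism, anharmonic coupling between lattice and torsion motion,
LO–TO splitting, temperature-dependent volumes, or hydrogen-bond network
cooperativity.  Passing tests therefore demonstrate correctness of the
analysis chain, not predictive power for any real crystal.

Harmonic MD is BAOAB Langevin on the 3N Cartesian displacements.  The
initial condition is drawn from the exact canonical distribution in
normal-mode coordinates (acoustic modes at rest), so no equilibration
phase is needed and equipartition holds from step one.  The default
friction **5×10⁻⁴ fs⁻¹** adds only ~2.7 cm⁻¹ of Lorentzian width so
spectral lines stay near their harmonic positions; the cost of weak
coupling is a slowly fluctuating kinetic-temperature estimate (the
5%-level equipartition checks in the tests use a stiffer 0.02 fs⁻¹).  The
integrator refuses dt larger than 1/20 of the stiffest mode's period.

Torsion dynamics is overdamped Langevin on one angle,
dτ = −V′(τ)/γ·dt + √(2k_BT dt/γ)·ξ, with V a two-term cosine series whose
four coefficients solve the linear system pinning both minima positions,
their energy offset, and the profile height at a named angle.  Defaults:
γ = 10 kJ mol⁻¹ ps rad⁻², dt = 0.01 ps.  Its stationary distribution is
the Boltzmann weight on the circle (KL < 0.05 at 10⁶ steps is a test);
escape rates agree with the overdamped Kramers estimate within a factor
of 3 (a sanity band, not an equality — Kramers assumes high barriers and
parabolic extrema).

The Ornstein–Uhlenbeck dipole uses the exact discretization
x_{n+1} = x_n e^{−dt/τc} + σ√(1−e^{−2dt/τc}) ξ per component, requires
dt < τc/5, and provides the analytic Debye reference spectrum.

## Problem sizes and determinism

Desk-scale defaults are chosen so the full test suite and the acceptance
script each run in minutes on one CPU: 1–4 molecule toy cells (up to
32-molecule supercells for disorder protocol checks), 10⁵–2×10⁵-step
harmonic MD, 20-seed ensembles of 10⁶-step (10 ns) torsion walkers for
occupancy statistics (flip-count noise dominates that estimator, so
trajectory length, not seed count, is the accuracy knob).  Every
stochastic component takes an explicit seed; pipeline reruns with the
same config are byte-identical, verified by manifest checksums.

## Known limitations

- Orientation averaging before mixing biases strongly anisotropic powder
  spectra (see above); only spherical inclusions are supported.
- The absorption scale is per effective path length; comparisons with
  measured extinction require a concentration/path calibration that is
  deliberately out of scope.
- The dynamic route is classical; the optional quantum factor corrects
  detailed balance but not zero-point motion.
- Flip counts depend on the declared basin/dwell convention.
- `set_torsion` requires the rotated fragment to stay whole under the
  minimum image; pathological cells smaller than a molecule are rejected
  by construction.
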