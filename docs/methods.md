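# Methods

This note records the models, conventions and numerical choices behind
`tmdimer`, and what the synthetic validation does and does not demonstrate
about real coarse-grained (CG) trajectories.

## Units and conventions

Coordinates are Angstrom, angles degrees wrapped to (−180°, 180°], energies
kJ/mol, temperatures K, k_B = 0.0083145 kJ/(mol·K).  Unit conversion happens
only at I/O boundaries (GRO files in nm are scaled ×10 on read, via
MDAnalysis).  Residue numbers are kept 1-based as read from files; internal
bead indices are 0-based and never serialized.

## Geometric descriptors

All descriptors are built from centres of geometry (COGs) of backbone (BB)
beads — one bead per residue — so they are insensitive to the presence of
side-chain beads.

- **Interhelical distance d**: Euclidean distance between the two helices'
  BB COGs.
- **Crossing angle Ω**: the dihedral over (N-half COG of helix 1, COG of
  helix 1, COG of helix 2, N-half COG of helix 2), where the N-half is the
  first ⌈n/2⌉ residues of the helical span.  The dihedral uses the standard
  atan2 form; positive Ω corresponds to left-handed dimers.
- **Rotation angles (phase, position)**: each helix's rotation about its own
  long axis, measured as the dihedral (partner COG, own COG, own upper-half
  COG, reference-residue BB bead).  The dihedral axis then runs along the
  helix, so the angle tracks the azimuth of the reference residue relative
  to the dimer interface: 0° means the reference residue faces the partner.
  *phase* is the angle of helix 1 and *position* that of helix 2; swapping
  the helix labels exchanges the two.  This choice — rather than putting the
  interhelical axis on the dihedral's central bond — is deliberate: with the
  interhelical axis central, the reference bead's perpendicular projection
  degenerates to a line segment and an imposed own-axis rotation cannot be
  read back.  With the convention used here a constructed rotation of 120°
  is recovered to better than 1°.
- **"Upper" COG**: interpreted as the N-terminal-half COG by default
  (extracellular side for a TM helix); configurable to the C-terminal half.
  The reference point for the rotation dihedrals is the residue's BB bead,
  the only bead guaranteed to exist.
- **Termini distances dN, dC**: distances between the first-residue and
  last-residue BB beads of the two helices.

Frames whose dihedral anchors are collinear (e.g. zero-radius degenerate
helices) yield NaN angles plus an explicit `undefined` flag; such frames are
excluded from density estimation rather than silently set to 0.

A descriptor row depends only on its own frame, so frame permutation
permutes rows identically and replicas are pooled by plain concatenation
with a provenance label.

## Synthetic dimer generator

The generator emulates CG backbone-bead dimer trajectories with known
ground truth.  Ideal helices use canonical α-helix Cα geometry — 1.5 Å
rise/residue, 100° twist/residue, 2.3 Å radius, 26 residues by default
(a typical TM span length); an optional side-chain bead per residue sits
2.5 Å radially outward.  Placement parameters are the descriptors
themselves: d, Ω, phase, position, plus an axial (membrane-normal) offset
of helix 2.  Because the half-helix COGs carry a small azimuthal offset
(≈0.22 Å for 13 beads at 100° twist), a one-shot construction misses the
requested angles by 1–3°; `place_dimer` therefore refines the construction
with a fixed-point loop that re-measures the descriptors with the geometry
module until they match the request to 10⁻³ degrees.  This also means
ground truth is verified, not assumed.  Two practical consequences of the
COG offsets are documented rather than hidden: a "parallel translated
copy" (dN = dC = d exactly) corresponds to position = phase + 180°, not to
phase = position; and spinning one helix about its own axis perturbs Ω by
up to ≈1.3° even though it leaves d exactly invariant.

Jitter is isotropic Gaussian per bead coordinate, i.i.d. across frames,
with no temporal correlation.  Trajectories are therefore piecewise
stationary with instant switches between arrangement segments.  What
passing tests on this generator show: the descriptor, contact, landscape
and pipeline code recovers known geometry and state populations to stated
tolerances.  What they do not show: behaviour on helices with flexible
loops, bent or kinked helices, correlated thermal motion, lipid
environments, or periodic-box artefacts (an optional orthorhombic
minimum-image mode exists for contacts, but trajectories are otherwise
assumed pbc-cleaned).

## Contacts

A residue pair (one residue per helix) is in contact when **any** bead of
one is strictly closer than the cutoff (default 6 Å) to any bead of the
other.  Strict "<" is deliberate: coordinates rounded to 0.1 Å can sit
exactly at the cutoff, and the inclusive/exclusive choice is then visible.
Occupancy is the plain pooled-frame fraction; intra-helix contacts are
never reported.  Difference maps align cells by residue number, so a point
mutation (same position, different residue name) compares cell-to-cell.

## Density landscapes and states

2D densities use a Gaussian product kernel with per-axis Scott bandwidth
h_i = σ_i·n^(−1/6) times a `bandwidth_adjust` multiplier (default 1.0,
matching common plotting defaults).  Below 2000 samples the kernel sum is
exact; above, samples are binned onto the 200×200 output grid and convolved
(truncation at 8σ), which agrees with the exact sum to grid resolution.
The grid pads the data range by 3 bandwidths and the density is **not**
renormalised afterwards, so the ∫ρ ≈ 1 invariant (1% tolerance) genuinely
checks coverage.  Angular axes are treated as linear on (−180°, 180°]:
populations near ±180° split across the seam, a known limitation shared
with maps drawn on linear axes.

Maxima are 3×3-neighbourhood peaks above a height fraction of the global
mode, greedily merged within a per-axis separation, ranked by density.
State regions are axis-aligned rectangles with closed-lower/open-upper
edges (so adjacent boxes tile without overlap); overlapping regions are
resolved by an explicit priority.  The default TrkA "active" box — both
rotation angles in [100°, 150°) — encodes the most populated arrangement
of the TrkA dimer in the phase-position plane.

## Well-tempered metadynamics

The toy sampler is overdamped Langevin (Euler–Maruyama):
dx = −U′(x)/γ·dt + √(2k_BT/γ)·dW, with polynomial potentials up to quartic
(the double well U(x) = a(x²−1)² + bx is the reference family).  Defaults:
γ = 1, dt = 0.002, T = 310 K.  The bias lives on a grid (default 1201
points over [−3, 3]); between nodes it is linearly interpolated, so its
force is piecewise constant; the inner loop is JIT-compiled with numba and
seeded, making every run byte-reproducible.

Hills of width σ = 0.05 are deposited every 5000 steps with the
well-tempered height W = W₀·exp(−V(s,t)/((f−1)k_BT)), W₀ = 0.05 kJ/mol,
f = 10.  The height formula includes k_B explicitly, the standard
well-tempered form with energies in kJ/mol.  `sum_hills` is exact Gaussian
summation over all hills with no kernel truncation.

The FES estimator is F(s) = −f/(f−1)·V(s) + C with C pinning min F = 0.
Reweighting uses the time-dependent offset
c(t) = k_BT·ln[∫e^{βfV/(f−1)}ds / ∫e^{βV/(f−1)}ds] with per-frame weights
∝ exp(β(V(s_t,t) − c(t))); since V and c change only at deposits, they are
evaluated once per hill epoch.  A simpler final-bias mode
(V(s_t, t_end), constant offset cancels) is available for comparison.

ΔG_bind = F(minimum over the bound window) − ⟨F⟩ over the unbound window;
negative values mean favourable association.  Windows are mandatory
explicit inputs (a helper suggests bound = contiguous region within 2 k_BT
of the global minimum, unbound = trailing region where |dF/ds| < 0.5 k_BT
per CV unit); no Jacobian or standard-state correction is applied.  Basin
comparisons in the validation use the basin-integrated form
G = −k_BT·ln∫e^{−F/k_BT}ds, compared against direct quadrature of the
analytic Boltzmann weight — an estimator-independent reference.

Convergence diagnostics follow standard practice: (1) the CV trace,
(2) hill-height decay, (3) ΔG(t) from time-sliced bias, (4) weighted block
analysis of the bound-state indicator, error evaluated every 10 blocks
from 1 to 1000.  The weighted block error reduces to
std(block means)/√(n_blocks) for uniform weights and uses an effective
block count W²/ΣW_b² otherwise.  With one block the error is undefined and
reported as NaN.

### Validation problem sizes

The double-well validation uses (a, b) ∈ {(5, 1), (6, 2), (8, 1.5)} kJ/mol
at 4×10⁷ steps (8000 hills) per setting — by then hill heights have
tempered well below W₀ and the recovered basin free-energy differences sit
within a small fraction of k_BT of quadrature.  "Sampled support" for the
reweighting consistency check is the region within 4 k_BT of the FES
minimum: outside it the reweighted histogram is dominated by counting
noise in bins the thermal ensemble rarely visits, which measures histogram
statistics rather than estimator agreement.

## File formats

PDB and GRO structures (and multi-model PDB trajectories) are read through
MDAnalysis.  Helix membership comes from two chains/segments, or, for
single-chain files, from a residue-numbering restart; anything else is a
"two helices required" error.  The plain-text fallback trajectory format
(magic header, `FRAME i time=t` records, one `x y z` line per bead) is the
portability contract: a truncated final frame is dropped with a warning,
while a mid-file bead-count mismatch is a hard error naming the frame.
HILLS/COLVAR files use the PLUMED whitespace-column dialect with a
`#! FIELDS ...` header; field order is preserved on write.  Every analysis
table carries `#` provenance headers (version, seed, parameters).

## Known limitations

- No circular KDE; rotation-angle densities split at ±180°.
- The toy sampler is 1D and overdamped; it validates the estimator chain,
  not CG molecular dynamics.
- Synthetic helices are ideal and fully helical; loop flexibility at the
  termini is not emulated (assignments can restrict the helical span when
  analysing real data).
- Contact minimum-image mode assumes an orthorhombic box.
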