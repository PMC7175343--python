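# Methods

`cgadsorb` simulates the adsorption of a coarse-grained protein onto charged
flat and nanostructured surfaces with Metropolis Monte Carlo in the NVT
ensemble. This note records the model, its assumptions, the numerical
choices, and what the synthetic test systems do and do not establish.

## Model

**Beads.** Each amino acid is a hard sphere carrying an integer point charge
at its center. Rigid bodies (a protein main body taken from a crystal
structure) use 2.5 Å beads placed at the Cα positions, a choice that gives a
realistic contact separation between charges rather than a realistic residue
volume; bead positions are fixed relative to one another. Flexible chains
(disordered regions built from sequence) use 2.0 Å beads so that bonded
residues sit at a realistic distance. At pH 7.4, Asp and Glu carry −1, Lys
and Arg +1; His, Cys and Tyr are treated as neutral. Chain termini are
separate spheres with +1 (N) and −1 (C); a terminus that is truncated in the
coordinates (its terminal residues unresolved) carries no terminal charge.
Bound ions become beads with their formal charge (Ca²⁺ = +2). Unresolved
residues contribute no beads to a rigid body. Mass per bead uses standard
average residue masses (terminal and ion beads carry formula masses); only
the mass-weighted radius of gyration is sensitive to them, and weakly.

**Interactions.** All energies are in kBT.

- *Screened electrostatics* between point charges: Debye–Hückel with the
  finite-size correction,
  `w = lB zi zj exp(-κ(r-σ)) / (r (1+κσ))` for `r ≥ σ`, `+∞` otherwise,
  where `σ` is the contact distance (sum of radii), `lB` the Bjerrum length
  and `κ⁻¹` the Debye length (≈19.2 Å at 25 mM 1:1 salt, 298.15 K,
  εr = 78.5).
- *Bonds* in flexible chains: harmonic, `kh (Rb − Req)²` with
  kh = 0.76 kBT/Å² and Req = 4.1 Å.
- *Lennard-Jones* between non-bonded chain beads, `4 εnb [(σ/r)¹² − (σ/r)⁶]`
  with εnb = 0.05 kBT — a weak generic cohesion, not a hydrophobicity model.
- *Charged wall*: Gouy–Chapman for a 1:1 salt,
  `w = 2 zi ln[(1+Γ0 e^{-κz})/(1−Γ0 e^{-κz})]` with
  `Γ0 = tanh(asinh(ρ̃)/2)` computed from the surface charge density in SI
  units. `z` is the bead-center height above the wall plane; the hard wall
  sits at one bead radius. There is no hydrophobic or van der Waals
  protein–surface term: adsorption in this model is purely electrostatic.
- *Nanoparticles*: charged spheres with total charge `4πR²ρ` (the same
  surface charge density as the wall), interacting with beads through the
  same screened-Coulomb term with `σ = R + r_bead`. The wall field is not
  corrected for the area shadowed by attached particles; terms are additive.

Temperature is fixed at 298.15 K (consistent with εr = 78.5). All SI
conversion is confined to the Debye length and Γ0; everything else works in
Å, e and kBT. The CODATA constants used are serialized into every run
summary.

**Geometry.** The cell is periodic in x and y (minimum-image convention for
every pair and particle interaction) and closed in z by a hard floor at the
wall plane and a hard ceiling at Lz. Nanostructured surfaces are triangular
("hexagonally packed") lattices of spheres tangent to the floor; the cell
must hold an integer number of lattice repeats (Lx = n·d, Ly = m·√3·d).
Projected coverage is `2πR²/(√3 d²)`; 20-nm spheres at 60-nm spacing cover
40%. Single free nanoparticles sit at the center of a spherical sampling
region with a hard outer boundary and no wall.

**Sampling.** Metropolis MC with symmetric proposals: rigid bodies use
whole-body translation (uniform in a cube) and rotation (uniform angle about
a uniformly random axis through the center of mass); flexible chains use
crankshaft (rotate the interior segment between two randomly picked beads
about their connecting axis), pivot (rotate one end about that axis) and
single-bead translation, mixed with equal weight. Default maximum steps are
5 Å / 0.3 rad (rigid), 1.0 rad (crankshaft/pivot) and 2 Å (bead); optional
step-size adaptation toward 30–50% acceptance runs during equilibration
only, so production sampling always obeys detailed balance. A sweep is N
attempted moves (N = bead count) for chains and 2 for rigid bodies. Energies
are tracked incrementally (only terms touching moved beads are recomputed)
and validated against a full recomputation at intervals; an infinite
starting energy is refused with instructions to re-initialize. Every run
records its seed, schedule, parameters and acceptance rates.

## Observables

- **F(z)**: free-energy profile `−ln P(z)` of the center-of-mass height,
  zeroed on the mean over the outer 20% of the sampled range (falling back
  to the outermost populated quartile when nothing out there is populated,
  flagged in the profile metadata). Empty bins are masked, not zero.
- **Orientation**: the molecule's long axis is the top eigenvector of the
  mass-weighted gyration tensor (sign fixed to z ≥ 0; degenerate,
  sphere-like bodies are rejected). Reported cosines are |axis·n̂| against
  the wall normal or against the unit vector from a nanoparticle center to
  the molecular center of mass, so 0 is lying flat/tangential and 1 is
  standing/radial.
- **g(r)** from a nanoparticle surface: shell counts over shell volume,
  normalized by the overall box concentration of the molecule (not a local
  bulk estimate).
- **Adsorbed fraction**: share of samples whose minimum bead-surface gap
  (wall or any particle) is within a cutoff. The molecule is "adsorbed"
  nowhere in the underlying physics, so the cutoff is a reporting choice:
  the default is two Debye lengths (≈38 Å at 25 mM), which spans the width
  of the screened-electrostatic well; it is a parameter and is reported with
  every number.
- **Surface excess**: `Γ = frac/(1−frac) · V_accessible/A_wall`. The raw
  adsorbed fraction of a single molecule depends on the bulk volume the box
  happens to offer, which differs between nanoparticle lattices (dense
  lattices displace more volume). Γ removes that confound and is the
  quantity compared across lattice spacings.
- **Polymer descriptors**: mass-weighted radius of gyration and the shape
  factor Ree²/Rg² (6 for a Gaussian chain, 12 for a rigid rod; a straight
  N-bead chain gives exactly 12(N−1)/(N+1)).
- Error bars use block averaging (10 blocks, ±1 SE).

Bin widths default to 2 Å (z and r) and 0.02 (cosine); all configurable.

## Synthetic test systems

No structure is downloaded anywhere in the package; all fixtures are built
by `cgadsorb.synthetic` deterministically.

- **Ideal chains** (freely jointed, uniform bond directions) provide the
  closed-form oracles `⟨Ree²⟩ = (N−1)b²` and `⟨Ree²⟩/⟨Rg²⟩ → 6`.
- **Charged rods**: collinear beads with a configurable longitudinal charge
  pattern. The default *fibrinogen-mimic rod* is a 445 Å rigid rod with net
  charge −8: a negative middle (−10 e spread over the central 70%), weakly
  negative ends, and three +1 "feet" per end sitting 25 Å off-axis. The
  off-axis feet emulate the positive patches that the thick end domains of
  the real molecule expose on their surface: when the rod lies with its
  positive face toward a surface the patches reach contact while the
  negative axis stays roughly one domain radius (≈25 Å, half the real
  molecule's end-domain thickness) away. A strictly collinear rod with the
  same charges cannot reproduce flat-lying adsorption on a negative surface
  — all its charges would sit at the same height, and the net negative
  charge would dominate — so the lateral offset is a structural feature of
  the mimic, chosen once from the real molecule's dimensions.
- **Synthetic fibrinogen stand-in**: a full PDB-format fixture with six
  chains (2×610 + 2×461 + 2×411 residues), ≈35% of residues unresolved
  (including two 410-residue Aα-chain C-terminal tails of side-chain charge
  −1 each), four bound calciums, a ≈450 Å rod geometry with thick end
  domains carrying positive surface patches, resolved net charge −8 e and
  −12 e once the unresolved tail charges and their C-termini are counted.
  It exercises the entire pipeline (PDB parsing with missing-residue
  remarks, coarse-graining, charge rules, MC, observables) with the
  documented bookkeeping of the real molecule. It is labelled synthetic
  everywhere: agreement on it validates the machinery, not the crystal
  structure.
- **Two-state toy**: one particle hopping between two sites with a known
  energy gap; the exact occupancies validate the Metropolis rule.

What passing these tests does *not* show: the mimic rod and the stand-in
have hand-placed charges and idealized geometry, so absolute adsorbed
fractions, well depths and orientation distributions are not predictions
for real fibrinogen; only the qualitative responses (more adsorption at
higher surface charge and on nanostructured surfaces, stronger protrusion
at higher curvature, flat-lying orientation on negative walls, an optimum
in lattice spacing) are meaningful comparisons.

## Study conditions and problem sizes

Simulated campaigns in the test suite use 25 mM 1:1 salt, surface charge
densities −0.001 to −0.01 e/Å², 20-nm particles (40% coverage; spacings
40/60/90 nm for the spacing scan), boxes of 600–2000 Å height, and runs of
3·10³ equilibration plus 3–4·10⁴ production sweeps averaged over 5–10
seeds. These sizes were chosen to resolve each trend's sign with the
package's own block-averaged errors; the single-molecule fraction estimates
remain dominated by capture/residence statistics, which is why trend tests
average several independent seeds rather than extending single runs.

## Numerical choices and edge cases

- Bead placement within a residue (Cα), terminal bead placement (backbone
  N/C atoms) and ion placement (the ion site) are conventions; the model
  only requires charge positions.
- Non-bonded exclusions: directly bonded neighbors skip the DH and LJ terms
  (they interact through the bond spring) but remain hard spheres; 1–3
  pairs interact fully. Configurable.
- LJ acts only between flexible-chain beads; rigid bodies have no
  intramolecular terms and interact with surfaces purely electrostatically.
- No interaction cutoff by default (interactions are already screened); an
  optional cutoff flag exists.
- Minimum image wraps x/y displacements to (−L/2, L/2]; z is never wrapped.
  No Ewald summation: with κ⁻¹ ≈ 19 Å and cells ≥ 60 nm, image interactions
  beyond the first are attenuated by e^{−30} or more.
- Relative solvent accessibility uses Shrake–Rupley SASA on heavy atoms
  (960 points, probe 1.4 Å, Bondi radii) against extended Gly-X-Gly
  maxima; residues at ≥20% count as accessible. Profile shapes, not
  absolute SASA values, are the meaningful output; other SASA dialects
  shift values by a few percent.
- Alternate locations: the first altloc is kept; glycans are ignored.
- Longitudinal profiles bin bead projections on the principal gyration axis
  into equal-width bins between the extreme projections; the summed charge
  profile conserves the net charge for any bin count.

## Known limitations

- Implicit ions and a mean-field wall: no ion–ion correlations, no charge
  regulation, no image charges.
- The main body is perfectly rigid (the real molecule has hinge
  flexibility) and the main body and disordered tails are simulated as
  separate molecules, never as one connected entity.
- No hydrophobic surface attraction; hydrophilic surfaces only.
- One molecule per box: no crowding, no multilayer adsorption; adsorbed
  "fractions" are single-molecule residence statistics.
- Absolute adsorbed fractions depend on the box height and on the adsorbed
  cutoff; only comparisons at fixed geometry (or via the surface excess)
  are meaningful.
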