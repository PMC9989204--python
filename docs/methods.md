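# Methods

This note documents the models behind each analysis, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical choices that affect results.

## Coordinate model and units

All quantities use nm / ps / unified atomic mass / elementary charge, the
conventions of the GRO format. Boxes are strictly orthorhombic; triclinic
input is rejected rather than silently truncated, because every analysis
here assumes a planar bilayer with a global z normal. Site indices are
0-based internally; GRO's 1-based serials are translated at the I/O
boundary. Coordinates are stored as read (unwrapped); wrapping happens on
demand per analysis — density profiles wrap, the lateral MSD requires
unwrapped input and rejects coordinates that jump more than half a box
edge between frames.

Minimum-image displacements wrap each component into (−L/2, L/2]. Every
distance-based analysis (bonds, RDF, contacts, bead reconstruction) goes
through this one primitive.

## The synthetic bilayer generator

The generator is kinematic, not physical: there are no forces, no
thermostat and no excluded volume. Its purpose is ground truth — each
observable the package computes has a closed-form expectation under the
generator, so recovery can be asserted exactly or within a stated
statistical tolerance.

- **Geometry.** `n_per_leaflet` lipids per leaflet on a square grid with
  spacing `√apl`, so the lateral box edge is `√(n·apl)`; phosphate planes
  sit at ± `phosphate_plane_sep`/2 around the box centre. Each lipid has a
  phosphate bead (charge −1), an amine bead (+1) offset 0.3 nm outward,
  and one rigid chain of `chain_sites` beads at 0.3 nm spacing pointing
  toward the midplane. Default geometry (64/leaflet, 0.5625 nm²/lipid,
  4.0 nm plane separation) gives a 6 × 6 nm patch of fluid-phase
  dimensions.
- **Tilt.** Chain orientation is drawn per chain and re-sampled every
  frame: a fixed polar angle, a hemisphere-uniform (isotropic) direction,
  or a folded Gaussian of width `tilt_param` degrees. Tilt is applied
  rigidly to the whole chain so per-bond and per-chain order parameters
  coincide — this is what makes P2 and S_CD closed-form.
- **Lateral dynamics.** Each molecule performs a rigid lateral random walk
  with independent Gaussian steps of variance `2·d_lat·dt` per axis, the
  exact discretization of 2-D Brownian motion with diffusion coefficient
  `d_lat`. The Einstein fit must recover `d_lat` to within sampling error.
- **Flips.** Scripted events mirror a molecule's z template through the
  midplane at `start_ps` and back after `residency_ps` (or never, if the
  residency extends past the end). These drive the flip-flop detector's
  ground truth.
- **Guests.** Rhamnolipid-like amphiphiles: a carboxylate bead (charge −1)
  planted exactly `depth_below_phosphate` nm below the nearer phosphate
  plane (the "just beneath the phosphates" localization regime), two
  hydroxyl beads, and two chains toward the midplane; alternating
  leaflets, uniformly random lateral placement.
- **Masses/charges/electrons.** Per-bead values are nominal but of
  realistic magnitude (phosphate 94.97 u / −1 e / 47 e⁻, amine 45/+1/26,
  chain bead 56/0/31). They exist so that density, charge and potential
  profiles have non-trivial, exactly conserved totals — not to reproduce
  any particular lipid's electron density.

What the generator does **not** emulate: conformational disorder within a
chain (chains are rigid rods), headgroup dynamics, undulations and
protrusions, water (beyond an optional uniform slab), electrostatic
screening and realistic partial charges. Passing tests therefore
demonstrate the correctness of the *analyses* under known geometry and
kinematics, not the realism of any membrane model.

## Leaflet geometry

Leaflets are split by the sign of `z_ref − z_mid`, where the reference is
one site per lipid (normally the phosphate) and `z_mid` is the mean
reference z of that frame; a molecule within `transit_band` (default
0.3 nm — smaller than half a headgroup, large enough to catch midplane
crossers) is labelled *transiting* and excluded from thickness and APL
counts. Thickness is the distance between mean reference planes. APL is
the lateral box area over the mean of the two leaflet counts (symmetric
for asymmetric bilayers); per-leaflet APLs are reported alongside, and
guests can be counted in or out — both conventions are reported because
field practice varies. This global-plane model is a deliberate
simplification relative to local-normal surface fitting; it is exact for
the flat bilayers studied here and inappropriate for vesicles.

## Order parameters

`cg_order_p2` computes `(3 cos²θ − 1)/2` per minimum-image bond vector
against +z, pooled over frames and equivalent bonds. Zero-length vectors
are skipped and counted; more than 1% skipped raises a warning.

`deuterium_order_scd` reports `|⟨(3cos²θ_CH − 1)/2⟩|` per carbon index
(absolute value, matching the usual positive-axis presentation). With
explicit hydrogens the measured C–H vectors are used. In reconstructed
mode two ideal tetrahedral C–H unit vectors are built in the plane
perpendicular to the C(k−1)→C(k+1) axis, split about the in-plane bend
direction by the ideal H–C–H angle (109.47°); terminal carbons have no
such axis and are omitted. For an exactly collinear chain the in-plane
bend direction is undefined; an arbitrary perpendicular is used, which is
exact for any analysis that depends only on θ_CH magnitudes relative to a
chain along z (the all-trans anchor) but is *not* equivalent to averaging
over the rotational degree of freedom — the test suite therefore checks
rotational averages with explicit hydrogens.

Error bars on order parameters are standard deviations over 5 equal
frame blocks (configurable), the usual block-averaging estimate for
correlated trajectories.

## Profiles and dipole potential

Densities are histogrammed on wrapped z after recentring each frame on
the mean z of the phosphate sites (configurable selection), which removes
bilayer drift that would smear profiles; bins are uniform and half-open
over the full box height, so the profile integral times the lateral area
recovers the selected total weight exactly (asserted to 0.1%). Electron
weights only make sense for atomistic-style site tables; for CG beads use
mass density.

The dipole potential double-integrates the binned charge density with the
trapezoidal rule, pinning both the field and the potential to zero at the
lower box edge. ε₀ enters once, as a named constant in e V⁻¹ nm⁻¹
(0.055263…), unit-tested against the parallel-plate closed form
σd/ε₀ (0.1 e nm⁻² over 1 nm → 1.809 V). A net system charge above
10⁻³ e attaches a warning: the double integral is then not
periodic-consistent. Binning (default 100 bins) and symmetrization are
left to the caller; profiles are not symmetrized by default.

## Contacts, RDF, kinetics

The RDF uses periodic KD-tree pair counting with minimum-image distances,
normalized per frame by the ideal-gas shell expectation; self-pairs are
excluded when selections overlap, and `r_max` must respect the
minimum-image bound (half the smallest box edge).

Contact recurrence is binary per frame: a (guest group, lipid class) pair
is "in contact" iff the minimum pairwise distance is below the cutoff.
Defaults are 0.35 nm for polar–polar (heavy-atom H-bond/salt-bridge
criterion) and 0.50 nm for apolar–apolar (van der Waals contact); both
are recorded in the output header, since conventions differ between
groups. The binary min-distance convention — rather than counting
simultaneous pairs — keeps the score in [0, 1] and robust to group size.

The lateral MSD averages over molecules and all time origins (FFT
algorithm) up to 50% of the trajectory length, after subtracting each
leaflet's per-frame centre-of-mass motion so collective drift does not
masquerade as diffusion (drift removal is switchable; with N molecules
per leaflet it biases MSD by a factor 1 − 1/N). Molecules that change
leaflet are excluded and reported. The Einstein fit takes the
least-squares slope over a fractional lag window (default 10–50%) and
returns D = slope/4.

Flip-flop detection: a crossing is the first frame with the opposite
leaflet label after frames with the original label; transiting frames
bridge — they extend a pending residency rather than resetting it, which
avoids splitting one event into many at the midplane. An event is
accepted iff the destination label is held for ≥ `min_residency`
(default 10 ns, the standard residency criterion for counting sterol
translocations); events whose observation window ends before either a
return or the threshold are reported censored, not accepted. Accepted
counts are monotone non-increasing in the threshold.

## CG mapping validation

Pseudo-CG beads are mass-weighted centres (not geometric centres) of the
atoms assigned to each bead, with atoms first made whole by minimum-image
reconstruction around the bead's first atom; a bead still spanning more
than half a box edge is rejected as ill-defined. Bond lengths use minimum
image; angles are in [0°, 180°]; dihedrals follow the IUPAC sign
convention in (−180°, 180°].

Histograms are compared only on identical binning (mismatches are errors,
never silently rebinned). The headline metric is the Jensen–Shannon
divergence in bits — symmetric, bounded by 1, zero iff identical — with
the overlap coefficient Σ min(pᵢ, qᵢ) reported alongside for
interpretability. The pass threshold defaults to 0.05 bits per term; the
underlying acceptance notion in the field is visual ("good
reproduction"), so the numeric threshold is this package's choice and is
configurable. Default bin widths (0.005 nm bonds, 2° angles, 5°
dihedrals, ranges padded 5%) resolve CG-scale bonded terms without
empty-bin noise.

## Pipeline and comparison

One YAML config drives a run (synthetic spec *or* input paths, selections,
analyses, parameters); all selections are parsed before any analysis
executes. Analyses run in dependency order, failures are recorded per
analysis in `manifest.json` without aborting the rest, and a fixed
config + seed reproduces every numeric output byte-for-byte (fixed float
formatting, no timestamps). Condition comparison (e.g. with vs without
guests) is parameter-locked: bundles produced with different parameters
are refused with a diff, because a Δ between differently-parameterized
runs is not an effect of the condition.

## Problem sizes used in tests

The automated checks run on desk-scale systems chosen so that each
stochastic tolerance has comfortable statistical headroom: 16–64 lipids
per leaflet, tens to a few thousand frames, 10⁶ orientations for the
isotropic P2 anchor, 10⁴ particles × 100 frames for the ideal-gas RDF,
and 5000 frames for diffusion recovery (fitted D within 15% of the
generator's coefficient; observed error is typically ≤ 7%).

## Known limitations

- Planar, z-normal membranes only: no curvature, no local normals, no
  Voronoi per-lipid areas.
- Heavy-atom distance criteria only for contacts; no donor–H–acceptor
  angle term.
- Electron densities require per-site electron counts; none are defined
  for CG beads.
- The dipole potential assumes near-neutrality; charged systems get a
  warning, not a correction.
- The generator's rigid chains make per-bond order parameters identical
  along the chain; real chains show a position-dependent order profile
  the generator cannot produce.
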