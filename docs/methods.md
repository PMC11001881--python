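# Methods

This note documents the models, numerical choices and known limitations of
`dualsbm`, in the package's own words.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Structure model and units

Structures are parsed into an ordered heavy-atom list (hydrogens dropped,
first alternate location kept, count of dropped altloc atoms logged).
Author residue numbering is used verbatim; insertion codes are part of
residue identity and selection ranges never span them.  Covalent bonds come
from CONECT records plus chemical-component templates and inter-residue
backbone linkage; residues without a template are kept as
`molecule_class="other"` with no inferred intra-residue bonds.

Coordinates are Å at every file interface and nm inside the simulation
stack; the conversion happens exactly once, when a topology is built.  The
force field is in reduced units: bead mass, contact well depth ε, and the
time unit τ are all 1, temperatures are in units of ε/k_B.

## Shadow contact map

A pair (i, j) is a native contact when |r_i − r_j| ≤ 0.6 nm, the category's
sequence-separation rule holds (≥ 3 residues within a chain for
protein–protein pairs, none for pairs involving nucleic acids, inter-chain
pairs always allowed), the pair shares no bond or angle term, and no third
atom occludes the segment.  Occlusion: atom k blocks the pair when the
distance from its centre to the open segment is below screening radius +
light radius (both 0.1 nm by default, both configurable) and k's projection
falls strictly between the endpoints.  Endpoints never occlude their own
pair.  The map is deterministic, invariant under rigid motion, monotone in
the cutoff (increasing it never removes contacts) and anti-monotone in the
screening radius; the test suite checks it against a dense ray-sampling
oracle on clouds of up to 120 atoms.

The 6 Å criterion is applied to heavy atoms only, since the intended inputs
are heavy-atom coordinate models.

## Potential energy terms

| term | form | default constants |
| --- | --- | --- |
| bond | ½ k_b (r − r₀)² | k_b = 2·10⁴ ε/nm² |
| angle | ½ k_θ (θ − θ₀)² | k_θ = 40 ε/rad² |
| dihedral | K_d[(1 − cos Δ) + ½(1 − cos 3Δ)], Δ = φ − φ₀ | K_d = 1 ε |
| dual dihedral | ½ [V(φ; φ₀ᴬ) + V(φ; φ₀ᴮ)] | — |
| contact | ε[(1 + (r_ex/r)¹²) ∏_b (1 − G_b(r)) − 1] | σ = 0.05 nm, r_ex = 0.04 nm, ε = 1 |
| non-native | ε_nn (r_nn/r)¹², truncated and shifted at 2.5 r_nn | r_nn = 0.25 nm |

The Gaussian contact well bottoms at exactly −ε at each native distance (up
to the small excluded-volume tail, < 2 %).  Bonds, angles, dihedrals and
proper dihedral enumeration come from covalent connectivity (every path
i–j–k–l around each bond; three-membered rings skipped); equilibrium values
are measured from the input conformation.  Non-bonded exclusions cover graph
distance ≤ 3 and all native pairs.  Analytic forces for every term are
validated against central finite differences (relative error < 10⁻⁴) and a
numba-compiled kernel is cross-checked against the vectorised reference to
10⁻⁹; the kernel exists purely for speed and the engine falls back to the
reference path (same trajectories — the noise stream is generated outside
the kernel) when numba is unavailable.

## Dual-basin merge

Both input topologies must share atom ordering and covalent topology.
Shared contacts with relative distance difference |r₀ᴬ − r₀ᴮ| / mean > 0.10
become two-well; dihedrals with periodic angular difference > 0.20 × 360° =
72° become two-well; all other shared terms, and all bonds and angles, keep
the state-B (active/target) values; state-unique contacts stay single-basin
at their own distance.  Both denominators are explicit configuration because
upstream conventions vary.  The divergence report (counts of dual contacts
and dihedrals) is bit-reproducible.  The ">20 %" dihedral criterion is
interpreted as an angular fraction of a full turn; an energy-based reading
would change which dihedrals are dual but not the merge machinery.

## Langevin engine

BAOAB splitting with one force evaluation per step; at γ = 0, T = 0 it
reduces to velocity Verlet.  Defaults follow the refolding protocol:
T = 0.67, dt = 0.002 τ, snapshots every 1000 steps, stop when the monitored
selection's best-fit RMSD to the target drops below 0.5 nm, cap 11 600 τ.
Trajectories are bitwise reproducible for a fixed seed.  Two documented
choices:

* The friction coefficient is not published for the original protocol;
  default γ = 1 τ⁻¹.  Consequently absolute first-passage times are
  meaningful only in their ordering, never in absolute value, and the tests
  assert orderings only.
* The source protocol's stop criterion is worded as RMSD against the
  *autoinhibited* structure although the simulated transition ends at the
  *active* structure; this is treated as a typo and the default monitors
  RMSD to the target (active) conformation.  The monitored reference is
  configurable, so either reading is available.

Energy conservation in the NVE limit is asserted as absence of secular
drift (difference of early/late segment means < 10⁻³ ε over 10⁴ steps);
the bounded shadow-energy oscillation of a symplectic integrator with
stiff bonds (k_b = 2·10⁴) is not drift and scales as dt² — at the protocol
step it is of order 10⁻² ε for a 10⁻³ nm jitter.  The thermostat holds the
time-averaged kinetic temperature within 2 % of the set point on a
100-atom system at the protocol step size.

## Order parameters and events

Q over a contact subset = fraction of pairs with current distance
< λ·r₀, λ = 1.2 (configurable); dual-basin contacts use the basin-specific
r₀ of the state whose Q is being computed.  Q_ID uses the autoinhibited
state's interdomain (NGN–KOW) contacts; Δd is the NGN–KOW
centre-of-geometry distance minus its active-state value.

Q_KOWα and Q_KOWβ subsets keep only *fold-discriminating* pairs: a pair is
dropped if it is a native contact of both states, or if its distance in the
other state's native structure already satisfies the formed criterion.
Without this filter the two Q values share a common baseline (≈ 25 % of
pairs at bead resolution) and Q_diff cannot span its nominal range.

Events are first threshold crossings per trajectory: domain dissociation at
Q_ID ≤ 0.30 (70 % of the interface broken), strand-pair formation at
contact fraction ≥ 0.5 per configured strand pair, association/locking at
≥ 0.75 of the factor–polymerase contacts.  First-passage histograms
conserve event counts (out-of-range events fall into the edge bins).
Landscapes are 2-D occupancy histograms that count every frame exactly
once; for fully dissociated frames (Q_ID = 0 carries no information) the
Δd axis is used in place of Q_ID.

## Geometry descriptors

* Superposition: Kabsch SVD with reflection rejection; collinear selections
  are refused (the rotation would be underdetermined).
* Swivel angle: superpose complex B onto A over the core module, then
  report the axis-angle magnitude of the best-fit rotation mapping A's
  swivel-module atoms onto the core-aligned B's.  Symmetric in its
  arguments to ~10⁻¹³ degrees.
* Helix axis: total-least-squares principal direction of per-base-pair C1′
  midpoints, oriented 5′→3′ along the first strand; radius = mean P-atom
  distance from the axis; hybrid diameter = 2 × radius.  Base pairing is
  supplied explicitly (config), not detected from geometry, to avoid
  ambiguity at distorted junctions.  This midpoint principal-direction fit
  is not the base-pair-step algorithm used by dedicated nucleic-acid tools;
  on ideal duplexes they agree exactly, on distorted ones differences of a
  few degrees are expected, which is why cross-validation tolerances for
  inter-duplex angles are ±5°.

## Synthetic fixtures: what they emulate and what they do not

**Two-state switcher** (`make_two_state_toy`): a rigid 12-bead anchor helix
(NGN stand-in) and a 14-bead switch (KOW stand-in) that is an anchor-docked
helix in state A (12 interdomain contacts) and a self-packed β-hairpin
displaced from the anchor in state B.  Both conformations are generated
from internal coordinates with identical bond length (3.8 Å) and bead angle
(the CA-helix value, 89.5°), so the merged model carries no bond or angle
strain and both endpoints are exact minima — mirroring the all-atom
situation where covalent geometry barely changes between folds.  The
hairpin turn is found once by a deterministic grid search maximising
clash-free cross-strand pairs.  The toy's switching temperature, measured
once at design time and frozen as `TOY_SWITCHING_TEMPERATURE = 0.85`, sits
above the interface melting onset (dissociation within ~10 τ) and below
hairpin melting; at T = 0.3 the α basin is stable on the test timescale.

What a green toy test does *not* establish: bead-scale resolution cannot
distinguish chain compaction from strand pairing by distances alone.  The
merged toy has a genuine compact intermediate — the docked helix bent at
its dual-dihedral turn — in which Q_KOWβ reads ≈ 0.9 while the helix and
interface are intact.  Fold completion is therefore marked by
Q_diff ≥ 0.5 (which requires the helix melted *and* the hairpin formed);
with that marker, interface breakage at the dissociation threshold precedes
fold completion in ≥ 90 % of transitions, whereas with the bare
Q_KOWβ ≥ 0.8 marker the measured ordering is 17/20.  Likewise the
12-contact interface quantises breakage in steps of 1/12, so the sharp
"≥ 60 % broken before the Q_diff zero crossing" bound is not expressible
between 58.3 % and 66.7 %: a minority of switching runs cross at exactly
7/12 = 58.3 % broken, and the corresponding acceptance assertion is left
failing with this analysis rather than weakened.

**Symmetric two-basin toy** (`make_symmetric_toy`): an arm tethered to the
midpoint of a straight base rail, docked at +y (state A) or −y (state B =
exact mirror image).  Mirroring is an isometry, so bonds and angles agree
exactly; merging with `dihedral_thresh = 0` makes every mirror-odd dihedral
a two-well (even) term, and the merged Hamiltonian evaluates *identically*
at the two endpoints (asserted as exact float equality).  Used for the
occupancy-symmetry check: pooled over 20 replicas, half started in each
basin, the Q_diff > 0 and < 0 occupancies agree within 3 standard errors.

**Ideal duplexes** (`make_ideal_duplex`, `make_bent_duplex_pair`): C1′ and
P pseudo-atoms on exact helices (36° twist, 3.38 Å rise, P radius 9.4 Å),
paired C1′ atoms antipodal so the midpoints lie exactly on the axis; the
true axis, radius and inter-axis angle are recorded as ground truth.  These
are oracles for the axis fit, not sequence-realistic nucleic acids.

## Scaling choices in the tests

The published refolding campaign is 500 replicas of an all-atom complex
with a 11 600 τ cap; the test suite and acceptance script run 20 replicas
of the bead toy for 500 τ (every toy switching event finishes within
~200 τ), the low-temperature stability check runs 400 τ instead of 10⁴ τ,
and the equipartition/temperature checks use 10⁵ steps.  These are runtime
scalings only; no threshold or tolerance was changed to fit the budget.

## Known limitations

* Deposited coordinate files (PDB entries, Zenodo models) are consumed
  as-is when present under `data/deposited/`, but are not shipped; the
  acceptance tests that need them fail with instructions in offline
  environments.
* Impropers/planarity restraints are not auto-generated from templates;
  the energy model supports only the terms enumerated from connectivity.
  For heavy-atom models with Gaussian contacts this does not affect the
  basin structure the package is built to study.
* Per-contact ε is uniform (1); any global contact:dihedral rebalancing
  used by other tools changes energy scales but not the divergence counts
  the merge reports.
* The engine is single-threaded by design (reproducibility); parallelism
  belongs at the replica level.
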