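# Methods

`pelkit` implements the potential-energy-landscape framework used to
characterise — and compare — force fields for structured biomolecules such
as RNA pseudoknots: locate the low-energy minima, find the first-order
saddle points (transition states) connecting them, assemble both into a
kinetic transition network (KTN), and summarise the network's topography
with disconnectivity graphs, funnel assignments and barrier queries.  A
coarse-grained RNA chain with swappable parameter sets plays the role of a
family of force fields so that every stage, including cross-model energy
re-ranking, can be exercised end-to-end at desk scale; all-atom engines
enter through the external-potential adapter.

## The landscape machinery

**Potential contract.**  Every model exposes `energy`, `gradient` and
(optionally analytic) `hessian` plus a count of invariant motions.  For
cluster and chain models the six rigid-body modes are projected out of
Hessian spectra (the invariant subspace is shifted far up the spectrum) and
out of gradient-convergence tests.  Finite-difference Hessians use a
centred step of 1e-4 in model units; gradients of every shipped model are
analytic and are tested against centred differences at relative tolerance
1e-5.

**Local minimisation** is L-BFGS followed, when the gradient RMS is still
above tolerance, by Newton polishing on the projected Hessian.  The
database-grade tolerance is 1e-6 kcal/mol/Å on the gradient RMS — tighter
than the deduplication energy tolerance, so two converged copies of one
minimum cannot straddle the matching threshold.

**Basin-hopping** perturbs all coordinates by a uniform random displacement
(half-width `step_size`), minimises, and applies a Metropolis test on the
*minimised* energies at temperature `T` (kcal/mol, i.e. kT).  The step size
adapts every 50 steps towards 50% acceptance.  Runs are reproducible from
the stored RNG seed.  Minima are deduplicated on the fly: by energy plus
aligned RMSD for distinguishable-bead systems, and by energy plus the
sorted interparticle-distance fingerprint for clusters of identical beads
(a permutation- and rotation-invariant signature; iterated
Hungarian/Kabsch alternation is kept only as an optional database-matching
pass because it is not a reliable global matcher).

**Transition states.**  Candidate saddles come from a doubly nudged elastic
band between two minima: 11 images by default, spring constant
10 (kcal/mol)/Å², improved-tangent nudging, with the doubly-nudged portion
of the perpendicular spring force retained, relaxed by FIRE until the
largest per-image force RMS falls below 1e-3.  Interior images that are
local energy maxima along the band are refined by hybrid
eigenvector-following: while the lowest (projected) Hessian eigenvalue is
positive, small uphill steps along that eigenvector push the search out of
the convex region; once it is negative, Newton steps with the sign of the
component along the lowest mode reversed converge to the saddle
(trust radius 0.3).  A converged point is accepted only with exactly one
negative eigenvalue; zero raises a rejected-candidate signal, two or more a
higher-order-saddle signal.  Band interpolation is linear in Cartesian
coordinates with a steric-clash repair pass that symmetrically separates
any site pair closer than half a diameter; this stands in for
quasi-continuous interpolation schemes, which are out of scope here.

**Descents from a saddle** displace ±0.05 Å along the negative eigenvector
(doubled up to four times on failure) and then run a small-step,
energy-monotone steepest-descent phase (move capped at 0.1 Å) before the
quasi-Newton polish.  The capped phase matters: a quasi-Newton minimiser
started at the saddle can hop straight across a shallow intermediate basin
and misassign the connectivity.

**KTN assembly.**  Stationary points enter the database through a matching
criterion (defaults: |ΔE| ≤ 1e-4 kcal/mol AND aligned RMSD ≤ 0.1 Å) chosen
to separate distinct minima of the toy models robustly; re-discoveries
increment a discovery count.  The connection driver joins two minima by
repeated cycles of: Dijkstra on a graph whose TS-backed edges are free and
whose missing edges cost squared structural distance (favouring short
interpolations), then a band search on the first unconnected gap of the
best path.  Degenerate rearrangements (a TS whose two descents reach the
same minimum) are stored but ignored by path queries.  Convergence of an
exploration is assessed across database snapshots: funnel count at fixed
ΔE, global-minimum energy, the minimax-barrier matrix between tracked
funnel bottoms, and the harmonic-superposition occupation of the lowest
basin (equal vibrational prefactors) at a reference temperature; all must
be stable to 1% over the last two snapshots.

**Superbasins and graphs.**  At each level E_ref + kΔE (E_ref defaults to
the global-minimum energy, ΔE to 1 kcal/mol) minima at or below the level
are merged by every transition state at or below it; stacking levels gives
the disconnectivity tree.  The exact merge energy of two minima is the
minimax barrier, computed by union-find over transition states in energy
order; the discretised merge level brackets it from above within ΔE.  A
funnel is a subtree whose lowest minimum lies at least `min_depth` below
the level where the subtree merges with a lower-energy subtree; shallower
subtrees are absorbed.  `min_depth` is a modelling choice the caller must
make (5ΔE is the documented heuristic).  Drawings order children by
subtree size, then lowest energy, then smallest member id — deterministic
and crossing-free — and a shared energy-axis configuration puts several
landscapes on one scale.

## The coarse-grained RNA chain

Three beads per nucleotide (phosphate P, sugar S, base B; bases carry a
purine/pyrimidine class) with the classic functional form: harmonic bonds
and angles, sinusoidal torsion terms A(1 + cos(nφ − δ)) on the four
backbone torsion classes, Lennard-Jones excluded volume/attraction
(Lorentz–Berthelot combining), and Debye–Hückel screened Coulomb
electrostatics for the phosphates (q_P = −1 e, dielectric 20, screening
length 9 Å — a typical monovalent-salt Debye length) standing in for an
implicit solvent.  An optional Gō-style well (3 kcal/mol at 4.5 Å) on
declared native base-base contacts gives the reference fold a
thermodynamic identity, the standard structure-based-model device.  Units
are kcal/mol and Å throughout; parameter sets serialise losslessly to a
keyed YAML block (`bonds`, `angles`, `torsions`, `nonbonded`).

Two parameter sets ship: `cg-default` and `cg-torsion2`, identical except
for torsion amplitudes and phases — the chain-model analogue of a dihedral
refit within one force-field family.  Helpers derive screening-length
variants, the analogue of exchanging one implicit-solvent model for
another.

**Order parameter.**  The fraction of native base-base contacts within
6.0 Å classifies minima as folded (≥ 0.8), partially folded (0.3–0.7) or
unfolded (≤ 0.2); representative seeding picks the lowest-energy minimum
in each band.

**Shipped fixture database.**  The re-ranking analyses run on a KTN of the
10-nucleotide hairpin GGGAAAUCCC (native pairs 1·10, 2·9, 3·8), populated
by basin-hopping with 120 steps from each of two starts — a folded hairpin
and an extended chain (seeds 11 and 12, step 2.0 Å, T = 2 kcal/mol).
These conditions were fixed once, during design, so that all three
order-parameter bands are populated (≈180 minima; roughly half unfolded,
a third folded, the rest partial).  On this database a 10% perturbation of
the screening length leaves the energy ordering of a stratified sample
essentially intact (Kendall τ ≈ 0.98) while swapping the torsion set
reorders it strongly (τ ≈ 0.35), with many discordant pairs among the
partially folded minima — ranking changes are a property of the potential,
not of the sampling.

## RNA structural descriptors

Multi-model PDB files are parsed with Biopython (first RNA-bearing chain
per model, first alternate location, residues renumbered 1-based).  Sugar
pucker is the Altona–Sundaralingam pseudorotation phase
P = atan2((ν4+ν1) − (ν3+ν0), 2ν2(sin 36° + sin 72°)) from the five
endocyclic torsions, with amplitude ν2/cos P; phases in [0°, 36°) are
C3'-endo (A-form).  Backbone α–ζ and glycosidic χ follow the standard atom
definitions; terminal torsions are reported as undefined, never imputed or
zeroed.

Base pairs are detected geometrically: ring centres within 7.5 Å, planes
within 35° of parallel, centres within 2.0 Å of coplanar (the feature that
separates pairing from stacking), and at least one donor–acceptor pair of
rim heavy atoms within 3.5 Å.  The interacting edge of each base
(Watson–Crick / Hoogsteen / Sugar; atoms shared between edges count for
both, ties break WC > Hoogsteen > Sugar) follows from which rim atoms
carry the hydrogen bonds; cis/trans annotation and the full edge-pair
taxonomy are out of scope.  G·C and A·U on both WC edges with ≥2 hydrogen
bonds are canonical; G·U on WC edges is wobble and counts toward the
canonical tally in profiles by default (toggleable); everything else is
non-canonical.  Stacking requires ring centres within 4.5 Å, planes within
30°, and in-plane centre offset ≤ 2.5 Å.  Pairs between sequence
neighbours (j = i+1) are excluded, as annotation tools conventionally do.
All cutoffs are configuration values; the defaults reproduce the
annotations of the idealised fixtures exactly.

Dot-bracket strings take canonical and wobble pairs only, resolve residue
conflicts in favour of the pair with more hydrogen bonds, and assign
crossing pairs to tiers `()[]{}<>` by first-fit on the crossing graph
(more than four mutually crossing tiers is an explicit overflow error).
Ensemble profiles average descriptors per residue over a basin's
structures — circular mean/SD for all angles, arithmetic for counts — and
report the dominant dot-bracket string with its frequency as a
secondary-structure homogeneity check.

## Synthetic fixtures and what they do (not) show

The fixture generator builds idealised geometry, not crystallographic
reality: bases are regular polygons with exocyclic donors/acceptors at
chemically sensible positions; pairs are posed by mapping the partner's
hydrogen-bonding edge onto target points 2.85 Å outside the first base's
edge (closed-form 2-D superposition plus a least-squares polish); riboses
are pentagons with out-of-plane displacements fitted to a prescribed
pseudorotation phase; stems stack pairs with A-form-like rise (2.81 Å) and
twist (32.7°); the pseudoknot fixture stacks a 3-bp stem coaxially on a
4-bp stem — the H-type arrangement — on a 21-nucleotide chain, with loop
residues placed outside every interaction cutoff; the "NMR-like" ensemble
is 14 such models with 0.05 Å Gaussian coordinate noise.  Passing tests on
these fixtures shows that the geometric annotators implement their
definitions exactly and are rotation/translation invariant.  It does not
show that the default cutoffs are optimal for experimental structures,
that the coarse-grained chain is a quantitative RNA model, or that
landscape topographies found here transfer to all-atom force fields —
those questions need real engines plugged in through the adapter.

## Numerical choices and problem sizes

Benchmark sizes are chosen so every pipeline runs on one CPU in minutes:
the Müller–Brown census uses 500 basin-hopping steps and pairwise
connection (recovering exactly 3 minima and 2 saddles against an
independent grid+Newton census); LJ7 uses 2000 steps from each of five
seeds (global minimum −16.5054 ε, four-minimum census against a long-run
oracle); barrier queries are validated against exhaustive path enumeration
on 200 random networks of up to 20 minima; the re-ranking analysis uses
the ~180-minimum hairpin database above.  Müller–Brown exponents are
capped at exp(200) far outside the region of interest so stray
basin-hopping moves cannot overflow; the stationary points are unaffected.
Energies serialise as shortest round-trip decimals, making database
read/write bit-exact and seeded explorations byte-reproducible.

## Known limitations

- Band interpolation is linear-plus-repair; tightly entangled endpoints
  that need internal-coordinate interpolation may yield poor candidates.
- Eigenpairs come from dense symmetric eigendecomposition, the right tool
  up to a few hundred coordinates; larger systems should supply analytic
  Hessian-vector products through the adapter.
- The Hungarian permutation pass is a heuristic matcher; for clusters the
  distance-fingerprint dedup is the robust path.
- Edge classification is three-edge, without cis/trans; hydrogen bonds are
  inferred from heavy-atom distances only (no explicit hydrogens).
- The Debye–Hückel term is a far-field caricature of implicit solvation;
  Generalised Born or surface-area models must come from an external
  engine.
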