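# pelkit — potential energy landscape exploration toolkit

`pelkit` characterises the potential energy landscape V(**x**) of a
molecular system by its stationary points: basin-hopping global
optimisation locates the local minima, doubly nudged elastic band (DNEB)
searches followed by hybrid eigenvector-following refine the first-order
saddle points (transition states) between them, and the resulting kinetic
transition network (KTN) — minima as nodes, transition states as edges —
is summarised by disconnectivity graphs, funnel assignments and minimax
barrier queries.  The motivating application is the assessment of
biomolecular force fields for polymorphic systems such as RNA pseudoknots:
different potentials for the same molecule can produce qualitatively
different landscape topographies (numbers of funnels, barrier heights,
which partially folded states are metastable), and those differences are
invisible to comparisons that only look at the native structure.

The toolkit is aimed at method developers and computational biophysicists
who want the full pipeline — exploration, network assembly, topography
analysis, per-nucleotide structural annotation of basin ensembles, and
cross-model energy re-ranking — runnable end-to-end on a desk machine.  It
ships analytic benchmark surfaces (Müller–Brown, quadratic bowl, double
well), Lennard-Jones clusters, and a coarse-grained three-bead RNA chain
whose interchangeable parameter sets stand in for a family of force
fields; all-atom engines plug in through an energy/gradient adapter.

Key quantities, in the field's standard notation:

- **Basin-hopping** samples the transformed landscape
  Ṽ(**x**) = min(V) over the catchment basin of **x**: perturb → minimise
  → Metropolis accept with probability min(1, e^(−ΔṼ/kT)).
- **Transition state**: stationary point with exactly one negative Hessian
  eigenvalue after projecting out overall translation/rotation.
- **Minimax barrier** between minima a, b:
  B(a,b) = min over paths p of max over transition states t∈p of E(t);
  branches of the disconnectivity graph merge at the discretised level
  E_ref + k·ΔE (ΔE = 1 kcal/mol by default) that first exceeds B.
- **Funnel**: subtree of the disconnectivity graph whose lowest minimum
  lies ≥ `min_depth` below the level where it merges with a lower-energy
  subtree.
- **Per-nucleotide descriptors**: sugar-pucker pseudorotation phase
  P = atan2((ν4+ν1)−(ν3+ν0), 2ν2(sin36°+sin72°)), backbone dihedrals α–ζ
  and χ, stacking and base-pairing counts, and pseudoknot-aware
  dot-bracket strings (crossing stems on separate bracket tiers).

## Worked example

Explore the Müller–Brown surface, connect the minima, and draw the
landscape:

```
$ pelkit explore --potential mueller-brown --nsteps 500 --seed 7 --out demo
explore: 3 minima, global minimum -146.699517

$ pelkit connect --ktn demo --potential mueller-brown
connect 0-1: connected (2 new TS)
connect 1-2: connected (0 new TS)

$ pelkit graph --ktn demo --delta-e 1.0 --min-depth 5 --out demo/graph
graph: 3 minima, 3 funnel(s) at min_depth 5.0
```

The three minima are the complete census of the surface (energies
−146.700, −108.167, −80.768), and the two transition states found by the
DNEB + eigenvector-following pipeline are its only saddles (−40.665 and
−72.249).  `demo/graph/` contains the disconnectivity graph (SVG + JSON
layout) and the barrier matrix; e.g. crossing from the global minimum
(id 0) to either other minimum requires passing the −40.664844 saddle,
read off row 0 of `barriers.tsv`.  With `--min-depth 5` each minimum
heads its own funnel (depths 108.0, 68.5 and 9.1 kcal/mol); raising
`min-depth` above 9.1 absorbs the shallow third funnel into its
neighbour.

Annotate an NMR-style ensemble of an H-type pseudoknot (here the built-in
idealised 21-nucleotide, 14-model fixture):

```
$ pelkit fixtures --kind nmr-like-ensemble --out fx
$ pelkit analyse --pdb fx/nmr-like-ensemble.pdb --out analysis
analyse: 14 model(s), 21 residues, dominant ((((.[[[.)))).....]]]
```

The dominant dot-bracket shows the two crossing stems of the pseudoknot
(4 bp on tier `()`, 3 bp on tier `[]`).  `analysis/profile_mean.tsv` has
one row per residue; residue 1, for instance, reports pucker phase 19.3°
(C3'-endo, as built), one canonical pair and one stacking partner.

Re-rank a database of coarse-grained RNA minima under a second parameter
set:

```
$ pelkit compare --ktn <db> --model-a toy-rna:GGGAAAUCCC:cg-default \
                 --model-b toy-rna:GGGAAAUCCC:cg-torsion2 --n 20 --out cmp
```

which reports Kendall τ, Spearman ρ and the discordant pairs.  On the
shipped hairpin database a 10% change of the electrostatic screening
length leaves τ ≈ 0.98 while swapping torsion parameter sets drops it to
τ ≈ 0.35 — energy re-ranking is a property of the potential, not of the
solvent caricature or the sampling.

Everything is also available as a library; see `docs/methods.md` for the
algorithms, defaults and their rationale.

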