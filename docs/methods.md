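# Methods

`allodyn` analyses conformational ensembles of homodimeric DNA-binding
regulators whose DNA affinity is allosterically controlled by a ligand
(the motivating system is a zinc-dependent MarR-family repressor).  The
package implements the analysis mathematics end-to-end and ships a
coarse-grained synthetic dimer with planted ground truth so that every
stage can be validated quantitatively on a desktop CPU.  It does not run
all-atom molecular dynamics; force-field simulation details of any source
trajectory are treated as provenance metadata.

## Units and conventions

Coordinates are in Angstrom, energies in kcal/mol, temperatures in K,
times in ps; k_B = 0.0019872041 kcal mol⁻¹ K⁻¹.  Residue identifiers are
author numbers from the input PDB (1-based, inclusive ranges) and are
never renumbered, so literature labels such as A71 map directly.  Only
the first MODEL of a PDB file is a `Structure`; multi-model files are
trajectories.  Alternate locations resolve to the highest-occupancy
conformer.  Hydrogens are kept when present; hydrogen-dependent analyses
degrade gracefully when they are absent (see Interactions).

## Accelerated-MD dual-boost mathematics

The boost potential raises the surface below a threshold `E_thresh`:

    V*(r) = V(r),                      V(r) ≥ E_thresh
    V*(r) = V(r) + ΔV(r),              V(r) < E_thresh
    ΔV(r) = (E_thresh − V(r))² / (E_thresh − V(r) + α)

`V*` is strictly increasing in `V` (the energy ordering of conformations
is preserved), continuous at the threshold, and approaches the asymptote
`E_thresh − α` from above as `V → −∞`.  The boosted force is the raw
force scaled by `dV*/dV = α² / (E_thresh − V + α)²` ∈ (0, 1].  The
dual-boost parameter prescriptions

    E_threshP = ⟨E_tot⟩ + 0.16·N_atoms     α_P = 0.16·N_atoms
    E_threshD = ⟨E_dih⟩ + 4·N_residues     α_D = (4/5)·N_residues

(all kcal/mol) are implemented as pure functions of conventional-MD
energy averages and system size.

Exponential frame reweighting (`w_i ∝ exp(ΔV_i/k_BT)`, max-subtracted
before exponentiation) is available but **off by default**: the landscape
stage histograms boosted frames directly, which mirrors the procedure the
package reproduces; reweighting is an explicit opt-in.

## Free-energy landscapes

Two reaction coordinates summarize the dimer ensemble: the pooled
C-alpha RMSD of the DNA-binding domain to a reference structure
(superposed on the same domain atoms by default; a different fit set,
e.g. the dimerization core, can be supplied), and the recognition-helix
separation measured between the two probe-residue C-alpha atoms (one per
chain).  Whether pooling or per-chain averaging was intended is
genuinely open; pooling is the default and the fit set is configurable.

The PMF on a 30×30 grid is `ΔG = −k_BT ln g(x, y)` with `g` the
normalized joint histogram, shifted so the minimum over defined bins is
zero; empty bins are undefined.  The sign convention is chosen so that
the most populated bin is the free-energy minimum.  Bin ranges default
to the observed [min, max] per axis and can be pinned explicitly so that
different systems share axes.

**Basins** are bins strictly lower than all defined 8-neighbours
(undefined neighbours count as +∞; ties disqualify).  On a histogram
with finite sampling, a broad well typically carries several
statistically co-deep strict minima, so the pipeline additionally
reports **major conformers**: 8-connected components of bins within
0.75 kcal/mol (~1.25 k_BT) of the global minimum.  That cutoff is the
depth resolution of the sampling used here — shallower features are not
statistically distinguishable — and sits below the inter-well saddle of
the synthetic reference landscape.  Each conformer's representative
frame is found by average-linkage hierarchical clustering of its member
frames on pairwise domain RMSD, cutting the dendrogram into two
clusters, and returning the medoid of the larger one (ties go to the
cluster containing the earliest frame; singleton sets return their only
frame; sets larger than 200 frames are subsampled evenly before
clustering).

## Correlation and community networks

The dynamic cross-correlation matrix uses C-alpha displacement vectors
after superposing all frames onto the iteratively recomputed mean
structure (whole-dimer fit; per-chain fitting is possible by selecting
one chain):

    C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^{1/2}

For display, entries with |C_ij| < 0.3 are conventionally masked.

The dynamical network has one node per residue; an edge connects
residues whose minimum heavy-atom distance is within 4.5 Å in at least
75% of frames (C-alpha-only mode available).  Same-chain sequence
neighbours (i, i±1) are excluded to avoid trivially dominant backbone
edges.  Edge weights are `w = −ln|C_ij|` (|C| floored at 10⁻⁶), the
standard choice that makes strongly correlated contacts short.  Optimal
paths between all pairs come from Floyd–Warshall with strict-improvement
updates, which deterministically prefers the path routed through the
lowest-index intermediate among co-optimal alternatives; **edge
betweenness counts one canonical optimal path per pair**, not all
co-optimal paths — path degeneracy is broken deterministically and the
choice is documented because it changes betweenness on symmetric graphs.

Communities come from Girvan–Newman edge removal: the current
highest-betweenness edge (canonical betweenness, recomputed each step;
lexicographic tie-break) is removed iteratively, each intermediate
connected-component partition is scored by Newman–Girvan modularity on
the *original, unweighted* contact graph (weighted scoring behind a
flag), and the first partition attaining the maximum is returned.
Communities with fewer than three residues are marked discarded: they
keep their labels in the output but are excluded from connectivity
reporting.  Inter-community connectivity is the maximum betweenness over
the edges joining each community pair.

## Protein–DNA interaction census

Three interface categories are counted from built-in atom-class tables
covering the 20 amino acids and the four DNA nucleotides (backbone
OP1/OP2/O3′/O5′/O4′ oxygens, base donors/acceptors, deoxyribose and base
carbons, thymine methyl under both C7 and C5M naming):

* hydrogen bonds — donor/acceptor heavy-atom pairs across the interface
  within 3.5 Å; when the structure carries hydrogens a D–H···A angle of
  at least 120° is additionally required, otherwise detection is
  distance-only (crystal structures usually lack hydrogens);
* ionic — side-chain cationic nitrogens (Lys NZ; Arg NE/NH1/NH2; His
  ND1/NE2) to phosphate oxygens within 4.0 Å;
* hydrophobic — apolar side-chain carbons (Ala/Val/Leu/Ile/Met/Phe/Pro/
  Trp plus Thr CG2) to DNA carbons within 4.5 Å, aggregated to one
  record per (residue, nucleotide) pair at the minimum distance.

The cutoffs are package defaults — the analysis they reproduce states
the categories but no geometry — so every report embeds the criteria
used; absolute counts are criteria-dependent and should only be compared
under identical criteria.  Counts are invariant under rigid motion and
monotone under cutoff tightening.

## Synthetic dimer generator

The generator builds a two-chain bead dimer in which every downstream
observable has planted ground truth:

* each chain is a string of compact blocks (two axial "pole" beads plus
  a ring, diameter 3.2 Å) spaced so that intra-block pairs rest well
  inside the 4.5 Å contact cutoff while inter-block pairs rest outside
  it except one bridge pole pair per adjacent block at 4.0 Å — the
  planted community layout; pole beads sit mid-sequence so bridge pairs
  are never sequence neighbours (which the contact stage excludes);
* all intra-block pairs and the bridges carry stiff harmonic springs
  (10 kcal mol⁻¹ Å⁻², plus 5 kcal mol⁻¹ Å⁻² hinge diagonals), keeping
  contact occupancies high and block geometry rigid;
* the centroid distance `s` between the two recognition blocks moves in
  a quartic double well `U(s) = h((s−c)² − w²)²/w⁴ − tilt·(s−c)` with
  minima exactly at d1, d2 and barrier height h for tilt = 0;
* dynamics are overdamped Langevin (Euler–Maruyama), massless, with an
  explicit seed; the optional boost applies the dual-boost force scaling
  to the double-well energy term only.

Because intra-chain elastic energies depend only on coordinate
differences within a chain, the stationary marginal of `s` is *exactly*
`p(s) ∝ s² e^{−U(s)/k_BT}` (the `s²` is the 3-D radial Jacobian).  The
quadrature helpers integrate this density for well populations, the
analytic free-energy gap, and the positions of the marginal free-energy
minima (slightly displaced from d1/d2 by the Jacobian and tilt) — the
closed-form targets every landscape test compares against.

### Study conditions

Three frozen scenarios (in `allodyn.studies`) size the synthetic
experiments for a single CPU:

* **landscape study** — 5-bead single-block chains, d1 = 20 Å,
  d2 = 28 Å, barrier 1.0 kcal/mol (~1.7 k_BT), tilt −0.02 kcal/mol/Å
  (balancing the radial Jacobian so both wells are comparably
  populated), friction 0.25, dt 0.01 ps, 10⁵ steps storing every 5th.
  These conditions give ~15–30 barrier crossings per run, enough for the
  stationary populations to equilibrate so that the measured well gap
  can be compared with the analytic value within bootstrap error.
* **crossing study** — the same geometry with a 3 kcal/mol (~5 k_BT)
  barrier: the rare-transition regime enhanced sampling exists for
  (unaided runs cross 0–2 times).  The boost threshold sits at the
  barrier top with α = 0.05·h, which nearly flattens the well-to-well
  profile; boosted runs cross an order of magnitude more often.
* **network study** — the full 40-beads-per-chain dimer (four 10-bead
  blocks per chain), 2×10⁴ steps; used for contact-graph and
  community-recovery checks.

Statistical tolerances follow from these conditions: the well-gap check
uses a block bootstrap (blocks of 2000 stored frames, comparable to the
correlation time of `s`) and a 3-standard-error band; basin localization
accepts the nearest of the *co-deep* basins (within 0.25 kcal/mol of the
side minimum — below that the histogram cannot order them) and requires
it within one bin of the analytic minimum.

### What the generator does and does not emulate

It reproduces the *structure* of the analysis problem: a two-state
collective coordinate, correlated/anticorrelated groups, persistent
contact blocks, and barrier-limited sampling.  It does not emulate
all-atom energetics, solvent, side-chain packing, or sequence-specific
protein–DNA recognition; the planted protein–DNA complex used by the
interaction tests is a bare geometric arrangement of donor/acceptor/
apolar atoms, labelled synthetic.  Passing tests therefore demonstrate
the correctness of the analysis mathematics and its implementation — not
that any particular biological system behaves this way.

## Numerical choices and degenerate inputs

* Kabsch superposition via SVD with a determinant correction (always a
  proper rotation); fewer than 3 points or collinear point sets are
  rejected.
* Zero-variance reaction coordinates and zero-fluctuation atoms raise
  informative errors instead of producing NaN surfaces/correlations.
* The Langevin integrator aborts when any |coordinate| exceeds 10⁶ Å or
  becomes non-finite, advising a smaller dt; stability requires roughly
  dt < 2ζ/Σk over the springs on a bead.
* DCD output pins the writer's free-text title line so repeated writes
  of the same trajectory are byte-identical.
* All randomness flows from explicit integer seeds; there is no global
  RNG state.

## Known limitations

* Betweenness counts canonical paths only; analyses that depend on
  co-optimal path multiplicity need a different betweenness definition.
* Girvan–Newman recomputes all-pairs paths per removal (O(E·V³) worst
  case); practical up to a few hundred residues, which covers the
  intended dimer systems.
* The crystal-structure separation check requires downloading the
  deposited entries; the packaged helper (`allodyn.core.fetch_pdb`)
  needs network access.
* Interaction counts ignore π-stacking, water-mediated bridges and any
  energy-based scoring; they are geometric censuses.
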