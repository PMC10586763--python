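# Methods

This note documents the model, the numerical conventions, the synthetic
data generator and the design choices behind `lspprn`, in the spirit of a
package methods appendix. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The LSP descriptor and alignment

A conformation is reduced to one Cα and one Cβ per residue. For a residue
pair (1, 2) the *link descriptor* is the quadruple

> d(Cα₁,Cα₂), d(Cα₁,Cβ₂), d(Cα₂,Cβ₁), θ(Cβ₁–Cα₁–Cα₂–Cβ₂)

— three Euclidean distances (Å) and the signed dihedral of the four-atom
sequence (degrees, IUPAC convention, range (−180°, 180°]). All four are
internal coordinates: proper rigid motions leave them unchanged (asserted
to 1e-9 Å / 1e-6°), and reflections preserve the distances while flipping
the sign of θ. This is what makes the method superposition-free.

Candidate links are Cα pairs strictly closer than the contact cutoff
(default 12 Å). Sequence-adjacent pairs are *not* excluded; this is
exposed only through the cutoff, not a bonded-neighbour rule. Two frames
are aligned by keeping a link — candidate in **both** frames — iff

> |Δd₁| < 0.2 Å, |Δd₂| < 0.45 Å, |Δd₃| < 0.45 Å, Δθ < 10°,

all comparisons strict, with Δθ the circular difference
min(|θ₁−θ₂|, 360°−|θ₁−θ₂|): −179° vs +179° is a 2° change, not 358°.
Requiring candidacy in both frames (intersection) is deliberate: an
orientation comparison is meaningful only for a link that exists in both
conformations.

### Window aggregation and normalization

A window of *m* frames (default 100; the canonical design is three
trajectories split into 100-frame windows, 15 windows total) produces
C(m,2) pairwise alignments — 4950 at m=100. The weighted network's edge
weight is

> W(i,j) = (# frame pairs retaining the link) / C(m,2) ∈ (0, 1],

i.e. "averaged and normalized" is read as the retention *proportion*. This
is the only normalization under which D = −ln W is a nonnegative length
and W behaves as a conservation probability. Edges never retained are
absent, not zero-weight. Windows are consecutive, non-overlapping, never
span trajectory boundaries, and trailing remainder frames are dropped with
a logged warning.

## Centralities

**Degree centrality** is the unnormalized weighted degree (node strength)
DC(v) = Σᵤ W(u,v). **Betweenness centrality** is unnormalized shortest-path
betweenness on edge distances D = −ln W. Both are used only in relative
comparisons (residue vs residue, construct vs construct), where
normalization constants cancel; absolute values depend on these
conventions and should not be compared across tools.

Numerical choices that matter:

- *Log base.* Natural log. Any other base rescales every distance by the
  same factor, which changes no shortest path and no BC value. The test
  suite asserts the correct form of this invariance — W → W^c (uniform
  distance rescaling) leaves BC unchanged. Note that W → c·W does **not**:
  it adds −ln c per *edge*, penalizing paths by hop count.
- *Zero-distance edges.* W = 1 gives D = 0 and is legal. Path counting on
  graphs with zero-weight cycles is ill-posed for predecessor-based
  (Brandes) algorithms, and enumerating every zero-length simple path
  through a fully conserved clique is combinatorial noise. BC therefore
  minimizes lexicographically (total distance, hop count): among
  minimum-distance routes only fewest-edge ones count, each with its
  multiplicity. This is implemented as an in-house Brandes variant with
  Dijkstra on (ΣD, hops) tuples; it reduces exactly to standard weighted
  betweenness when all distances are positive (cross-checked against
  networkx in the tests, and against an exhaustive simple-path enumeration
  oracle on small graphs).
- *Determinism.* Graphs are built in sorted roster/edge order; community
  detection (greedy modularity on W, via networkx) is canonicalized by
  ranking communities on mean DC with lowest-residue-index tie-breaks.
  Reruns are byte-identical.

**Aggregation.** Per-residue DC/BC window values are summarized as mean and
standard error SE = SD/√m with the sample (m−1) standard deviation over m
windows. Mutant constructs are compared with the reference as
100 × (mut − ref)/ref of the mean; residues with reference mean 0 are
reported as undefined (`NA`), never silently dropped.

## Virtual Cβ

Glycine has no Cβ, but the descriptor needs one per residue. A virtual Cβ
is placed from backbone N/Cα/C by ideal tetrahedral geometry: the unit
direction making equal 110.5° angles with Cα→N and Cα→C, tilted out of the
backbone plane on the L-amino-acid side, at 1.521 Å. The construction was
validated against the standard linear-combination Cβ reconstruction used
in structure prediction (agreement ≈ 0.015 Å on ideal backbones, well
inside the ~0.35 Å spread of real Cβ positions). Collinear or coincident
backbone atoms raise a degenerate-geometry error naming the residue; a
*missing* Cβ on a non-glycine residue is a hard error, never imputed.
`glycine_mode="drop"` excludes glycine nodes entirely, for sensitivity
analysis.

## Synthetic ensembles

The generator emulates what an MD ensemble of a small zinc-finger-like
domain looks like *to this analysis*; it is explicitly not a physical
model. Defaults (chosen once as a realistic operating point and then left
alone):

| parameter | default | meaning |
|---|---|---|
| `n_residues` | 50 | C1A-domain-like chain length |
| `rigid_blocks` | residues 5–14, 33–42 | the two Zn²⁺-hub analogs |
| `flexible_set` | residues 18–26 | the surface loop analog |
| `sigma_rigid` | 0.15 Å | per-residue jitter inside blocks |
| `sigma_flex` | 1.2 Å | independent loop jitter |
| `sigma_background` | 0.4 Å | remaining residues |
| `rot_jitter_deg_per_ang` | 8 °/Å | local Cα→Cβ orientation jitter, scaled by σ |
| `block_wobble_deg` / `_trans` | 2° / 0.1 Å | shared per-block rigid wobble |
| `global_motion` | on, ±20 Å + uniform rotation | per-frame nuisance motion |

The base fold is a deterministic spherical spiral with 3.8 Å Cα spacing
(radius auto-scaled so the chain fits; adjacent turns sit ~7 Å apart, so
the 12 Å contact graph is sparse but well connected) with Cβ offset
radially outward. Per frame, each rigid block receives a shared small
rigid wobble, every residue receives class-dependent positional jitter
plus a small random rotation of its Cα→Cβ vector (so descriptors degrade
through genuine orientation change), and finally an arbitrary global rigid
motion is applied. Jitter and global-motion draws come from independent
child streams of the seed, so toggling global motion changes nothing
internal — downstream networks are identical, which is the package's
strongest self-check of superposition-freedom.

The σ values map onto descriptor tolerances sensibly: a per-residue
translation σ perturbs a pair distance between two frames by ≈ 2σ, so
rigid-block links (2σ ≈ 0.3 Å vs the 0.2 Å primary tolerance) retain
moderate-to-high W while flexible-loop links (2σ ≈ 2.4 Å) almost never
match — the planted rigidity ordering emerges as a DC ordering.

**Coupling** (`apply_coupling`) moves loop residues with a target block's
shared transform and block-level jitter — the network analog of the
proline mutation that pins the ligand-binding loop to the hydrophobic
core. `remove_coupling` restores the original specification exactly (the
rescue analog).

What the generator does **not** emulate: force-field energetics, solvent,
Zn²⁺ coordination chemistry, anharmonic transitions, correlated
side-chain packing beyond Cβ. Passing tests therefore demonstrate that
the *pipeline* recovers planted rigidity structure under realistic noise
and nuisance motion — not that any particular biological system behaves
this way.

## Problem sizes used in tests and the acceptance script

Unit and property tests use 2–50-residue frames and 2–100-frame windows.
The acceptance script runs the full canonical design — 3 trajectories ×
500 frames per construct, 100-frame windows, 15 windows per construct,
50 residues — for three constructs (wild-type-like, stiffened-loop,
rescued), which keeps a complete from-scratch reproduction under a
minute on one CPU. Statistical recovery checks (rigidity ordering,
stiffened-loop sign recovery) run over 10 generator seeds with margins
frozen from pilot runs: rigid/flexible mean-DC ratio > 3, and a 100%
noise bound on loop |ΔDC%| between independent realizations of the same
condition (observed noise ≈ 15–40%, observed coupling effect ≈ +1000%
or more per loop residue).

## Known limitations

- DC/BC absolute scales are convention-dependent (unnormalized here);
  only relative profiles are meaningful across tools.
- The hub partition (greedy modularity) is one replaceable choice among
  many community methods; it is deterministic but not canonical.
- The PDB reader requires identical residue rosters across models and one
  chain per analysis; heterogeneous ensembles must be curated first.
- Binary MD trajectory formats are out of scope by design; convert to
  multi-model PDB (any tool, e.g. mdtraj/MDAnalysis) before ingestion.
- With very small windows (m < ~20) W is a coarse proportion and SE
  estimates over few windows are themselves noisy.
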