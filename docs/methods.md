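# Methods

## Scope and model

`cofnet` implements the structural post-analysis used to reason about
electron transfer in multi-cofactor redox enzymes.  The underlying physical
picture is the standard tunneling argument: single-step electron transfer
between redox centers is productive when the closest approach of their
cofactor atoms (edge-to-edge distance) is within roughly 14 Å; beyond that,
transfer requires either an intervening relay or a conformational change
that shortens the gap.  The package therefore treats a structure as a set of
rigid cofactors, reduces it to a weighted graph, and asks purely geometric
and graph-theoretic questions: which centers are connected at a threshold,
which nodes branch or dead-end, which route minimizes its largest step, and
how distances change between conformational states.  No rate, driving-force
or reorganization-energy modeling is attempted — inputs for a Moser–Dutton
treatment are not part of the data this package consumes.

## Distance metrics

Both conventions in common use are computed for every pair:

- *center-to-center*: Euclidean distance between geometric centers.  For
  flavins (FMN/FAD) and NAD the center is taken over the redox-active ring
  system (isoalloxazine, nicotinamide) rather than the whole molecule, since
  the phosphate/adenosine tails are not part of the redox moiety.
- *edge-to-edge* (side-to-side): minimum over all cross atom pairs,
  hydrogens excluded by default (models at ~3 Å resolution carry no reliable
  hydrogen positions; a flag reinstates them).  Ties are broken by source
  atom order.

The threshold is applied to the edge metric, matching how exclusion
arguments ("more than 22 Å, too far to transfer") are made in practice.
Reported precision is 0.1 Å; internal computation is full double precision.

## Graph construction and path analysis

The electron-transfer graph has an edge wherever edge-to-edge distance ≤ τ
(default 14 Å); edges carry both metrics.  The graph is undirected — the
enzymes of interest run reversibly (bifurcation/confurcation), so
directionality is an interpretation layered on top, not a property of the
geometry.  Topology classification: branch points are nodes of degree ≥ 3,
dead ends are degree-1 nodes not designated entry/exit terminals, and
connected components are reported outright.  Simple paths are enumerated
exhaustively (the graphs have ~15 nodes; worst-case enumeration is trivial)
and sorted by node count, then largest step, then label sequence.

The minimax (bottleneck) path is computed without any threshold on the
complete distance graph: the bottleneck value is read off the minimum
spanning tree (the MST path between two nodes attains the minimax bottleneck),
then among all paths within that bottleneck the one with fewest nodes and
lexicographically smallest label sequence is returned.  A 1e-12 Å slack is
used when thresholding at the bottleneck to absorb float round-off.

## Cofactor detection

Hetero residues are matched against a component-code dictionary
(SF4 → [4Fe-4S]; FES/FS2 → [2Fe-2S]; F3S → [3Fe-4S]; FMN; FAD; NAD/NAI).
The bimetallic NiFe site is assembled, not matched: each Ni atom is paired
with its nearest Fe atom not already claimed by an FeS cluster, accepting the
pair within a 3.5 Å cutoff (bridged bimetallic separations in hydrogenases
are ~2.6 Å, well inside; the cutoff also sweeps in carbonyl/cyanide ligand
components such as FCO).  A Ni with no partner is reported as CUSTOM with a
warning rather than an error.  Labels are deterministic (chain + ordinal)
unless a user label map supplies conventional names (A1–A5, B1–B5, C1, S1,
NiFe, FMN, NAD).

Coordination shells list protein side-chain S/N/O donors within a cutoff
(default 3.0 Å) of any metal atom of a cofactor, each with its minimal
distance; backbone N/O are excluded.  This is the tool used to exhibit
unusual shells such as the 4-Cys + His coordination of the B2 [2Fe-2S]
cluster.

Stoichiometry converts type counts to elemental totals via the dictionary
(fe_total = Σ count·fe_per_type, likewise Ni) and reports Fe:Ni as an exact
rational, undefined (None) when no Ni is present.  The hydrogenase pentamer
composition 8×[4Fe-4S] + 4×[2Fe-2S] + 1×NiFe gives 41:1.

## Superposition and domain motions

Least-squares superposition uses the Kabsch SVD construction with the
determinant correction, so the returned matrix is always a proper rotation;
reflection-related inputs superpose with a residual instead of inverting
chirality.  Atoms are paired by (chain, residue number, insertion code, atom
name) identity — states are models of the same molecule, so no sequence
alignment is attempted, and any identity mismatch is an error rather than a
silent partial pairing.  Inputs with fewer than 3 pairs or collinear
geometry are rejected.

A domain motion between states A and B is extracted by superposing B on A
over a user-chosen core selection, then superposing the domain selection of
the core-aligned B onto its position in A.  The rotation angle comes from
the matrix trace, θ = arccos((tr R − 1)/2) ∈ [0°, 180°]; the axis from the
antisymmetric part (eigenvector fallback near 180°).  The reported axis
denotes the rotation line with its sign chosen so the translation component
along it is non-negative; θ is unchanged by swapping the states.  Angular
precision under coordinate noise scales as σ/(r√N) for a domain of N atoms
with radius of gyration r — recovery of a constructed 24° motion is exact to
1e-6° on noiseless coordinates and stays within 0.5° at σ = 0.2 Å for
protein-domain-sized selections (hundreds of atoms, tens of Å); a 4-atom
cluster alone is too small a lever arm for that precision, which is why the
noise tests rotate whole chains.

State comparison reports, per requested label pair, the edge distance in
both states, the delta, and a flag marking pairs within τ in exactly one
state — the signature of a conformational gate.

## The synthetic generator

The generator realizes distance-geometry specifications: rigid idealized
templates — a distorted cubane [4Fe-4S] (Fe–Fe 2.70 Å, Fe–S ~2.3 Å), a
rhombic [2Fe-2S] (Fe–Fe 2.70 Å), a planar three-ring isoalloxazine, a
nicotinamide ring, a Ni–Fe pair at 2.6 Å — are translated until every
constrained pair sits at its target (edge-to-edge, center-to-center, or
between two named atoms) within tolerance (default 0.05 Å) and every
unconstrained pair exceeds a repulsion floor.  Orientations are drawn once
per body from the seed; the solver is a sequential projection
(position-based-dynamics style) on rigid-body translations, preceded by a
cheap center-only spring embedding for initialization, with decaying gain
(the edge metric is only piecewise smooth — the achieving atom pair switches
— which otherwise produces limit cycles), deterministic jitter kicks to
escape repulsion/constraint stalemates, and seeded restarts.  Infeasible
systems raise an error listing the violated constraints.  Output is
bit-for-bit reproducible given (spec, seed).

The packaged heteropentamer fixture encodes the cofactor topology of the
electron-bifurcating NiFe-HydABCSL hydrogenase: 13 cofactors in the
flavin-free apo state (A1–A5, B1–B5, C1, S1, NiFe — the as-purified enzyme
loses its flavin), plus FMN and NAD in the holo BR/PB states.  Distance
targets carried by the published analysis: FMN–B1 6.0; C1–FMN 15.5 (BR);
C1–B2 19 (apo) / 13.4 (PB); B2–B3 18 (apo) / 17.0 (PB); C1–B3 17.4 (PB);
B1–C1 kept at 23 (> 22 exclusion); C1–B5 11; NAD C4–FMN N5 4.2.  Fixture
parameters chosen here, not published values: unlabeled chain steps default
to 11.0 Å (safely inside τ); C1–FMN in the PB state is set to 13.5 Å so that
C1 exhibits its degree-3 "Y" role in the fully gated holo state (the
published text gives no PB value for this pair); NAD–B1 is held at 15.2 Å so
the substrate does not fake a transfer edge to B1.  The repulsion floor is
17.6 Å — above the largest gated gap — so unconstrained pairs can neither
enter the graph at τ = 14 nor undercut the minimax bottlenecks.

Because the nicotinamide must stack 4.2 Å from the flavin N5 while staying
beyond τ of B1, translation of randomly oriented templates cannot realize
the B1/FMN/NAD block; it is constructed deterministically instead (B1 at the
origin; the flavin approaching with its dimethylbenzene edge so N5 points
away; NAD extending outward from N5, tilted along the ring normal, roll
chosen to maximize clearance) and held fixed while the solver places the
remaining bodies.  Coordination-shell fixtures graft Cys/His side-chain
fragments at canonical donor distances (Sγ–Fe 2.3 Å, Nε–Fe 2.2 Å).  The
optional dimer places a second pentamer (lowercase chains) with all
inter-pentamer cofactor distances > 40 Å.

What the generator does *not* emulate: protein fold and packing (only
minimal ligand fragments exist), chemically exact cofactor geometry
(templates are idealized), crystallographic disorder, or density-derived
coordinate error.  Passing tests on these fixtures therefore demonstrate
that the measurement, graph, gating and recovery machinery is correct on
models whose ground truth is known — not that any particular deposited
model satisfies the encoded distances.  For real models the same code paths
run unchanged on PDB/mmCIF input; the homolog FeS-gap driver accepts
downloaded entries as arguments and measures them with the identical
pipeline it applies to its synthetic stand-ins (which encode the printed
19.4/19.5 Å values and are labelled synthetic wherever they appear).

## File handling conventions

Parsing and writing are delegated to gemmi.  All models and all
ATOM/HETATM records are captured; the default model for analysis is the
first.  Alternative locations are collapsed to the highest-occupancy
conformer (ties prefer altloc 'A').  Elements are inferred from atom names
via a fallback table (FE, NI, SG, SF…) when the element column is blank, as
in legacy dialects.  Writing groups residues by chain, so global atom order
is not a round-trip invariant — order within a residue is, along with
elements, identifiers and coordinates at format precision (3 decimals for
PDB).  Chain identifiers wider than two characters are rejected for PDB
output with a pointer to mmCIF.

## Problem sizes and determinism

The shipped analyses use the pentamer fixture (95–122 atoms, 13–15
cofactors; 190 atoms for the dimer), 100-spec generator sweeps with 3–6
bodies each, and brute-force oracle comparisons on random graphs of ≤ 8
nodes — sizes at which exhaustive enumeration is exact and the full suite
runs in well under a minute.  All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; reports contain no timestamps, so
regeneration from the same inputs and configuration is byte-identical
(modulo the echoed output directory in the provenance block).

## Known limitations

- Detection keys on standard component codes; exotic clusters need a custom
  dictionary entry (CUSTOM type).
- The NiFe assembly takes the single nearest free Fe; models with severely
  disordered bimetallic sites may need a hand-tuned cutoff.
- Minimax tie-breaking is lexicographic on labels, which is deterministic
  but arbitrary where several routes tie exactly.
- The domain-motion axis convention (translation-along-axis ≥ 0) reports the
  rotation line, not a signed screw sense.
- The generator solves translations only; orientation-sensitive constraint
  systems beyond the built-in holo block require constructing orientations
  by hand, as the fixture itself does.
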