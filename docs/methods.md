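# Methods

## The model: topological fragment spaces

A topological fragment space encodes a combinatorial compound library
without storing compounds. Each *topology graph* models one combinatorial
reaction: its nodes hold lists of interchangeable molecular fragments
(synthons) and its edges list the bonds formed between them, as
`(label_a, label_b, order)` connections between labelled attachment points.
A product is one fragment per node, bonded along the edges; the space is the
disjoint union of all products over all graphs, counted per fragment
combination (two combinations that happen to build the same structure count
twice — this matches the arithmetic `size = Σ_graphs Π_nodes |fragments|`).

Fragments carry two kinds of placeholder atoms. A *linker dummy* `[*:L]`
marks a connection point. A *ring dummy* `[1*:L]` (isotope 1) additionally
stands in for an atom that a partner fragment contributes to a ring formed
across the border, so the ring — including aromaticity — is already
perceivable at fragment level. Because each labelled dummy is replaced by
exactly one real atom on assembly, every real atom keeps its element,
charge, aromatic flag and degree-counting-dummies in every product. The one
quantity that can change is hydrogen count: fragments are stored with the
electron localization that minimizes hydrogens, and assembly picks one valid
localization for the product (an azole ring formed across a border gains its
N–H only there).

Dialect limits: one dummy carries one label, so a partner atom that would
form two border bonds at once (a single atom bridging two connections)
cannot be mirrored; interior ring dummies (no real-atom neighbour) carry no
label. Stereochemistry is ignored throughout and stripped on read with a
warning; no coordinates are ever generated.

## Assembly and hydrogen re-localization

Assembly copies all real atoms and real–real bonds of the chosen fragments,
adds one bond per edge connection between the attachment atoms (the unique
real neighbours of the labelled dummies), and deletes all dummies. Bonds
incident to ring dummies need no transfer: they are either border bonds
(re-formed explicitly) or mirrors of real bonds in the partner fragment.
The merged molecule is then sanitized; if kekulization fails, hydrogens are
added one at a time to candidate aromatic nitrogens (charge 0, degree 2, no
hydrogen), tried in atom-index order with backtracking up to depth 3. This
is deterministic, and because atom order is node order × fragment-SMILES
order, products of one group combination re-localize consistently as long as
group-mates write their shared ring systems in the same atom order — true by
construction for the fixture and generator templates, and guarded globally
by the enumeration-oracle tests.

## The decomposition engine

For a property plugin the engine computes, per fragment, the *internal
property component* (IPC: the part of the value computable without partners)
and hashable *boundary information* (everything at the borders the remainder
can depend on). Fragments of a node are grouped by boundary information;
each group holds an exact value→count distribution over its IPCs, with the
first fragment (node order) attaining a value kept as its representative.
For every combination of one group per node, one exemplary product is
assembled from the groups' first members and the shared *external property
component* (EPC) inferred from it. The group distributions are then
convolved — values combined with the plugin's associative, commutative
operation, counts multiplied as arbitrary-precision integers — and the EPC
folded in; graph results merge by adding counts.

Counts are Python integers throughout: target spaces exceed 10^17 products
and floats would silently lose exactness. Convolution is a pairwise left
fold over nodes with dictionary accumulation, which keeps the work
proportional to the number of *distinct* value combinations rather than the
number of fragment tuples. When several combinations collide on a value,
the first one under that fold order wins as the stored example choice; the
order derives entirely from file order, so two runs are byte-identical.
Graphs are independent tasks (optionally parallel via joblib); merging is
associative and order-fixed, so worker count never changes the result. Up
to 10 example fragment-choices are kept per value and assembled into
canonical SMILES only on demand.

An IPC cache keyed by fragment id memoizes IPC/boundary pairs across nodes
and graphs (fragment ids are required to be structure-stable). It is on by
default only for the pattern plugin, where matching dominates runtime; for
cheap properties the lookup saves nothing. For context-dependent plugins
the topology context is part of the key, so the cache is always correct.

## Property plugins

**Heavy atoms** — exactly fragment-additive; dummies count zero, boundary
empty, EPC always 0.

**Molecular weight** (milli-Dalton integers, toolkit standard atomic
weights; output rounded to 2 decimals by default) — additive over atoms
including localized hydrogens. Because the re-localized hydrogen of a
border azole appears in the product's mass, the atoms of aromatic ring
systems containing both nitrogen and dummies are excluded from the IPC and
settled by the EPC, sharing the TPSA plugin's ring-system machinery.

**TPSA** (centi-Å² integers) — per-atom tabulated contributions; the table
is RDKit's implementation of the published atom types, so the decomposed
path and the whole-molecule reference share one table (S/P types off by
default to match the toolkit default; `include_s_and_p` flips both sides).
Contributions depend only on an atom's local state, which assembly
preserves — except hydrogen count in border-crossing aromatic nitrogen
heterocycles. All fused aromatic ring systems containing ≥1 nitrogen and
≥1 dummy are therefore excluded from the IPC; the boundary information
identifies each such system by the canonical SMILES of its extracted
subgraph plus the sorted linker labels touching it, and the EPC (product
value minus ΣIPC, equal to the excluded atoms' contributions on the
exemplary product — both computed and differentially tested) supplies the
missing surface. A deliberately uncorrected variant exists as a regression
baseline; it produces provably wrong histograms on azole-forming spaces.

**Rotatable bonds** — a bond rotates iff it is single, not in a ring, not
terminal (both ends heavy-degree ≥ 2, degree counting dummies — invariant
under assembly) and not a C–N amide bond (carbon with a double-bonded
terminal oxygen, nitrogen non-aromatic and non-terminal). The IPC counts
internal bonds decidable locally; excluded are border bonds, N–C single
bonds whose carbon is double-bonded to a linker (amide-ness depends on the
partner), and bonds on a path between two attachment atoms that the
topology connects externally (they lie on a macrocycle in every product;
membership is decided by a biconnected-component test after adding a
virtual edge between the attachments). The boundary descriptor per
connection records terminality and the amide-relevant cases of the
linker-adjacent atom — non-terminal aliphatic N; acyl carbon; carbon with
single+double bonds to two linkers; terminal double-bonded oxygen; and the
*count* of single-bonded non-terminal aliphatic nitrogens on a carbon
double-bonded to the linker. Terminality and the count (rather than a
boolean) are required for group-EPC constancy: a methyl and an ethyl
attachment, or one versus two amide-sensitive nitrogens, would otherwise
share a group while contributing differently.

**Patterns** — the value of a product is the subset of a query list it
matches (bitmask; union combination; empty identity). Queries are SMARTS
without recursion or disconnected components. A query matching entirely
inside a fragment (no dummy atoms in the embedding) joins that fragment's
IPC. Crossing matches are anticipated by the *subpattern library*: every
proper connected induced subgraph of every query, each open bond capped
with a node matching only dummy atoms (`[#0]`), enumerated with the ESU
algorithm (each subset exactly once, capped at 10^5 per query) and
deduplicated by graph isomorphism on raw atom/bond expression strings —
conservative: equivalent but differently written expressions stay separate,
which costs speed, never correctness. A fragment's boundary information is
the set of (subpattern, saturated-slot→linker-label mapping) pairs over all
embeddings whose core lands on real atoms and caps on dummies. The EPC
enumerates all embeddings of each full query on the exemplary product and
includes a query iff some embedding spans ≥ 2 source fragments (atom
provenance is carried through assembly). The library serializes to JSON
(saturation nodes marked by atom maps) and is reusable across spaces.

Ring-membership primitives (`R`, `r5`, …) are honoured only for rings
complete at fragment level or closed directly across borders via ring
dummies. Membership in a macrocycle closed through a topology cycle is
invisible at fragment level; a guard test asserts this documented mismatch
on the macrocycle fixture.

Post-processing aggregations: counts by subset size (sums to the space
size), per-query counts (not disjoint — a subsuming query pair is ordered
accordingly), and the count of products with at least one match.

**Joint pairs** — two plugins compose into one whose value, boundary and
EPC are component pairs, giving exact joint histograms (e.g. the
oral-bioavailability rule of thumb, TPSA ≤ 140 Å² and ≤ 10 rotatable
bonds) that marginal histograms cannot provide.

## Numerical choices

Decimal-valued properties are exact scaled integers (TPSA ×100, MW ×1000);
per-atom table values are exact at those scales, so sums are exact and the
only float operation — the whole-molecule reference value — is rounded once.
Optional precision rounding is half-up on the scaled integers; rounding to
the intrinsic precision is the identity. The oracle comparison is exact on
counts and allows one least-significant scaled unit on decimal values
(0.01 Å² / 0.01 Da). Degenerate inputs: empty spaces, nodes, and connection
lists are rejected at load with the failing object named; a dummy-only
connector fragment parses (it has zero heavy atoms) but cannot be assembled.

## Validation surface

The enumeration oracle assembles every product of a small space (cap 10^5)
and measures it directly: whole-molecule toolkit TPSA/MolWt, a SMARTS-based
amide-excluding rotatable-bond count, and plain substructure matching for
patterns — never the plugins' IPC/EPC machinery. Named fixtures cover the
mechanisms that must be right: the triazole ring closure (border azole, +1
hydrogen), a triazole+amide three-node reaction, a cyclic three-node
macrocycle topology, an amine×acid coupling with terminal/amide/plain
borders, and a lactam/open-amide space where one product matches a
ring-constrained and a ring-forbidden pattern variant at two sites.

Randomized spaces are built from a curated motif alphabet (amides, esters,
amines, aromatic N-heterocycles, halides, nitriles, Michael acceptors,
sulfones, epoxides) with deterministic seeding — same recipe, same bytes.
The default validation sweep uses 20 recipes spanning ~10^2 to ~3×10^4
products (about 7×10^4 enumerated products in total, chosen so the whole
sweep runs in well under a minute per property set); the scale demonstration
uses a 1000×1000×1000 linear space (10^9 products, never enumerated) and
checks exact count conservation.

What the generator does *not* emulate: realistic reagent inventories and
their functional-group frequencies, protecting groups, charged species,
stereochemistry, very large fragments, and vendor reaction diversity
(everything is built from ~40 templates around one ring-closure chemistry).
Passing the sweep shows the decomposition is exact for the covered
mechanisms — border amides, border azoles, macrocycles, crossing patterns
over 2–3 fragments, subsuming and both-site queries — not that the template
chemistry is representative of any commercial catalogue.

## Known limitations

- Hydrogen re-localization picks the first valid candidate in atom order;
  if two localizations of a border ring system differ in their contribution
  pattern *and* group-mates write the system in different atom orders, the
  shared EPC could disagree with a sibling product. Not observed under the
  oracle sweep; templates keep ring-atom order fixed.
- Pattern ring primitives on topology-cycle macrocycles (documented above).
- One label per dummy: a single partner atom bridging two connections of an
  edge is not representable.
- Subpattern enumeration is exponential in query size (capped, hard error
  beyond); pattern-histogram size is exponential in the number of matched
  queries per product, which is intrinsic to the subset value type —
  aggregations exist for exactly that reason.
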