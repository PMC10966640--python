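# fragprop

Exact molecular-property distributions over **topological fragment spaces**
— combinatorial make-on-demand libraries encoded as reaction topologies —
**without enumerating a single product** (beyond one exemplary molecule per
fragment-group combination).

Modern fragment spaces encode 10^8–10^17 synthesizable molecules as
topology graphs: each node holds interchangeable reactant fragments, each
edge the bonds a reaction forms between them. At that scale you cannot
enumerate-and-measure, yet library selection and design need to know how
TPSA, flexibility or the presence of specific substructures are distributed
over the products. `fragprop` computes those histograms *exactly*, with
arbitrary-precision product counts and up to 10 verifiable example
molecules per histogram bin.

## The algorithm in one paragraph

A property value of a product is decomposed into per-fragment **internal
property components** (IPCs) — the part computable from a fragment alone —
and an **external property component** (EPC) contributed by the fragment
borders. Everything at a border the EPC can depend on is condensed into
hashable **boundary information**; fragments with equal boundary
information are interchangeable without changing any product's EPC. Per
node, fragments are grouped by boundary information and reduced to an exact
IPC value→count distribution; per combination of groups, one exemplary
product fixes the shared EPC; the group distributions are then convolved
(values combine, counts multiply) and summed over combinations and graphs:

> value(product) = ⊕ᵢ IPC(fragmentᵢ) ⊕ EPC(group combination),
> count(v) = Σ over group combinations Π over nodes countᵢ(vᵢ)

Implemented properties: heavy atoms, molecular weight, TPSA (with the
cross-border aromatic-nitrogen-heterocycle correction), rotatable bonds
(Veber definition: single, non-ring, non-terminal, non-amide), occurrence
of arbitrary SMARTS query sets (subset-valued, detecting matches that
*cross* fragment borders via saturated subpattern matching and atom
provenance), and exact joint distributions of any two properties. A
brute-force enumeration oracle validates every mechanism on small spaces.

## Worked example

Export the bundled two-node triazole ring-closure space (each product's
1,2,4-triazole is assembled from two half-ring fragments, and gains the
azole N–H that neither fragment carries) and compute its TPSA histogram:

```bash
$ fragprop fixtures-export fig3_triazole_halves --out fig3.json
$ fragprop dist tpsa --space fig3.json
41.57   8
61.80   4
```

Twelve products: eight pure-alkyl-substituted triazoles at 41.57 Å² (the
three ring nitrogens, one carrying the re-localized hydrogen) and four with
a hydroxymethyl substituent adding an alcohol oxygen (+20.23 Å²). A naive
per-fragment sum would miss the N–H and report every product 2.90 Å² too
low (an aromatic N–H contributes 15.79 Å², a bare aromatic nitrogen only
12.89 Å²); the engine excludes the border ring system from the fragment
IPCs and
restores it through the EPC, which is why the histogram is exact:

```bash
$ fragprop oracle-check tpsa --space fig3.json
{
 "space": "fig3_triazole_halves",
 "property": "tpsa",
 "products": "12",
 "match": true
}
```

SMARTS queries work the same way even when no fragment contains the match:

```bash
$ printf 'c1nncn1\ttriazole\n' > q.txt
$ fragprop dist patterns --space fig3.json --queries q.txt
triazole        12
$ fragprop examples patterns --space fig3.json --queries q.txt
Cc1n[nH]c(C)n1  triazole
```

All 12 products contain the triazole as a *crossing pattern* — atoms from
both fragments — and the example molecule for the bin verifies it. For
large query sets, preprocess once and reuse:
`fragprop preprocess-patterns --queries q.txt --out lib.json`, then
`fragprop dist patterns --library lib.json ...`.

The library surface mirrors the CLI: `read_space` / `space_distribution` /
`realize_examples` with plugin objects (`TpsaPlugin`,
`RotatableBondsPlugin`, `PatternSetPlugin`, `PairPlugin`, ...); a
1000×1000×1000-fragment space (10^9 products) yields its exact TPSA
histogram in a few seconds.

## Layout

- `src/fragprop/space.py` — space dialect, validation, product assembly
- `src/fragprop/engine.py` — grouping, EPC inference, exact convolution,
  merging, caching, example tracking
- `src/fragprop/properties/` — property plugins and the plugin contract
- `src/fragprop/oracle.py` — enumeration oracle and comparison reports
- `src/fragprop/fixtures.py` — named fixture spaces and the seeded
  random-space generator
- `docs/methods.md` — model, decompositions, numerical choices, limitations
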