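# foldict

Minimum-message-length inference of recurrent supersecondary-structure
*concepts* from protein tableaux.

## The problem

Protein folding patterns reuse a limited repertoire of assemblies of
secondary structural elements (SSEs) — β-hairpins, β-α-β units, Greek keys,
barrels.  `foldict` discovers such recurrent substructures *without any
prior catalogue*, by asking a purely information-theoretic question: which
dictionary of substructures lets us transmit a whole collection of protein
folding patterns in the fewest bits?

A folding pattern is represented as a **tableau**: the string of helices
(`H`) and strands (`E`) along the chain, a symmetric SSE-contact matrix
(two SSEs are in contact if any heavy-atom pair, one atom per residue and
one residue per SSE, lies closer than the sum of van der Waals radii plus
1 Å), and the symmetric matrix of interaxial dihedral angles between the
least-squares axes fitted through each SSE's Cα trace.

A **concept** is a subtableau of ≥ 2 *consecutive* SSEs whose contact graph
is connected, equipped with a von Mises concentration κ that governs how
tightly the angles of its usages cluster around the archetype's angles
(small κ = flexible concept, large κ = rigid).

## The inference criterion

Given a source collection of tableaux *T*, a candidate dictionary *C* is
scored by the length of a two-part lossless encoding

&nbsp;&nbsp;&nbsp;&nbsp;I(C & T) = I(C) + I(T | C),

where I(·) = −log₂ Pr(·) is Shannon information in bits.  The first part
states every archetype and its κ; the second part encodes each tableau via
its optimal **dissection** — a partition of the SSEs into consecutive
regions, each assigned to a dictionary concept (SSE string implied,
contact cells coded as rare Bernoulli mismatches, angles coded as von
Mises deviations from the archetype) or to the null concept `c_0000`
(one SSE, coded under adaptive null codes).  The optimal dissection is
found exactly by dynamic programming; the best dictionary is searched by
simulated annealing over five perturbation primitives (add / remove a
concept, grow or shrink one by one SSE against its source, move κ one grid
step, swap a concept with one of its current usages).  A dictionary is
accepted only if it beats the null encoding I_null(T) — the built-in
hypothesis test — and its quality is the compression gain
I_null(T) − I(C & T) > 0.

The codec is real, not notional: `encode_tableau`/`decode_tableau`
arithmetic-code every tableau into an actual bit string and reconstruct it
exactly (angles to the quantization step ε, default 1°).

## Worked example

```python
from foldict import ConceptDictionaryModel
from foldict.synthetic import SynthParams, make_benchmark, recovery_score

params = SynthParams(seed=1)                  # reference benchmark conditions
collection, truth = make_benchmark(params)
model = ConceptDictionaryModel(collection)
res = model.fit(seed=1)
print(res.summary())
```

prints

```
Concept dictionary inference (minimum message length)
=========================================================
Tableaux in collection:             60
Null encoding (bits):              7466.13
Two-part encoding (bits):          7118.02
Compression gain (bits):            348.11
Compression gain (%):                 4.66
Concepts inferred:                   1
Dictionary statement (bits):         60.60
SSE coverage by concepts:           25.97%
---------------------------------------------------------
id       nSSE SSE string       kappa  usages
c_0001      4 EHHE              46.4      30
```

The benchmark plants a 4-SSE `EHHE` motif (κ_true = 50) in 30 of 60 random
tableaux.  The search, started from an empty dictionary, recovers exactly
that motif: one concept with the planted SSE string and contact pattern,
κ inferred next to the true concentration, used in precisely the 30
planted tableaux (`recovery_score(...)` reports recovery = True, mean
absolute archetype-angle deviation 2.25°, usage/planted-span overlap
1.00).  Transmitting dictionary plus dissections saves 348 bits (4.66%)
over the null encoding; on pure-noise collections the search returns the
empty dictionary, i.e. the null hypothesis survives.

## Command-line tools

```
foldict tableau  structure.pdb -o chain.tab          # coordinates -> tableau
foldict simulate --seed 1 -o coll.tab --truth-out gt.json
foldict infer    coll.tab --seed 1 -o dict.json      # annealing inference
foldict dissect  dict.json coll.tab -o reports/      # markup + JSON + FASTA
foldict cluster  dict.json --seed 1 --newick-out tree.nwk \
                 --similarity-out sim.tsv            # meta-concept UPGMA tree
```

All commands are bitwise reproducible under a fixed `--seed`.

## Layout

| module                  | contents                                              |
|-------------------------|-------------------------------------------------------|
| `foldict.tableau`       | Tableau container, text format                        |
| `foldict.structure_io`  | PDB/mmCIF → SSEs → axes → angles/contacts → tableau   |
| `foldict.codec`         | code lengths, null model, arithmetic encoder/decoder  |
| `foldict.dictionary`    | Concept/Dictionary model, candidate gate, JSON format |
| `foldict.dissection`    | exact DP dissection, brute-force oracle, reports      |
| `foldict.search`        | simulated annealing, proposal primitives              |
| `foldict.model`         | `ConceptDictionaryModel` / `DictionaryResults`        |
| `foldict.metacluster`   | meta-concepts, feature vectors, cosine + UPGMA        |
| `foldict.synthetic`     | benchmark generator with planted motifs               |
| `foldict.cli`           | `foldict` command group                               |

See `docs/methods.md` for the model, codec conventions, parameter
defaults, and known limitations.
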