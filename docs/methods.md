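# Methods

This note documents the model behind `foldict`, the codec conventions that
make its message lengths well defined, the default parameters, what the
synthetic benchmark does and does not emulate, and the package's known
limitations.

## 1. Tableau construction

An SSE is a helix (`H`) or strand (`E`) segment of one polypeptide chain.
Segments may be supplied externally (whitespace table `chain type start
end`) or assigned from Cα geometry alone: residues inside d(i,i+3) ∈
[4.7, 5.7] Å windows become helix, residues inside d(i,i+2) ∈ [6.0, 7.2] Å
windows become strand, helix wins conflicts, runs are split at
residue-numbering gaps, and segments shorter than 4 (H) or 3 (E) residues
are discarded.  The Cα-only assigner is deliberately simple — it keeps the
package free of an external secondary-structure program — and is expected
to fragment kinked helices and miss irregular strands; for production use,
feed assignments from a dedicated assigner through the external-file
adapter.

Each segment's axis is the total-least-squares line through its Cα
coordinates (first principal direction of the centered trace), with the
sign chosen so the direction points from N- to C-terminus.  The
orientation angle of a pair of SSEs is the signed dihedral between the two
planes that each axis spans with their mutual perpendicular — equivalently
the IUPAC torsion of the four points (f₁ − d₁, f₁, f₂, f₂ + d₂), where f₁,
f₂ are the feet of the common perpendicular.  Conventions for degenerate
geometry: parallel axes give 0° (same direction) or 180° (antiparallel);
intersecting axes use the direction of d₁ × d₂ as the limit of the mutual
perpendicular and emit a warning.  Angles live on (−180°, 180°] and the
whole construction is invariant under proper rigid motions.

Two SSEs are in contact when some heavy-atom pair (one atom per residue,
one residue per segment) is closer than r_vdw(a) + r_vdw(b) + 1 Å, with
Bondi radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å, hydrogens excluded,
and unknown elements falling back to 1.70 Å with a warning.  Waters and
HETATM groups are excluded; the first-listed altloc is kept.

## 2. The coded object and the null model

The transmitted content of a tableau is (n, SSE string, contact matrix,
angles of *contacting* pairs).  Angles of non-contacting pairs are derived
data — recomputable from coordinates — and are not part of any message.

Null (dictionary-free) code:

* n + 1 by an Elias-gamma code, 2⌊log₂(n+1)⌋ + 1 bits;
* SSE symbols by an adaptive binary Krichevsky–Trofimov (KT) code,
  −log₂((c + ½)/(t + 1)) for the t-th symbol with prior own-count c;
* the n(n−1)/2 upper-triangle contact cells, row-major, by the same KT
  code;
* one uniform angle code, log₂(360/ε), per contacting pair.

Quantization ε defaults to 1°, which is below the noise of tableau
comparison; ε must divide 360 so the bins tile the circle.

## 3. Concepts, dissections, and the concept code

A concept's archetype is a subtableau of ≥ 2 consecutive SSEs with a
connected contact graph, cut verbatim from a source tableau
(non-contacting archetype angles are zeroed — they are never coded — which
gives concepts a canonical serialized form).  Each concept carries a von
Mises concentration κ restricted to a public grid: 0 plus 64
geometrically spaced values in [0.1, 1000].  Coding κ therefore costs
log₂ 65 bits, and the grid is part of the CodeSpec, so every message
remains decodable.  This grid code replaces an optimal-precision
continuous-parameter treatment; it is simpler, exactly decodable, and the
grid is dense enough that the κ discretization loss is well under a bit
per concept in practice.

A dissection tiles SSEs 1..n into consecutive regions.  Each region label
is uniform over the |C| + 1 options (log₂(|C|+1) bits); a null label
covers exactly one SSE, a concept label covers its archetype's length.  A
concept may explain a region only if (gate) the SSE strings agree exactly
and every archetype contact is present in the tableau.  Inside a concept
region: contact cells are coded as Bernoulli(p_flip = 0.05) mismatches
against the archetype (so extra contacts are tolerated but penalized, a
missing archetype contact is forbidden by the gate); angles of pairs that
contact in the archetype are coded as von Mises(0, κ) deviations,
max(0, −log₂(f(δ)·ε_rad)); angles of extra contacts fall back to the
uniform code.  The von Mises cost is floored at zero because for very
large κ the density times the bin width can exceed one.

**Cross-region convention.**  Every pair of SSEs not interior to a single
concept region, and every SSE symbol outside concept regions, is coded
under the *fixed* null code of the whole tableau: KT costs condition on
the actual values of all preceding symbols in the canonical order,
whatever model coded them.  The decoder always knows those values, so the
stream stays decodable, and each per-cell null cost is a constant of the
tableau, independent of the segmentation.  This is the property that makes
the total message length additive over regions and lets dynamic
programming find the globally optimal dissection exactly; the test suite
verifies exact bit agreement with exhaustive enumeration.  Ties are broken
deterministically: fewer regions, then earlier concept id, then leftmost
split.

Two-part total for a collection: dictionary statement
(Elias-gamma |C| + 1, plus each archetype under the null code plus its κ
index) plus the optimal dissection length of every tableau.  The
compression gain is I_null(T) − I(C & T); a dictionary is returned only if
the gain is positive, otherwise the empty dictionary stands (null
hypothesis retained).

## 4. The arithmetic codec

`encode_tableau` walks the dissection and feeds every symbol, with the
exact probabilities above (rational frequencies for KT, Bernoulli and
uniform codes; integer-scaled von Mises bin masses), through a 32-bit
integer arithmetic coder; `decode_tableau` mirrors it.  Termination costs
at most 2 bits, so an all-null encoding lands within 2 bits of the
analytic null length; decoded angles are bin centers, within ε/2 of the
originals.  The von Mises bin masses are integer-rounded, so encoded
lengths may deviate from the analytic von Mises costs by a rounding term;
the analytic costs are authoritative for the optimization, the coder
demonstrates decodability.

## 5. Simulated annealing search

State: a list of concepts (initially empty).  Proposals pick uniformly
among the applicable primitives — Add (random connected subtableau from
the collection, κ initialized to the grid median), Remove, Perturb-length
(grow/shrink one SSE against the concept's source span, floor n ≥ 2),
Perturb-κ (one grid step), Swap-with-usage (replace the archetype by a
region currently encoded by the concept) — redrawing invalid proposals up
to 50 times before forcing an Add.  Candidates are scored by the full
two-part total (every tableau re-dissected; match costs and per-tableau
DP results are memoized on concept content, so unchanged subproblems are
cache hits, and the running total is verified against a from-scratch
recomputation at every temperature change).  Acceptance follows the
Metropolis rule in base 2 — accept improvements, else accept with
probability 2^(−Δ/T) — because message lengths are in bits, so the
temperature is also in bits.

Schedule defaults: T₀ = 1000 bits, geometric cooling α = 0.95, 200
proposals per temperature, T_min = 0.1 bits, stop early after 20
temperatures without a single acceptance.  These values were chosen so
that initial temperatures accept essentially everything (T₀ is large
against the ~tens-of-bits scale of single-concept changes at desk-scale
collections) and the final temperatures are far below one bit; the
best-seen dictionary (not the final state) is returned, after the null
test above, with ids renumbered c_0001… by decreasing archetype size then
lexicographic SSE string (provenance order breaks ties).

## 6. Meta-concepts and the concept hierarchy

The flat dictionary is given structure by re-running the same inference
with the concept archetypes as the source collection, yielding
meta-concepts.  Each concept becomes a bag-of-meta-concepts count vector
(usages of each meta-concept in the optimal dissection of its archetype,
on raw counts), concepts are compared by cosine similarity — with the
conventions that two zero vectors are maximally similar (1) and a zero
against a nonzero vector is dissimilar (0) — and the similarity matrix is
clustered by UPGMA on distance 1 − s, merging the lowest-index closest
pair at height d/2.  The resulting ultrametric tree is exported as Newick
with branch lengths equal to height differences.

## 7. Synthetic benchmark

`foldict.synthetic` generates collections whose statistics mimic what the
coding model assumes about real tableaux: SSE counts uniform on a range,
i.i.d. H/E types, contacts dense for adjacent pairs and sparse for distant
ones (defaults 0.9 / 0.15 — real folding patterns concentrate information
near the tableau diagonal), angles uniform on the circle, quantized to ε
bin centers.  A planted motif overwrites a random consecutive span with an
archetype (reference motif: 4 SSEs, `EHHE`, contacts {1–2, 2–3, 3–4,
1–4}); usage angles are archetype plus von Mises(0, κ_true) noise.
Reference conditions: 60 tableaux of 5–10 SSEs, plant fraction 0.5,
κ_true = 50 (angular s.d. ≈ 8°).

What the generator does *not* emulate: geometric realizability (no 3-D
coordinates exist behind a random tableau), amino-acid sequences,
correlations between SSE type and contact pattern, β-sheet topology, and
the long-tailed size distribution of real domains.  Recovery of the
planted motif therefore demonstrates that the inference machinery finds
exactly the structure its own model class describes — it does not by
itself certify performance on real structural data, where SSE assignment
noise and motif variability enter.

## 8. Numerical choices and degenerate inputs

* Angle wrap is (−180°, 180°], with −180° mapped to +180°.
* Empty tableaux are valid (1-bit message); tableaux with one SSE dissect
  to a single null region.
* DP/brute-force tie tolerance is 10⁻¹² relative to candidate totals;
  totals are compared to 10⁻⁹ in tests.
* von Mises densities use the exponentially scaled Bessel function
  I₀e, stable up to the κ grid maximum of 1000.
* Axis fitting requires ≥ 3 non-coincident Cα points; an all-coincident
  segment is a hard error.
* Archetype angles are serialized at 2 decimals (≥ ε/2 fidelity at the
  default ε = 1°).

## 9. Problem sizes

The test suite and the acceptance script run at desk scale by design:
collections of 50–60 tableaux of 4–10 SSEs, dictionaries of a handful of
concepts, 10–20 seeded annealing replicates.  These sizes make the
stochastic-search properties (null-hypothesis retention on noise,
planted-motif recovery) reproducible in minutes on one CPU while
exercising every code path; the library itself has no hard size limits
other than `brute_force_dissect`'s n ≤ 12 guard.

## 10. Known limitations

* The built-in Cα-geometry SSE assigner is an approximation; external
  assignments are preferred for fidelity.
* Concepts are strictly consecutive in sequence; motifs formed by
  sequence-distant SSEs are representable only through their contact
  pattern inside a longer consecutive span (allowing non-consecutive
  concept spans would make optimal dissection intractable).
* The dictionary is flat; hierarchical (nested) dictionaries are out of
  scope, and the meta-concept tree is an exploratory device, not a model
  of structural evolution.
* Multi-chain (quaternary) tableaux and β-sheet topology labels are not
  supported.
* The annealer re-dissects the collection per proposal; very large
  collections would need sharded dissection (which must not change
  results) or a smarter incremental objective.
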