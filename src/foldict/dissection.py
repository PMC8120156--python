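"""Optimal dissection of a tableau against a concept dictionary.

A dissection partitions the SSEs ``1..n`` into consecutive regions, each
assigned to a dictionary concept (region length = archetype size) or to
the null concept ``c_0000`` (length 1).  Region labels cost
``log2(|C| + 1)`` each.  Pairs interior to a concept region are coded by
that concept's mismatch/von-Mises model; every other pair — and every SSE
symbol outside concept regions — is coded under the tableau's fixed null
code, whose per-cell costs do not depend on the segmentation.  The total
message length is therefore additive over regions and the optimum is found
exactly by dynamic programming over prefixes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .codec import (CodeSpec, MessageLength, NullCosts, universal_int_len,
                    uniform_angle_len, von_mises_angle_len)
from .dictionary import Dictionary, NULL_CONCEPT_ID
from .tableau import Tableau, wrap_angle

__all__ = ["RegionAssignment", "Dissection", "match_cost", "dissect",
           "brute_force_dissect", "total_collection_len",
           "write_dissection_report", "INVALID"]

INVALID = None          # sentinel: concept cannot explain the span
_TIE_TOL = 1e-9


@dataclass
class RegionAssignment:
    """One region of a dissection: 1-based inclusive SSE span and label."""

    span: tuple
    concept_id: str
    region_bits: MessageLength

    @property
    def is_null(self) -> bool:
        return self.concept_id == NULL_CONCEPT_ID


@dataclass
class Dissection:
    """A full tiling of a tableau's SSEs by concept/null regions."""

    tableau_id: str
    regions: list
    total_bits: MessageLength

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def concept_regions(self):
        return [r for r in self.regions if not r.is_null]

    def to_json_dict(self) -> dict:
        return {
            "tableau_id": self.tableau_id,
            "total_bits": round(self.total_bits.bits, 6),
            "breakdown": {k: round(v, 6)
                          for k, v in self.total_bits.breakdown.items()},
            "regions": [{"span": list(r.span), "concept_id": r.concept_id,
                         "bits": round(r.region_bits.bits, 6)}
                        for r in self.regions],
        }


# ---------------------------------------------------------------------------
# Concept match cost
# ---------------------------------------------------------------------------

def match_cost(t: Tableau, span: tuple, concept, spec: CodeSpec):
    """Bits to code the interior of ``span`` using ``concept``, or INVALID.

    ``span`` is 1-based inclusive and must have the archetype's length.
    The match gate requires the SSE strings to agree exactly and every
    archetype contact to be present in the tableau over the span.  The cost
    sums the Bernoulli mismatch code over interior contact cells and, for
    each interior contacting pair, a von Mises(kappa) deviation code when
    the pair contacts in the archetype or a uniform angle code otherwise.
    """
    a, b = span
    arch = concept.archetype
    nc = arch.n
    if b - a + 1 != nc:
        raise ValueError(f"span {span} length != archetype n={nc}")
    a0 = a - 1
    if t.sse_string[a0:a0 + nc] != arch.sse_string:
        return INVALID
    sub_c = t.contacts[a0:a0 + nc, a0:a0 + nc]
    if np.any(arch.contacts & ~sub_c):
        return INVALID
    p = spec.flip_prob
    bits_match, bits_flip = -math.log2(1.0 - p), -math.log2(p)
    u = uniform_angle_len(spec)
    cost = 0.0
    for i in range(nc):
        for j in range(i + 1, nc):
            mism = bool(sub_c[i, j]) ^ bool(arch.contacts[i, j])
            cost += bits_flip if mism else bits_match
            if sub_c[i, j]:
                if arch.contacts[i, j]:
                    delta = wrap_angle(t.angles[a0 + i, a0 + j]
                                       - arch.angles[i, j])
                    cost += von_mises_angle_len(delta, concept.kappa, spec)
                else:
                    cost += u
    return cost


# ---------------------------------------------------------------------------
# Dynamic programming
# ---------------------------------------------------------------------------

def _candidate_better(cand, best):
    """Tie-break: fewer bits, then fewer regions, then earlier concept id,
    then leftmost split (encoded in the comparison key)."""
    if cand[0] < best[0] - _TIE_TOL:
        return True
    if cand[0] > best[0] + _TIE_TOL:
        return False
    return cand[1:] < best[1:]


def dissect(t: Tableau, C: Dictionary, spec: CodeSpec | None = None,
            null_costs: NullCosts | None = None) -> Dissection:
    """Globally optimal dissection of ``t`` against ``C`` (exact DP)."""
    spec = spec or C.spec
    n = t.n
    nc_costs = null_costs or NullCosts(t, spec)
    label = math.log2(len(C.concepts) + 1)
    # best[j]: (bits, n_regions, tie_key) for prefix of length j
    best = [None] * (n + 1)
    back = [None] * (n + 1)          # (prev_j, concept or None, region_bits)
    best[0] = (0.0, 0, ())
    concepts = list(C.concepts)
    for j in range(1, n + 1):
        null_bits = nc_costs.s_null[j - 1]
        cand = (best[j - 1][0] + label + null_bits, best[j - 1][1] + 1,
                best[j - 1][2] + (("~null", j),))
        choice = (j - 1, None, null_bits)
        for ci, c in enumerate(concepts):
            ncn = c.archetype.n
            if ncn > j:
                continue
            a = j - ncn + 1                      # 1-based start
            mc = match_cost(t, (a, j), c, spec)
            if mc is INVALID:
                continue
            bits = mc + nc_costs.back(a - 1, j - 1)
            alt = (best[j - ncn][0] + label + bits, best[j - ncn][1] + 1,
                   best[j - ncn][2] + ((c.id, j),))
            if _candidate_better(alt, cand):
                cand, choice = alt, (j - ncn, c, bits)
        best[j] = cand
        back[j] = choice
    # traceback
    regions = []
    j = n
    while j > 0:
        prev, c, bits = back[j]
        if c is None:
            regions.append(RegionAssignment(
                span=(j, j), concept_id=NULL_CONCEPT_ID,
                region_bits=MessageLength({"structure": nc_costs.sse_costs[j - 1],
                                           "contacts": bits - nc_costs.sse_costs[j - 1]})))
        else:
            regions.append(RegionAssignment(
                span=(prev + 1, j), concept_id=c.id,
                region_bits=MessageLength({"regions": bits})))
        j = prev
    regions.reverse()
    total = MessageLength({
        "structure": universal_int_len(n + 1),
        "labels": label * len(regions),
        "regions": sum(r.region_bits.bits for r in regions),
    })
    return Dissection(tableau_id=t.id, regions=regions, total_bits=total)


def dissect_total_bits(t: Tableau, C: Dictionary,
                       spec: CodeSpec | None = None,
                       null_costs: NullCosts | None = None) -> float:
    """Total bits of the optimal dissection (no traceback; used in search)."""
    return dissect(t, C, spec, null_costs).total_bits.bits


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_dissect(t: Tableau, C: Dictionary,
                        spec: CodeSpec | None = None) -> Dissection:
    """Exhaustive enumeration of all tilings/assignments (test oracle).

    Refuses tableaux with n > 12.  Applies the same additive objective and
    tie-break as :func:`dissect`.
    """
    spec = spec or C.spec
    n = t.n
    if n > 12:
        raise ValueError(f"brute force limited to n <= 12, got n={n}")
    nc_costs = NullCosts(t, spec)
    label = math.log2(len(C.concepts) + 1)
    best = {"key": None, "regions": None}

    def recurse(j, bits, nreg, tie, regions):
        if j == n:
            key = (bits, nreg, tie)
            if best["key"] is None or _candidate_better(key, best["key"]):
                best["key"] = key
                best["regions"] = list(regions)
            return
        # null step
        nb = nc_costs.s_null[j]
        regions.append((j + 1, j + 1, None, nb))
        recurse(j + 1, bits + label + nb, nreg + 1, tie + (("~null", j + 1),),
                regions)
        regions.pop()
        # concept steps
        for c in C.concepts:
            ncn = c.archetype.n
            if j + ncn > n:
                continue
            mc = match_cost(t, (j + 1, j + ncn), c, spec)
            if mc is INVALID:
                continue
            rb = mc + nc_costs.back(j, j + ncn - 1)
            regions.append((j + 1, j + ncn, c, rb))
            recurse(j + ncn, bits + label + rb, nreg + 1,
                    tie + ((c.id, j + ncn),), regions)
            regions.pop()

    recurse(0, 0.0, 0, (), [])
    regions = []
    for a, b, c, rb in best["regions"]:
        if c is None:
            regions.append(RegionAssignment(
                span=(a, b), concept_id=NULL_CONCEPT_ID,
                region_bits=MessageLength({"structure": nc_costs.sse_costs[a - 1],
                                           "contacts": rb - nc_costs.sse_costs[a - 1]})))
        else:
            regions.append(RegionAssignment(span=(a, b), concept_id=c.id,
                                            region_bits=MessageLength({"regions": rb})))
    total = MessageLength({
        "structure": universal_int_len(n + 1),
        "labels": label * len(regions),
        "regions": sum(r.region_bits.bits for r in regions),
    })
    return Dissection(tableau_id=t.id, regions=regions, total_bits=total)


# ---------------------------------------------------------------------------
# Collection-level totals
# ---------------------------------------------------------------------------

def total_collection_len(collection, C: Dictionary,
                         spec: CodeSpec | None = None) -> MessageLength:
    """Two-part total: dictionary statement + optimal per-tableau encodings."""
    from .codec import dictionary_len
    spec = spec or C.spec
    total = dictionary_len(C, spec)
    for t in collection:
        total = total + dissect(t, C, spec).total_bits
    return total


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_dissection_report(d: Dissection, sequence: str | None = None,
                            sse_residue_spans: list | None = None):
    """Render a dissection as (markup text, JSON dict, FASTA string).

    ``sequence`` is the amino-acid string of the chain; ``sse_residue_spans``
    gives each SSE's 1-based inclusive residue span.  Residues outside every
    SSE are loop and always labeled with the null concept.  Without sequence
    information only the JSON part carries content beyond region listing.
    """
    js = d.to_json_dict()
    if sequence is None or sse_residue_spans is None:
        markup = "\n".join(
            f"{r.span[0]}-{r.span[1]}\t{r.concept_id}" for r in d.regions)
        return markup + ("\n" if markup else ""), js, ""
    if len(sse_residue_spans) != sum(r.span[1] - r.span[0] + 1
                                     for r in d.regions):
        raise ValueError("sse_residue_spans length does not match dissection")
    for s, e in sse_residue_spans:
        if not (1 <= s <= e <= len(sequence)):
            raise ValueError(f"SSE residue span ({s}, {e}) outside sequence "
                             f"of length {len(sequence)}")
    # per-residue concept labels
    labels = [NULL_CONCEPT_ID] * len(sequence)
    fasta_records = []
    for r in d.regions:
        first = sse_residue_spans[r.span[0] - 1]
        last = sse_residue_spans[r.span[1] - 1]
        rs, re_ = first[0], last[1]
        for k in range(rs - 1, re_):
            labels[k] = r.concept_id
        subseq = sequence[rs - 1:re_]
        fasta_records.append(f">{d.tableau_id}|{r.concept_id}|{rs}-{re_}\n"
                             f"{subseq}")
    lines = [f"# dissection of {d.tableau_id}  "
             f"({d.total_bits.bits:.2f} bits, {d.n_regions} regions)"]
    width = 60
    for off in range(0, len(sequence), width):
        chunk = sequence[off:off + width]
        lines.append(f"{off + 1:>6} {chunk}")
        tags = []
        pos = off
        while pos < min(off + width, len(sequence)):
            cid = labels[pos]
            run = pos
            while run < min(off + width, len(sequence)) and labels[run] == cid:
                run += 1
            tags.append(f"{cid}[{pos + 1}-{run}]")
            pos = run
        lines.append("       " + " ".join(tags))
    markup = "\n".join(lines) + "\n"
    js["residue_labels"] = labels
    fasta = "\n".join(fasta_records) + ("\n" if fasta_records else "")
    return markup, js, fasta


def load_dissection_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
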