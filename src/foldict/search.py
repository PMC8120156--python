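"""Simulated-annealing inference of the optimal concept dictionary.

Starting from an empty dictionary, the search explores dictionary space
with five perturbation primitives — add a candidate subtableau, remove a
concept, grow/shrink a concept by one SSE against its source, move its
von Mises concentration one grid step, and swap a concept with one of its
current usages — accepting each proposal by the Metropolis rule on the
two-part message length (base-2, temperatures in bits) under a geometric
cooling schedule.  The best-seen dictionary is returned only if it beats
the null encoding of the collection (the minimum-message-length
null-hypothesis test); otherwise the empty dictionary is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codec import (CodeSpec, NullCosts, null_tableau_len, universal_int_len,
                    uniform_angle_len, von_mises_angle_len)
from .dictionary import (Concept, Dictionary, DisconnectedError,
                         extract_candidate, finalize_ids)

__all__ = ["AnnealParams", "anneal", "propose", "compression_gain",
           "CollectionState"]


@dataclass
class AnnealParams:
    """Annealing schedule and seed.

    t0
        Initial temperature in bits (scale of message-length differences
        accepted freely at the start).
    alpha
        Geometric cooling factor per temperature step, 0 < alpha < 1.
    iters_per_temp
        Proposals evaluated at each temperature.
    t_min
        Final temperature in bits.
    stall_limit
        Stop after this many consecutive temperatures without a single
        accepted proposal.
    seed
        Seed for the search's random number generator.
    """

    t0: float = 1000.0
    alpha: float = 0.95
    iters_per_temp: int = 200
    t_min: float = 0.1
    stall_limit: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (self.t0 > self.t_min > 0.0):
            raise ValueError("need t0 > t_min > 0")


# ---------------------------------------------------------------------------
# Cached dissection engine
# ---------------------------------------------------------------------------

class CollectionState:
    """Per-collection caches for fast repeated dissection during search.

    Match costs are memoized per concept *content* (independent of concept
    ids), and per-tableau DP results are memoized on the subset of concepts
    that can validly place in that tableau together with the dictionary
    size (which fixes the label cost).  Tableaux in which no concept places
    are dissected all-null in closed form.  Concept contents are interned
    to small integer ids so memo keys hash cheaply.
    """

    def __init__(self, collection, spec: CodeSpec):
        self.tabs = list(collection)
        self.spec = spec
        self.by_id = {t.id: t for t in self.tabs}
        self.null_costs = [NullCosts(t, spec) for t in self.tabs]
        self.null_totals = [float(universal_int_len(t.n + 1) + nc.core)
                            for t, nc in zip(self.tabs, self.null_costs)]
        self.null_sum = float(sum(self.null_totals))
        # plain-Python per-tableau structures for the hot loops
        self._sse = [t.sse_string for t in self.tabs]
        self._con = [[[bool(t.contacts[i, j]) for j in range(t.n)]
                      for i in range(t.n)] for t in self.tabs]
        self._ang = [[[float(t.angles[i, j]) for j in range(t.n)]
                      for i in range(t.n)] for t in self.tabs]
        self._s_null = [[float(x) for x in nc.s_null] for nc in self.null_costs]
        # back_tab[ti][a][b] = null bits of pairs (i<a, a<=j<=b)
        self._back_tab = [[[float(nc.back(a, b)) for b in range(nc.n)]
                           for a in range(nc.n)] for nc in self.null_costs]
        self._key_ids: dict = {}        # cache_key -> interned int id
        self._placements: dict = {}     # key id -> [ {start0: cost} ]
        self._sizes: dict = {}          # key id -> archetype n
        self._arch_bits: dict = {}      # key id -> archetype statement bits
        self._dp_memo: list = [dict() for _ in self.tabs]
        self._vm_cost: dict = {}        # (kappa, delta rounded) -> bits
        self._kappa_bits = math.log2(len(spec.kappa_grid))
        p = spec.flip_prob
        self._bits_match = -math.log2(1.0 - p)
        self._bits_flip = -math.log2(p)
        self._u = uniform_angle_len(spec)

    # -- concept-level caches ---------------------------------------------
    def _vm(self, delta: float, kappa: float) -> float:
        key = (kappa, round(delta, 9))
        got = self._vm_cost.get(key)
        if got is None:
            got = von_mises_angle_len(delta, kappa, self.spec)
            self._vm_cost[key] = got
        return got

    def _match_cost_fast(self, ti: int, a0: int, arch_sse, arch_con,
                         arch_ang, kappa: float) -> float | None:
        nc = len(arch_sse)
        if self._sse[ti][a0:a0 + nc] != arch_sse:
            return None
        con, ang = self._con[ti], self._ang[ti]
        cost = 0.0
        for i in range(nc):
            ci, ai = con[a0 + i], ang[a0 + i]
            aci, aai = arch_con[i], arch_ang[i]
            for j in range(i + 1, nc):
                tc = ci[a0 + j]
                if aci[j]:
                    if not tc:
                        return None
                    cost += self._bits_match
                    d = ai[a0 + j] - aai[j]
                    if d <= -180.0:
                        d += 360.0
                    elif d > 180.0:
                        d -= 360.0
                    cost += self._vm(d, kappa)
                elif tc:
                    cost += self._bits_flip + self._u
                else:
                    cost += self._bits_match
        return cost

    def intern(self, concept) -> int:
        """Intern a concept's content; computes placements on first sight."""
        ck = concept.cache_key()
        kid = self._key_ids.get(ck)
        if kid is None:
            kid = len(self._key_ids)
            self._key_ids[ck] = kid
            arch = concept.archetype
            nc = arch.n
            arch_sse = arch.sse_string
            arch_con = [[bool(arch.contacts[i, j]) for j in range(nc)]
                        for i in range(nc)]
            arch_ang = [[float(arch.angles[i, j]) for j in range(nc)]
                        for i in range(nc)]
            got = []
            for ti, t in enumerate(self.tabs):
                valid = {}
                for a0 in range(0, t.n - nc + 1):
                    c = self._match_cost_fast(ti, a0, arch_sse, arch_con,
                                              arch_ang, concept.kappa)
                    if c is not None:
                        valid[a0] = c
                got.append(valid)
            self._placements[kid] = got
            self._sizes[kid] = nc
            self._arch_bits[kid] = (null_tableau_len(arch, self.spec).bits
                                    + self._kappa_bits)
        return kid

    def placements(self, concept):
        kid = self.intern(concept)
        return kid, self._placements[kid]

    def archetype_bits(self, concept) -> float:
        return self._arch_bits[self.intern(concept)]

    # -- per-tableau DP ----------------------------------------------------
    def _dp(self, ti: int, active, label: float):
        """Optimal (bits, regions) for tableau ``ti`` over the concepts in
        ``active`` = [(key id, size, {start0: cost}), ...]."""
        s_null = self._s_null[ti]
        back_tab = self._back_tab[ti]
        n = len(s_null)
        best = [0.0] * (n + 1)
        back = [None] * (n + 1)
        for j in range(1, n + 1):
            b = best[j - 1] + label + s_null[j - 1]
            ch = (j - 1, None)
            for kid, size, starts in active:
                if size > j:
                    continue
                mc = starts.get(j - size)
                if mc is None:
                    continue
                alt = best[j - size] + label + mc + back_tab[j - size][j - 1]
                if alt < b - 1e-12:
                    b, ch = alt, (j - size, kid)
            best[j] = b
            back[j] = ch
        regions = []
        j = n
        while j > 0:
            prev, kid = back[j]
            regions.append((prev, kid))
            j = prev
        regions.reverse()
        total = universal_int_len(n + 1) + best[n]
        return total, tuple(regions)

    def tableau_total(self, ti: int, kids, n_dict: int):
        """(bits, regions) for tableau ``ti`` against a dictionary of size
        ``n_dict`` whose concepts are interned as ``kids``."""
        active = []
        akeys = []
        for kid in kids:
            pl = self._placements[kid][ti]
            if pl:
                active.append((kid, self._sizes[kid], pl))
                akeys.append(kid)
        memo_key = (n_dict, tuple(sorted(akeys)))
        memo = self._dp_memo[ti]
        got = memo.get(memo_key)
        if got is None:
            label = math.log2(n_dict + 1)
            if not active:
                n = len(self._s_null[ti])
                got = (self.null_totals[ti] + n * label,
                       tuple((j, None) for j in range(n)))
            else:
                got = self._dp(ti, active, label)
            memo[memo_key] = got
        return got

    def collection_total(self, concepts) -> float:
        """Two-part total for the whole collection (dictionary + data)."""
        kids = [self.intern(c) for c in concepts]
        total = universal_int_len(len(concepts) + 1)
        for kid in kids:
            total += self._arch_bits[kid]
        n_dict = len(concepts)
        for ti in range(len(self.tabs)):
            total += self.tableau_total(ti, kids, n_dict)[0]
        return float(total)

    def usages(self, concepts, concept_index: int):
        """Current usages of one concept: list of (tableau_index, start0)."""
        kids = [self.intern(c) for c in concepts]
        target = kids[concept_index]
        out = []
        for ti in range(len(self.tabs)):
            if not self._placements[target][ti]:
                continue
            _, regions = self.tableau_total(ti, kids, len(concepts))
            for start0, kid in regions:
                if kid == target:
                    out.append((ti, start0))
        return out


# ---------------------------------------------------------------------------
# Proposal primitives
# ---------------------------------------------------------------------------

_PRIMITIVES = ("add", "remove", "length", "kappa", "swap")


def _try_primitive(prim, concepts, state: CollectionState, rng,
                   counter: list):
    spec = state.spec
    if prim == "add":
        eligible = [t for t in state.tabs if t.n >= 2]
        if not eligible:
            return None
        t = eligible[int(rng.integers(len(eligible)))]
        a = int(rng.integers(1, t.n))           # 1-based start in [1, n-1]
        b = int(rng.integers(a + 1, t.n + 1))   # 1-based end   in [a+1, n]
        try:
            cand = extract_candidate(t, (a, b), spec,
                                     concept_id=f"c_tmp{counter[0]}")
        except (DisconnectedError, ValueError):
            return None
        counter[0] += 1
        return concepts + [cand]
    if not concepts:
        return None
    ci = int(rng.integers(len(concepts)))
    c = concepts[ci]
    if prim == "remove":
        return concepts[:ci] + concepts[ci + 1:]
    if prim == "kappa":
        idx = spec.kappa_index(c.kappa)
        step = 1 if rng.random() < 0.5 else -1
        new = idx + step
        if not (0 <= new < len(spec.kappa_grid)):
            new = idx - step
        from dataclasses import replace
        cand = replace(c, kappa=float(spec.kappa_grid[new]))
        return concepts[:ci] + [cand] + concepts[ci + 1:]
    if prim == "length":
        tid, (s, e) = c.provenance
        src = state.by_id.get(tid)
        if src is None:
            return None
        grow = rng.random() < 0.5
        left = rng.random() < 0.5
        if grow:
            ns, ne = (s - 1, e) if left else (s, e + 1)
        else:
            ns, ne = (s + 1, e) if left else (s, e - 1)
        if not (1 <= ns <= ne <= src.n) or ne - ns + 1 < 2:
            return None
        try:
            cand = extract_candidate(src, (ns, ne), spec,
                                     concept_id=f"c_tmp{counter[0]}",
                                     kappa=c.kappa)
        except (DisconnectedError, ValueError):
            return None
        counter[0] += 1
        return concepts[:ci] + [cand] + concepts[ci + 1:]
    if prim == "swap":
        for cc in concepts:
            state.placements(cc)
        uses = state.usages(concepts, ci)
        if not uses:
            return None
        ti, a0 = uses[int(rng.integers(len(uses)))]
        t = state.tabs[ti]
        span = (a0 + 1, a0 + c.archetype.n)
        try:
            cand = extract_candidate(t, span, spec,
                                     concept_id=f"c_tmp{counter[0]}",
                                     kappa=c.kappa)
        except (DisconnectedError, ValueError):
            return None
        counter[0] += 1
        return concepts[:ci] + [cand] + concepts[ci + 1:]
    raise AssertionError(prim)


def _propose(concepts, state: CollectionState, rng, counter,
             max_redraws: int = 50):
    """One perturbed concept list, or None if nothing could be drawn."""
    for _ in range(max_redraws):
        applicable = ["add"]
        if concepts:
            applicable += ["remove", "length", "kappa", "swap"]
        prim = applicable[int(rng.integers(len(applicable)))]
        cand = _try_primitive(prim, concepts, state, rng, counter)
        if cand is not None:
            return cand
    # redraws exhausted: force Add
    for _ in range(1000):
        cand = _try_primitive("add", concepts, state, rng, counter)
        if cand is not None:
            return cand
    return None


def propose(C: Dictionary, collection, rng,
            state: CollectionState | None = None) -> Dictionary:
    """Public single-proposal interface (used by tests; the annealer keeps
    its own state across calls)."""
    state = state or CollectionState(collection, C.spec)
    for c in C.concepts:
        state.placements(c)
    cand = _propose(list(C.concepts), state, rng, [0])
    if cand is None:
        raise RuntimeError("no valid proposal could be generated "
                           "(collection admits no candidate concepts)")
    return Dictionary(concepts=cand, spec=C.spec)


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------

def anneal(collection, params: AnnealParams | None = None,
           spec: CodeSpec | None = None, return_details: bool = False):
    """Infer the minimum-message-length concept dictionary for a collection.

    Returns the best-seen dictionary if its two-part total beats the null
    encoding of the collection, otherwise the empty dictionary.  With
    ``return_details=True`` also returns the per-temperature trace and the
    best two-part total in bits.
    """
    params = params or AnnealParams()
    spec = spec or CodeSpec()
    if not collection:
        raise ValueError("collection must be non-empty")
    rng = np.random.default_rng(params.seed)
    state = CollectionState(collection, spec)
    counter = [0]

    concepts: list = []
    current = state.collection_total(concepts)
    best_concepts, best_total = list(concepts), current

    trace = []
    temp = params.t0
    stall = 0
    while temp >= params.t_min and stall < params.stall_limit:
        accepts = 0
        for _ in range(params.iters_per_temp):
            cand = _propose(concepts, state, rng, counter)
            if cand is None:
                continue
            cand_total = state.collection_total(cand)
            delta = cand_total - current
            if delta < 0 or rng.random() < 2.0 ** (-min(delta / temp, 60.0)):
                concepts, current = cand, cand_total
                accepts += 1
                if current < best_total - 1e-12:
                    best_concepts, best_total = list(concepts), current
        recomputed = state.collection_total(concepts)
        trace.append({"temp": temp, "current_bits": current,
                      "best_bits": best_total, "n_concepts": len(concepts),
                      "recomputed_bits": recomputed, "accepts": accepts})
        current = recomputed
        stall = stall + 1 if accepts == 0 else 0
        temp *= params.alpha

    if best_total < state.null_sum:
        result = finalize_ids(Dictionary(concepts=best_concepts, spec=spec))
    else:
        result = Dictionary(concepts=[], spec=spec)
        best_total = min(best_total, state.collection_total([]))
    if return_details:
        return result, trace, float(best_total)
    return result


def compression_gain(collection, C: Dictionary,
                     spec: CodeSpec | None = None) -> float:
    """Bits saved over the null model: sum of null lengths minus the
    two-part total; negative when the dictionary does not pay for itself."""
    from .dissection import total_collection_len
    spec = spec or C.spec
    null_sum = sum(null_tableau_len(t, spec).bits for t in collection)
    return float(null_sum - total_collection_len(collection, C, spec).bits)
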