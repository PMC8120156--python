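"""Synthetic tableau collections with planted motifs.

Emulates the statistical structure real tableaux exhibit — SSE strings
over {H, E}, dense near-diagonal contacts with sparser long-range ones,
and angles on (-180, 180] — and can plant a ground-truth motif: a span of
each selected tableau is overwritten with a concept archetype whose angles
are re-drawn as von Mises perturbations of the archetype angles, the same
flexibility model the concept codec assumes.  Everything is reproducible
from a seed, so inference, dissection and clustering can be benchmarked
without any structural download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .codec import CodeSpec, quantize_angle
from .dictionary import Concept, Dictionary
from .tableau import Tableau, wrap_angle

__all__ = ["SynthParams", "GroundTruth", "random_tableau", "plant_motif",
           "make_benchmark", "recovery_score", "default_motif",
           "random_dictionary"]


@dataclass
class SynthParams:
    """Generator settings.

    The defaults are the reference benchmark conditions: 60 tableaux of
    5-10 SSEs, adjacent-pair contact probability 0.9 versus 0.15 for
    longer-range pairs, a 4-SSE motif planted in half the collection with
    usage-angle concentration kappa_true = 50 (angular s.d. about 8 deg).
    """

    n_tableaux: int = 60
    sse_range: tuple = (5, 10)
    p_helix: float = 0.5
    p_contact_adjacent: float = 0.9
    p_contact_far: float = 0.15
    motif: Concept | None = None
    plant_fraction: float = 0.5
    kappa_true: float = 50.0
    seed: int = 0
    spec: CodeSpec = field(default_factory=CodeSpec)

    def __post_init__(self):
        for p in (self.p_helix, self.p_contact_adjacent, self.p_contact_far,
                  self.plant_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.kappa_true < 0:
            raise ValueError("kappa_true must be >= 0")
        if self.sse_range[0] > self.sse_range[1] or self.sse_range[0] < 0:
            raise ValueError(f"bad sse_range {self.sse_range}")


@dataclass
class GroundTruth:
    """Planted-motif annotations for a generated collection."""

    motif: Concept | None
    kappa_true: float
    spans: list            # per tableau: (start, end) 1-based inclusive, or None

    def planted(self):
        return [(i, s) for i, s in enumerate(self.spans) if s is not None]

    def to_json_dict(self) -> dict:
        return {"kappa_true": self.kappa_true,
                "motif_sse": self.motif.sse_string if self.motif else None,
                "spans": [list(s) if s else None for s in self.spans]}


def default_motif(spec: CodeSpec | None = None) -> Concept:
    """The reference 4-SSE planted motif: an alpha-beta unit EHHE with a
    connected contact pattern and fixed archetype angles."""
    spec = spec or CodeSpec()
    n = 4
    contacts = np.zeros((n, n), dtype=bool)
    for i, j in [(0, 1), (1, 2), (2, 3), (0, 3)]:
        contacts[i, j] = contacts[j, i] = True
    angles = np.zeros((n, n), dtype=float)
    vals = {(0, 1): -42.5, (1, 2): 160.5, (2, 3): 27.5, (0, 3): -8.5}
    for (i, j), a in vals.items():
        angles[i, j] = angles[j, i] = a
    arch = Tableau(id="motif|1-4", sse_string="EHHE",
                   contacts=contacts, angles=angles)
    kappa = spec.kappa_grid[len(spec.kappa_grid) // 2]
    return Concept(id="c_true", archetype=arch, kappa=float(kappa),
                   provenance=("motif", (1, 4)))


def _random_angle(rng, spec: CodeSpec) -> float:
    k = int(rng.integers(spec.n_angle_bins))
    return -180.0 + (k + 0.5) * spec.epsilon_deg


def random_tableau(params: SynthParams, rng, tableau_id: str = "synth") -> Tableau:
    """One random tableau: size uniform on sse_range, i.i.d. SSE types,
    banded contact probabilities, uniform quantized angles."""
    spec = params.spec
    n = int(rng.integers(params.sse_range[0], params.sse_range[1] + 1))
    sse = "".join("H" if rng.random() < params.p_helix else "E"
                  for _ in range(n))
    contacts = np.zeros((n, n), dtype=bool)
    angles = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            p = params.p_contact_adjacent if j - i == 1 else params.p_contact_far
            c = rng.random() < p
            contacts[i, j] = contacts[j, i] = c
            a = _random_angle(rng, spec)
            angles[i, j] = angles[j, i] = a
    return Tableau(id=tableau_id, sse_string=sse, contacts=contacts,
                   angles=angles)


def plant_motif(t: Tableau, motif: Concept, kappa_true: float, rng,
                spec: CodeSpec | None = None):
    """Overwrite a random consecutive span of ``t`` with the motif.

    SSE types and contacts are copied from the archetype; each
    archetype-contact angle becomes archetype + von Mises(0, kappa_true)
    noise, wrapped and quantized.  Returns (new tableau, 1-based span).
    The planted span always satisfies the concept match gate by
    construction.
    """
    spec = spec or CodeSpec()
    m = motif.archetype.n
    if m > t.n:
        raise ValueError(f"motif of {m} SSEs does not fit tableau n={t.n}")
    a0 = int(rng.integers(0, t.n - m + 1))
    sse = list(t.sse_string)
    contacts = t.contacts.copy()
    angles = t.angles.copy()
    for i in range(m):
        sse[a0 + i] = motif.archetype.sse_string[i]
    for i in range(m):
        for j in range(i + 1, m):
            c = bool(motif.archetype.contacts[i, j])
            contacts[a0 + i, a0 + j] = contacts[a0 + j, a0 + i] = c
            if c:
                noise = (0.0 if kappa_true == 0 else
                         float(np.degrees(rng.vonmises(0.0, kappa_true))))
                if kappa_true == 0:
                    noise = float(rng.uniform(-180.0, 180.0))
                a = quantize_angle(
                    wrap_angle(motif.archetype.angles[i, j] + noise), spec)
            else:
                a = 0.0
            angles[a0 + i, a0 + j] = angles[a0 + j, a0 + i] = a
    out = Tableau(id=t.id, sse_string="".join(sse), contacts=contacts,
                  angles=angles)
    return out, (a0 + 1, a0 + m)


def make_benchmark(params: SynthParams):
    """Generate (collection, GroundTruth) reproducibly from params.seed.

    ``round(plant_fraction * n_tableaux)`` tableaux, chosen at random,
    receive the motif (params.motif, or the reference motif when a
    positive plant fraction is requested with no motif supplied).
    """
    rng = np.random.default_rng(params.seed)
    motif = params.motif
    if motif is None and params.plant_fraction > 0:
        motif = default_motif(params.spec)
    collection = [random_tableau(params, rng, tableau_id=f"synth{i:04d}")
                  for i in range(params.n_tableaux)]
    spans = [None] * params.n_tableaux
    n_plant = int(round(params.plant_fraction * params.n_tableaux))
    if n_plant and motif is not None:
        fits = [i for i, t in enumerate(collection)
                if t.n >= motif.archetype.n]
        chosen = rng.choice(len(fits), size=min(n_plant, len(fits)),
                            replace=False)
        for k in sorted(int(c) for c in chosen):
            i = fits[k]
            collection[i], spans[i] = plant_motif(
                collection[i], motif, params.kappa_true, rng, params.spec)
    return collection, GroundTruth(motif=motif, kappa_true=params.kappa_true,
                                   spans=spans)


def random_dictionary(collection, rng, spec: CodeSpec | None = None,
                      max_concepts: int = 4) -> Dictionary:
    """A random dictionary of up to ``max_concepts`` valid candidates
    extracted from random spans of the collection (for stress tests and
    oracle comparisons)."""
    from .dictionary import DisconnectedError, extract_candidate
    spec = spec or CodeSpec()
    concepts = []
    want = int(rng.integers(0, max_concepts + 1))
    attempts = 0
    while len(concepts) < want and attempts < 200:
        attempts += 1
        t = collection[int(rng.integers(len(collection)))]
        if t.n < 2:
            continue
        a = int(rng.integers(1, t.n))
        b = int(rng.integers(a + 1, t.n + 1))
        kappa = float(spec.kappa_grid[int(rng.integers(len(spec.kappa_grid)))])
        try:
            concepts.append(extract_candidate(
                t, (a, b), spec, concept_id=f"c_{len(concepts) + 1:04d}",
                kappa=kappa))
        except (DisconnectedError, ValueError):
            continue
    return Dictionary(concepts=concepts, spec=spec)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _mean_abs_angle_dev(concept: Concept, motif: Concept) -> float:
    arch, m = concept.archetype, motif.archetype
    devs = [abs(wrap_angle(arch.angles[i, j] - m.angles[i, j]))
            for i in range(m.n) for j in range(i + 1, m.n)
            if m.contacts[i, j]]
    return float(np.mean(devs)) if devs else 0.0


def recovery_score(inferred: Dictionary, truth: GroundTruth,
                   angle_tol_deg: float = 15.0,
                   collection=None) -> dict:
    """Did the inference recover the planted motif?

    Recovery requires some inferred concept with the motif's exact SSE
    string and contact matrix whose archetype angles deviate (circular mean
    of absolute deviations over archetype contacts) by less than
    ``angle_tol_deg``.  When the collection is supplied, the report also
    measures how well that concept's usages overlap the planted spans.
    """
    report = {"motif_recovered": False, "best_concept_id": None,
              "mean_abs_angle_dev_deg": None, "usage_overlap": None}
    if truth.motif is None or not inferred.concepts:
        return report
    m = truth.motif
    matching = [c for c in inferred.concepts
                if c.sse_string == m.sse_string
                and np.array_equal(c.archetype.contacts, m.archetype.contacts)]
    if not matching:
        return report
    devs = [(_mean_abs_angle_dev(c, m), c) for c in matching]
    dev, best = min(devs, key=lambda x: x[0])
    report["best_concept_id"] = best.id
    report["mean_abs_angle_dev_deg"] = dev
    report["motif_recovered"] = bool(dev < angle_tol_deg)
    if collection is not None:
        from .dissection import dissect
        overlaps = []
        for i, span in truth.planted():
            d = dissect(collection[i], inferred)
            jac = 0.0
            want = set(range(span[0], span[1] + 1))
            for r in d.regions:
                if r.concept_id == best.id:
                    got = set(range(r.span[0], r.span[1] + 1))
                    jac = max(jac, len(want & got) / len(want | got))
            overlaps.append(jac)
        report["usage_overlap"] = float(np.mean(overlaps)) if overlaps else None
    return report


def save_ground_truth(truth: GroundTruth, path):
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
        fh.write("\n")
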