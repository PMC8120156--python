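"""Concepts and concept dictionaries.

A *concept* is a topologically conserved assembly of at least two
consecutive SSEs whose contact graph is connected, represented by a
concrete archetype subtableau drawn from a source tableau, plus a von
Mises concentration ``kappa`` controlling how tightly usage angles must
cluster around the archetype's.  A *dictionary* is an ordered set of
concepts; the null concept ``c_0000`` (unexplained single SSEs) is
implicit and never stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from .codec import CodeSpec
from .tableau import Tableau

__all__ = ["Concept", "Dictionary", "extract_candidate", "is_connected",
           "finalize_ids", "save_dictionary", "load_dictionary",
           "DisconnectedError"]

DICT_FORMAT_VERSION = 1
NULL_CONCEPT_ID = "c_0000"


class DisconnectedError(ValueError):
    """Candidate subtableau rejected: contact graph not connected."""

    def __init__(self, isolated):
        self.isolated = list(isolated)
        sses = ", ".join(str(i + 1) for i in self.isolated)
        super().__init__(f"contact graph not connected; SSE(s) {sses} "
                         f"unreachable from SSE 1")


def is_connected(contacts: np.ndarray) -> bool:
    """True iff the undirected contact graph is connected (n >= 1)."""
    contacts = np.asarray(contacts, dtype=bool)
    n = contacts.shape[0]
    if n == 0:
        raise ValueError("connectivity undefined for an empty graph")
    return len(set(_components(contacts))) == 1


@dataclass(frozen=True)
class Concept:
    """A dictionary entry: archetype subtableau + concentration + provenance.

    ``provenance`` is ``(source_tableau_id, (start, end))`` with a 1-based
    inclusive SSE span into the source tableau.
    """

    id: str
    archetype: Tableau
    kappa: float
    provenance: tuple = ("", (0, 0))

    def __post_init__(self):
        if self.archetype.n < 2:
            raise ValueError(f"concept {self.id!r}: archetype needs >= 2 SSEs")
        if not is_connected(self.archetype.contacts):
            comp = _components(self.archetype.contacts)
            raise DisconnectedError([i for i in range(self.archetype.n)
                                     if comp[i] != comp[0]])

    @property
    def n(self) -> int:
        return self.archetype.n

    @property
    def sse_string(self) -> str:
        return self.archetype.sse_string

    def cache_key(self) -> tuple:
        """Content identity (id- and provenance-free), for match-cost caches."""
        return (self.sse_string,
                self.archetype.contacts.tobytes(),
                np.round(self.archetype.angles, 6).tobytes(),
                round(float(self.kappa), 12))

    def __eq__(self, other):
        if not isinstance(other, Concept):
            return NotImplemented
        return (self.id == other.id and self.kappa == other.kappa
                and self.provenance == other.provenance
                and self.archetype.equals(other.archetype))


def _components(contacts):
    """Component label per vertex (iterative depth-first search; contact
    graphs here are small, so plain Python beats sparse-matrix setup)."""
    c = np.asarray(contacts, dtype=bool)
    n = c.shape[0]
    labels = [-1] * n
    lab = 0
    for s in range(n):
        if labels[s] != -1:
            continue
        stack = [s]
        labels[s] = lab
        while stack:
            v = stack.pop()
            for w in range(n):
                if c[v, w] and labels[w] == -1:
                    labels[w] = lab
                    stack.append(w)
        lab += 1
    return labels


@dataclass
class Dictionary:
    """Ordered set of concepts sharing one :class:`CodeSpec`."""

    concepts: list = field(default_factory=list)
    spec: CodeSpec = field(default_factory=CodeSpec)

    def __len__(self):
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    def __getitem__(self, key):
        if isinstance(key, str):
            for c in self.concepts:
                if c.id == key:
                    return c
            raise KeyError(key)
        return self.concepts[key]

    def validate(self):
        ids = [c.id for c in self.concepts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate concept ids")
        for c in self.concepts:
            # revalidation: every stored concept must still be a valid candidate
            Concept(c.id, c.archetype, c.kappa, c.provenance)

    def signature(self) -> tuple:
        return tuple(c.cache_key() for c in self.concepts)


def extract_candidate(t: Tableau, span: tuple, spec: CodeSpec | None = None,
                      concept_id: str = "c_cand", kappa: float | None = None) -> Concept:
    """Cut a candidate concept out of a tableau.

    ``span`` is 1-based inclusive over SSEs and must cover >= 2 SSEs whose
    contact subgraph is connected; otherwise the candidate is rejected.
    Non-contacting archetype angles are zeroed (they are derived data and
    never coded), giving concepts a canonical serializable form.  ``kappa``
    defaults to the grid median; the annealer's kappa moves refine it.
    """
    start, end = span
    if end - start + 1 < 2:
        raise ValueError(f"candidate span {span} shorter than 2 SSEs")
    if not (1 <= start <= end <= t.n):
        raise ValueError(f"span {span} outside tableau of n={t.n}")
    arch = t.subtableau(start - 1, end, new_id=f"{t.id}|{start}-{end}")
    comp = _components(arch.contacts)
    if len(set(comp)) > 1:
        raise DisconnectedError([i for i in range(arch.n) if comp[i] != comp[0]])
    arch.angles = np.where(arch.contacts, arch.angles, 0.0)
    spec = spec or CodeSpec()
    if kappa is None:
        kappa = spec.kappa_grid[len(spec.kappa_grid) // 2]
    return Concept(id=concept_id, archetype=arch, kappa=float(kappa),
                   provenance=(t.id, (start, end)))


def finalize_ids(C: Dictionary) -> Dictionary:
    """Reassign ids c_0001... ordered by decreasing archetype size, then
    lexicographic SSE string; ties broken by provenance (stable)."""
    order = sorted(range(len(C.concepts)),
                   key=lambda k: (-C.concepts[k].n,
                                  C.concepts[k].sse_string,
                                  C.concepts[k].provenance,
                                  k))
    concepts = [replace(C.concepts[k], id=f"c_{r + 1:04d}")
                for r, k in enumerate(order)]
    return Dictionary(concepts=concepts, spec=C.spec)


# ---------------------------------------------------------------------------
# Serialization (JSON)
# ---------------------------------------------------------------------------

def _rle_upper(contacts: np.ndarray) -> list:
    """Run-length encode the row-major strict upper triangle."""
    n = contacts.shape[0]
    flat = [int(contacts[i, j]) for i in range(n) for j in range(i + 1, n)]
    runs = []
    for v in flat:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([v, 1])
    return runs


def _unrle_upper(runs: list, n: int) -> np.ndarray:
    flat = []
    for v, ln in runs:
        flat.extend([bool(v)] * ln)
    if len(flat) != n * (n - 1) // 2:
        raise ValueError("contact run-length data does not match n")
    contacts = np.zeros((n, n), dtype=bool)
    it = iter(flat)
    for i in range(n):
        for j in range(i + 1, n):
            contacts[i, j] = contacts[j, i] = next(it)
    return contacts


def _concept_to_json(c: Concept) -> dict:
    n = c.n
    angles = [[i + 1, j + 1, round(float(c.archetype.angles[i, j]), 2)]
              for i in range(n) for j in range(i + 1, n)
              if c.archetype.contacts[i, j]]
    return {"id": c.id, "sse_string": c.sse_string,
            "contacts": _rle_upper(c.archetype.contacts),
            "angles": angles, "kappa": float(c.kappa),
            "provenance": [c.provenance[0], list(c.provenance[1])]}


def _concept_from_json(d: dict) -> Concept:
    sse = d["sse_string"]
    n = len(sse)
    contacts = _unrle_upper(d["contacts"], n)
    angles = np.zeros((n, n), dtype=float)
    for i, j, a in d["angles"]:
        angles[i - 1, j - 1] = angles[j - 1, i - 1] = float(a)
    arch = Tableau(id=f"{d['provenance'][0]}|{d['provenance'][1][0]}-"
                      f"{d['provenance'][1][1]}",
                   sse_string=sse, contacts=contacts, angles=angles)
    return Concept(id=d["id"], archetype=arch, kappa=float(d["kappa"]),
                   provenance=(d["provenance"][0], tuple(d["provenance"][1])))


def save_dictionary(C: Dictionary, path, metadata: dict | None = None):
    """Write a dictionary (including its CodeSpec) as JSON."""
    doc = {"version": DICT_FORMAT_VERSION,
           "spec": C.spec.to_dict(),
           "concepts": [_concept_to_json(c) for c in C.concepts]}
    if metadata:
        doc["metadata"] = metadata
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_dictionary(path) -> Dictionary:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt dictionary file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "version" not in doc:
        raise ValueError(f"not a dictionary file: {path}")
    if doc["version"] != DICT_FORMAT_VERSION:
        raise ValueError(f"dictionary format version {doc['version']} is not "
                         f"supported (expected {DICT_FORMAT_VERSION})")
    spec = CodeSpec.from_dict(doc["spec"])
    concepts = [_concept_from_json(cd) for cd in doc["concepts"]]
    return Dictionary(concepts=concepts, spec=spec)
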