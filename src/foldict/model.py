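"""Model/Results interface to concept-dictionary inference.

``ConceptDictionaryModel`` holds a source collection of tableaux and a
codec specification; ``fit`` runs the simulated-annealing minimum-message-
length search and returns a ``DictionaryResults`` carrying the inferred
dictionary, the message-length bookkeeping, per-tableau dissections, the
annealing trace, and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np

from .codec import CodeSpec, dictionary_len, null_tableau_len
from .dictionary import Dictionary
from .dissection import dissect
from .search import AnnealParams, anneal
from .tableau import read_tableau_file

__all__ = ["ConceptDictionaryModel", "DictionaryResults"]


class ConceptDictionaryModel:
    """Minimum-message-length concept-dictionary model of a tableau
    collection.

    Parameters
    ----------
    collection : sequence of Tableau
        The source collection to be explained.
    spec : CodeSpec, optional
        Codec settings (angle quantization, kappa grid, flip probability).

    Examples
    --------
    >>> from foldict.synthetic import SynthParams, make_benchmark
    >>> coll, truth = make_benchmark(SynthParams(seed=7))
    >>> model = ConceptDictionaryModel(coll)
    >>> res = model.fit(seed=7)          # doctest: +SKIP
    >>> print(res.summary())             # doctest: +SKIP
    """

    def __init__(self, collection, spec: CodeSpec | None = None):
        if not collection:
            raise ValueError("collection must be non-empty")
        self.collection = list(collection)
        self.spec = spec or CodeSpec()
        self.null_bits = float(sum(null_tableau_len(t, self.spec).bits
                                   for t in self.collection))

    @classmethod
    def from_files(cls, paths, spec: CodeSpec | None = None):
        """Build a model from tableau text files (each may hold several
        records)."""
        collection = []
        for p in paths:
            collection.extend(read_tableau_file(p))
        return cls(collection, spec)

    def fit(self, params: AnnealParams | None = None,
            **kwargs) -> "DictionaryResults":
        """Run the annealing search; keyword arguments (seed, t0, alpha,
        iters_per_temp, t_min, stall_limit) override AnnealParams fields."""
        if params is None:
            params = AnnealParams(**kwargs)
        elif kwargs:
            raise TypeError("pass either params or keyword overrides, not both")
        dictionary, trace, best_bits = anneal(
            self.collection, params, self.spec, return_details=True)
        return DictionaryResults(self, dictionary, params, trace, best_bits)


class DictionaryResults:
    """Fitted dictionary plus diagnostics."""

    def __init__(self, model: ConceptDictionaryModel, dictionary: Dictionary,
                 params: AnnealParams, trace: list, total_bits: float):
        self.model = model
        self.dictionary = dictionary
        self.params = params
        self.trace = trace
        self.total_bits = float(total_bits)
        self.null_bits = model.null_bits
        self._dissections = None

    @property
    def n_concepts(self) -> int:
        return len(self.dictionary.concepts)

    @property
    def compression_gain(self) -> float:
        """Bits saved over the null encoding (the model-selection score)."""
        return self.null_bits - self.total_bits

    @property
    def dictionary_bits(self) -> float:
        return dictionary_len(self.dictionary, self.model.spec).bits

    @property
    def dissections(self) -> list:
        """Optimal dissection of every source tableau (computed lazily)."""
        if self._dissections is None:
            self._dissections = [dissect(t, self.dictionary, self.model.spec)
                                 for t in self.model.collection]
        return self._dissections

    def concept_usage_counts(self) -> dict:
        counts = {c.id: 0 for c in self.dictionary.concepts}
        for d in self.dissections:
            for r in d.regions:
                if not r.is_null:
                    counts[r.concept_id] += 1
        return counts

    def sse_coverage(self) -> float:
        """Fraction of SSEs lying in concept (non-null) regions."""
        covered = total = 0
        for d in self.dissections:
            for r in d.regions:
                ln = r.span[1] - r.span[0] + 1
                total += ln
                if not r.is_null:
                    covered += ln
        return covered / total if total else 0.0

    def summary(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Concept dictionary inference (minimum message length)\n")
        w("=" * 57 + "\n")
        w(f"Tableaux in collection:     {len(self.model.collection):>10d}\n")
        w(f"Null encoding (bits):       {self.null_bits:>14.2f}\n")
        w(f"Two-part encoding (bits):   {self.total_bits:>14.2f}\n")
        w(f"Compression gain (bits):    {self.compression_gain:>14.2f}\n")
        pct = (100.0 * self.compression_gain / self.null_bits
               if self.null_bits else 0.0)
        w(f"Compression gain (%):       {pct:>14.2f}\n")
        w(f"Concepts inferred:          {self.n_concepts:>10d}\n")
        if self.n_concepts:
            w(f"Dictionary statement (bits):{self.dictionary_bits:>14.2f}\n")
            w(f"SSE coverage by concepts:   {100 * self.sse_coverage():>13.2f}%\n")
            w("-" * 57 + "\n")
            w(f"{'id':8s} {'nSSE':>4s} {'SSE string':12s} {'kappa':>9s} "
              f"{'usages':>7s}\n")
            usage = self.concept_usage_counts()
            for c in self.dictionary.concepts:
                w(f"{c.id:8s} {c.n:>4d} {c.sse_string:12s} "
                  f"{c.kappa:>9.3g} {usage[c.id]:>7d}\n")
        else:
            w("Null hypothesis retained: no dictionary compresses this "
              "collection.\n")
        return buf.getvalue()

    def plot_trace(self, ax=None):
        """Annealing trajectory: current and best-seen totals vs temperature
        step (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        steps = np.arange(len(self.trace))
        ax.plot(steps, [r["current_bits"] for r in self.trace],
                label="current", lw=1)
        ax.plot(steps, [r["best_bits"] for r in self.trace],
                label="best seen", lw=1.5)
        ax.axhline(self.null_bits, color="grey", ls="--", lw=1,
                   label="null encoding")
        ax.set_xlabel("temperature step")
        ax.set_ylabel("two-part message length (bits)")
        ax.legend()
        return ax
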