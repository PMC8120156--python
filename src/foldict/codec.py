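"""Message-length computations and the lossless tableau codec.

Everything here is measured in bits of Shannon information.  The coded
object for one tableau is ``(n, sse_string, contact matrix, angles of
contacting pairs)``; non-contacting angles are derived data and are not
transmitted.  Two code families are used:

* the *null* model — Elias-gamma for ``n``, Krichevsky–Trofimov (KT)
  adaptive binary codes for SSE symbols and contact cells, and a uniform
  code over quantized angle bins;
* the *concept* model — inside a region explained by a dictionary concept
  the SSE symbols are implied by the archetype, contact cells are coded as
  Bernoulli mismatches against the archetype, and angles of pairs that
  contact in the archetype are coded as von Mises deviations from the
  archetype angle with the concept's concentration ``kappa``.

A working arithmetic coder (``encode_tableau`` / ``decode_tableau``) turns
these probabilities into an actual decodable bit string, so losslessness is
demonstrated, not merely asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e

__all__ = [
    "CodeSpec", "MessageLength", "universal_int_len", "adaptive_binary_len",
    "kt_symbol_costs", "uniform_angle_len", "von_mises_angle_len",
    "null_tableau_len", "dictionary_len", "encode_tableau", "decode_tableau",
    "NullCosts", "angle_bin_index", "angle_bin_center", "quantize_angle",
]

LOG2E = math.log2(math.e)


# ---------------------------------------------------------------------------
# Code specification
# ---------------------------------------------------------------------------

def _default_kappa_grid() -> tuple:
    """kappa = 0 (uniform) plus 64 geometrically spaced values in [0.1, 1000]."""
    return (0.0,) + tuple(np.geomspace(0.1, 1000.0, 64))


@dataclass(frozen=True)
class CodeSpec:
    """Parameters fixing the codec, shared by encoder and decoder.

    epsilon_deg
        Angle quantization step in degrees; must divide 360 exactly.
    kappa_grid
        Admissible von Mises concentrations; strictly increasing, first 0.
        A concept's kappa is stated by its index, costing log2(len(grid)).
    flip_prob
        Bernoulli probability of a contact-cell mismatch inside a concept
        region (small: topology is expected to be conserved).
    """

    epsilon_deg: float = 1.0
    kappa_grid: tuple = field(default_factory=_default_kappa_grid)
    flip_prob: float = 0.05

    def __post_init__(self):
        nb = 360.0 / self.epsilon_deg
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError(f"epsilon_deg={self.epsilon_deg} must divide 360")
        g = np.asarray(self.kappa_grid, dtype=float)
        if g.size < 1 or g[0] != 0.0 or np.any(np.diff(g) <= 0):
            raise ValueError("kappa_grid must start at 0 and strictly increase")
        if not (0.0 < self.flip_prob < 0.5):
            raise ValueError("flip_prob must be in (0, 0.5)")

    @property
    def n_angle_bins(self) -> int:
        return int(round(360.0 / self.epsilon_deg))

    def kappa_index(self, kappa: float) -> int:
        g = np.asarray(self.kappa_grid)
        i = int(np.argmin(np.abs(g - kappa)))
        near = abs(g[i] - kappa) <= 1e-9 * max(1.0, abs(kappa))
        if not near:
            raise ValueError(f"kappa={kappa} is not on the kappa grid")
        return i

    def to_dict(self) -> dict:
        return {"epsilon_deg": self.epsilon_deg,
                "kappa_grid": list(self.kappa_grid),
                "flip_prob": self.flip_prob}

    @classmethod
    def from_dict(cls, d: dict) -> "CodeSpec":
        return cls(epsilon_deg=d["epsilon_deg"],
                   kappa_grid=tuple(d["kappa_grid"]),
                   flip_prob=d["flip_prob"])


@dataclass
class MessageLength:
    """A code length in bits with an additive labeled breakdown."""

    breakdown: dict

    @property
    def bits(self) -> float:
        return float(sum(self.breakdown.values()))

    def __add__(self, other: "MessageLength") -> "MessageLength":
        out = dict(self.breakdown)
        for k, v in other.breakdown.items():
            out[k] = out.get(k, 0.0) + v
        return MessageLength(out)

    def __float__(self):
        return self.bits


# ---------------------------------------------------------------------------
# Elementary code lengths
# ---------------------------------------------------------------------------

def universal_int_len(n: int) -> float:
    """Elias-gamma code length of a positive integer: 2*floor(log2 n) + 1."""
    if n < 1 or int(n) != n:
        raise ValueError(f"universal_int_len needs a positive integer, got {n}")
    return 2.0 * int(math.log2(int(n))) + 1.0


def kt_symbol_costs(symbols) -> np.ndarray:
    """Per-symbol KT code lengths for a binary sequence.

    Symbol ``t`` (0-based) with prior count ``c`` of its own value costs
    ``-log2((c + 0.5) / (t + 1))``.
    """
    sym = np.asarray([int(s) for s in symbols], dtype=int)
    costs = np.empty(sym.size, dtype=float)
    counts = [0, 0]
    for t, s in enumerate(sym):
        costs[t] = -math.log2((counts[s] + 0.5) / (t + 1.0))
        counts[s] += 1
    return costs


def adaptive_binary_len(symbols) -> float:
    """Total KT adaptive code length of a binary sequence (empty -> 0)."""
    return float(kt_symbol_costs(symbols).sum())


def uniform_angle_len(spec: CodeSpec) -> float:
    """Cost of one angle under the uniform null code: log2(360 / epsilon)."""
    return math.log2(spec.n_angle_bins) if spec.n_angle_bins > 1 else 0.0


def von_mises_angle_len(delta_deg: float, kappa: float, spec: CodeSpec) -> float:
    """Cost of an angular deviation under a von Mises(0, kappa) code.

    ``max(0, -log2(f(delta; 0, kappa) * epsilon_rad))`` with
    ``f(d) = exp(kappa cos d) / (2 pi I0(kappa))``.  At kappa = 0 this equals
    the uniform cost exactly; the floor at 0 guards very large kappa where
    density times bin width exceeds 1.
    """
    spec.kappa_index(kappa)  # domain check: kappa must be codable
    if kappa == 0.0:
        return uniform_angle_len(spec)
    d = math.radians(delta_deg)
    eps_rad = math.radians(spec.epsilon_deg)
    # log f = kappa*(cos d - 1) - log(2 pi i0e(kappa))   [i0e = exp(-k) I0(k)]
    logf = kappa * (math.cos(d) - 1.0) - math.log(2.0 * math.pi * i0e(kappa))
    return max(0.0, -(logf + math.log(eps_rad)) * LOG2E)


# ---------------------------------------------------------------------------
# Angle quantization
# ---------------------------------------------------------------------------

def angle_bin_index(angle_deg: float, spec: CodeSpec) -> int:
    """Index of the epsilon-wide bin covering an angle in (-180, 180]."""
    nb = spec.n_angle_bins
    k = int(math.ceil((angle_deg + 180.0) / spec.epsilon_deg)) - 1
    return min(max(k, 0), nb - 1)


def angle_bin_center(k: int, spec: CodeSpec) -> float:
    return -180.0 + (k + 0.5) * spec.epsilon_deg


def quantize_angle(angle_deg: float, spec: CodeSpec) -> float:
    return angle_bin_center(angle_bin_index(angle_deg, spec), spec)


# ---------------------------------------------------------------------------
# Null model of a whole tableau
# ---------------------------------------------------------------------------

_SSE_BIT = {"H": 0, "E": 1}


def upper_pairs(n: int):
    """Row-major order of the strict upper triangle: (0,1), (0,2), ..."""
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j


def null_tableau_len(t, spec: CodeSpec) -> MessageLength:
    """Two-part-free encoding of a tableau without any dictionary.

    n+1 by Elias gamma, SSE string by KT, the n(n-1)/2 upper-triangle
    contact cells (row-major) by KT, and one uniform angle per contacting
    pair.
    """
    n = t.n
    structure = universal_int_len(n + 1)
    structure += adaptive_binary_len([_SSE_BIT[s] for s in t.sse_string])
    cells = [int(t.contacts[i, j]) for i, j in upper_pairs(n)]
    contacts = adaptive_binary_len(cells)
    angles = sum(cells) * uniform_angle_len(spec)
    return MessageLength({"structure": structure, "contacts": contacts,
                          "angles": angles})


class NullCosts:
    """Per-tableau fixed null code lengths, the DP's building blocks.

    KT costs condition on the *actual values* of all preceding symbols in
    the canonical order (whole SSE string; whole upper triangle row-major),
    regardless of which cells a dissection routes through a concept model.
    This makes every per-cell null cost independent of the segmentation, so
    the dissection objective is additive over regions, while remaining
    decodable (the decoder always knows all previously decoded values).
    """

    def __init__(self, t, spec: CodeSpec):
        self.n = n = t.n
        self.spec = spec
        self.sse_costs = kt_symbol_costs([_SSE_BIT[s] for s in t.sse_string])
        u = uniform_angle_len(spec)
        pairs = list(upper_pairs(n))
        cell_vals = [int(t.contacts[i, j]) for i, j in pairs]
        cell_costs = kt_symbol_costs(cell_vals)
        # pair_cost[i, j]: null cost of cell (i,j) plus its angle if contacting
        self.pair_cost = np.zeros((n, n), dtype=float)
        for (i, j), c in zip(pairs, cell_costs):
            self.pair_cost[i, j] = c + (u if t.contacts[i, j] else 0.0)
        # colp[a, j] = sum_{i < a} pair_cost[i, j]
        self.colp = np.zeros((n + 1, n), dtype=float)
        if n:
            self.colp[1:, :] = np.cumsum(self.pair_cost, axis=0)
        # s_null[j] = SSE symbol j + all pairs (i, j), i < j
        self.s_null = np.array(
            [self.sse_costs[j] + self.colp[j, j] for j in range(n)])
        self.core = float(self.s_null.sum())   # null bits minus the n-code

    def back(self, a: int, b: int) -> float:
        """Null cost of all pairs (i, j) with i < a <= j <= b (backward
        cross-region pairs of a region spanning [a, b], 0-based inclusive)."""
        return float(self.colp[a, a:b + 1].sum())


def dictionary_len(C, spec: CodeSpec | None = None) -> MessageLength:
    """First-part cost: state |C|+1, then each concept's archetype under the
    null code plus its kappa by grid index."""
    spec = spec or C.spec
    out = MessageLength({"dictionary": universal_int_len(len(C.concepts) + 1)})
    kbits = math.log2(len(spec.kappa_grid))
    for c in C.concepts:
        arch = null_tableau_len(c.archetype, spec)
        out = out + MessageLength({"dictionary": arch.bits + kbits})
    return out


# ---------------------------------------------------------------------------
# Arithmetic coder
# ---------------------------------------------------------------------------

_TOP = 1 << 32
_MASK = _TOP - 1
_HALF = _TOP >> 1
_QUARTER = _TOP >> 2


class _ArEncoder:
    def __init__(self):
        self.low, self.high = 0, _MASK
        self.pending = 0
        self.out = []

    def _emit(self, bit):
        self.out.append(bit)
        if self.pending:
            self.out.extend([1 - bit] * self.pending)
            self.pending = 0

    def encode(self, cum_lo: int, cum_hi: int, total: int):
        span = self.high - self.low + 1
        self.high = self.low + (span * cum_hi) // total - 1
        self.low = self.low + (span * cum_lo) // total
        while True:
            if self.high < _HALF:
                self._emit(0)
            elif self.low >= _HALF:
                self._emit(1)
                self.low -= _HALF
                self.high -= _HALF
            elif self.low >= _QUARTER and self.high < 3 * _QUARTER:
                self.pending += 1
                self.low -= _QUARTER
                self.high -= _QUARTER
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1

    def finish(self) -> str:
        self.pending += 1
        self._emit(0 if self.low < _QUARTER else 1)
        return "".join("01"[b] for b in self.out)


class _ArDecoder:
    def __init__(self, bits: str):
        self.bits = bits
        self.pos = 0
        self.low, self.high = 0, _MASK
        self.code = 0
        for _ in range(32):
            self.code = (self.code << 1) | self._next()

    def _next(self) -> int:
        if self.pos < len(self.bits):
            b = self.bits[self.pos]
            if b not in "01":
                raise ValueError("bit string must contain only 0/1")
            self.pos += 1
            return int(b)
        self.pos += 1
        return 0

    def target(self, total: int) -> int:
        span = self.high - self.low + 1
        return ((self.code - self.low + 1) * total - 1) // span

    def update(self, cum_lo: int, cum_hi: int, total: int):
        span = self.high - self.low + 1
        self.high = self.low + (span * cum_hi) // total - 1
        self.low = self.low + (span * cum_lo) // total
        while True:
            if self.high < _HALF:
                pass
            elif self.low >= _HALF:
                self.low -= _HALF
                self.high -= _HALF
                self.code -= _HALF
            elif self.low >= _QUARTER and self.high < 3 * _QUARTER:
                self.low -= _QUARTER
                self.high -= _QUARTER
                self.code -= _QUARTER
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1
            self.code = (self.code << 1) | self._next()


# ---------------------------------------------------------------------------
# Frequency models shared by encoder and decoder
# ---------------------------------------------------------------------------

_FLIP_TOTAL = 1 << 20
_VM_SCALE = 1 << 16
_vm_cache: dict = {}


def _flip_freqs(spec: CodeSpec):
    f1 = max(1, round(spec.flip_prob * _FLIP_TOTAL))
    return (_FLIP_TOTAL - f1, f1)


def _vm_cumfreqs(kappa: float, spec: CodeSpec) -> np.ndarray:
    """Cumulative integer frequencies over deviation bins for von Mises."""
    key = (round(float(kappa), 12), spec.epsilon_deg)
    cum = _vm_cache.get(key)
    if cum is None:
        nb = spec.n_angle_bins
        centers = np.radians(
            [-180.0 + (k + 0.5) * spec.epsilon_deg for k in range(nb)])
        w = np.exp(kappa * (np.cos(centers) - 1.0))
        f = np.maximum(1, np.round(w * _VM_SCALE).astype(np.int64))
        cum = np.concatenate([[0], np.cumsum(f)])
        _vm_cache[key] = cum
    return cum


class _KT:
    """Adaptive binary KT state usable for coding or costing."""

    __slots__ = ("c0", "c1")

    def __init__(self):
        self.c0 = self.c1 = 0

    def bounds(self, sym: int):
        f0 = 2 * self.c0 + 1
        total = 2 * (self.c0 + self.c1) + 2
        return (0, f0, total) if sym == 0 else (f0, total, total)

    def update(self, sym: int):
        if sym == 0:
            self.c0 += 1
        else:
            self.c1 += 1


# ---------------------------------------------------------------------------
# Tableau encode / decode against a dictionary and a dissection
# ---------------------------------------------------------------------------

def _region_layout(t, C, d):
    """Map each SSE (0-based) to its region; return (region_of, concept_of).

    ``concept_of[r]`` is the Concept for concept regions, None for null.
    Raises on an invalid dissection (bad tiling, label, or match gate).
    """
    n = t.n
    region_of = np.full(n, -1, dtype=int)
    concepts_by_id = {c.id: c for c in C.concepts}
    concept_of = []
    pos = 0
    for r, reg in enumerate(d.regions):
        a, b = reg.span  # 1-based inclusive
        a0, b0 = a - 1, b - 1
        if a0 != pos:
            raise ValueError(f"dissection regions do not tile: gap at SSE {pos + 1}")
        if reg.concept_id in (None, "c_0000"):
            if b0 != a0:
                raise ValueError("null regions must cover exactly one SSE")
            concept_of.append(None)
        else:
            c = concepts_by_id.get(reg.concept_id)
            if c is None:
                raise ValueError(f"unknown concept {reg.concept_id!r}")
            if b0 - a0 + 1 != c.archetype.n:
                raise ValueError(f"region span does not match archetype size "
                                 f"for {reg.concept_id}")
            if t.sse_string[a0:b0 + 1] != c.archetype.sse_string:
                raise ValueError(f"SSE mismatch for {reg.concept_id} at {a}-{b}")
            sub = t.contacts[a0:b0 + 1, a0:b0 + 1]
            if np.any(c.archetype.contacts & ~sub):
                raise ValueError(f"archetype contact absent in tableau for "
                                 f"{reg.concept_id} at {a}-{b}")
            concept_of.append(c)
        region_of[a0:b0 + 1] = r
        pos = b0 + 1
    if pos != n:
        raise ValueError("dissection regions do not cover the tableau")
    return region_of, concept_of


def _enc_bit(enc, bit):
    enc.encode(bit, bit + 1, 2)


def _dec_bit(dec) -> int:
    b = dec.target(2)
    dec.update(b, b + 1, 2)
    return int(b)


def _enc_gamma(enc, n: int):
    z = int(math.log2(n))
    for _ in range(z):
        _enc_bit(enc, 0)
    for k in range(z, -1, -1):
        _enc_bit(enc, (n >> k) & 1)


def _dec_gamma(dec) -> int:
    z = 0
    while _dec_bit(dec) == 0:
        z += 1
        if z > 64:
            raise ValueError("truncated or corrupt gamma code")
    val = 1
    for _ in range(z):
        val = (val << 1) | _dec_bit(dec)
    return val


def encode_tableau(t, C, d, spec: CodeSpec | None = None) -> str:
    """Arithmetic-encode a tableau against dictionary ``C`` and dissection
    ``d``; returns a '0'/'1' string decodable by :func:`decode_tableau`."""
    spec = spec or C.spec
    n = t.n
    region_of, concept_of = _region_layout(t, C, d)
    enc = _ArEncoder()
    _enc_gamma(enc, n + 1)
    nlab = len(C.concepts) + 1
    label_index = {c.id: k + 1 for k, c in enumerate(C.concepts)}
    if nlab > 1:
        for reg, c in zip(d.regions, concept_of):
            lab = 0 if c is None else label_index[c.id]
            enc.encode(lab, lab + 1, nlab)
    region_start = {}
    for i in range(n):
        r = region_of[i]
        if r not in region_start:
            region_start[r] = i
    # SSE symbols: concept-region symbols are implied by the archetype
    kt = _KT()
    for i in range(n):
        sym = _SSE_BIT[t.sse_string[i]]
        if concept_of[region_of[i]] is None:
            enc.encode(*kt.bounds(sym))
        kt.update(sym)
    # contact cells, row-major upper triangle
    f0, f1 = _flip_freqs(spec)
    kt = _KT()
    for i, j in upper_pairs(n):
        v = int(t.contacts[i, j])
        c = concept_of[region_of[i]] if region_of[i] == region_of[j] else None
        if c is not None:
            a = region_start[region_of[i]]
            mism = v ^ int(c.archetype.contacts[i - a, j - a])
            enc.encode(*((0, f0, _FLIP_TOTAL) if mism == 0
                         else (f0, _FLIP_TOTAL, _FLIP_TOTAL)))
        else:
            enc.encode(*kt.bounds(v))
        kt.update(v)
    # angles of contacting pairs, same order
    nb = spec.n_angle_bins
    from .tableau import wrap_angle
    for i, j in upper_pairs(n):
        if not t.contacts[i, j]:
            continue
        c = concept_of[region_of[i]] if region_of[i] == region_of[j] else None
        if c is not None:
            a = region_start[region_of[i]]
            if c.archetype.contacts[i - a, j - a]:
                delta = wrap_angle(t.angles[i, j] - c.archetype.angles[i - a, j - a])
                k = angle_bin_index(delta, spec)
                cum = _vm_cumfreqs(c.kappa, spec)
                enc.encode(int(cum[k]), int(cum[k + 1]), int(cum[-1]))
                continue
        k = angle_bin_index(t.angles[i, j], spec)
        enc.encode(k, k + 1, nb)
    return enc.finish()


def decode_tableau(bits: str, C, spec: CodeSpec | None = None,
                   tableau_id: str = "decoded"):
    """Invert :func:`encode_tableau`.

    Reconstructs the SSE string and contacts exactly and every coded angle
    to its bin center (within epsilon/2).  Non-contacting angles, which are
    never transmitted, are returned as 0.
    """
    from .tableau import Tableau, wrap_angle
    spec = spec or C.spec
    dec = _ArDecoder(bits)
    n = _dec_gamma(dec) - 1
    nlab = len(C.concepts) + 1
    # labels -> regions
    regions = []          # (start0, concept or None)
    pos = 0
    while pos < n:
        if nlab > 1:
            lab = dec.target(nlab)
            dec.update(lab, lab + 1, nlab)
        else:
            lab = 0
        if lab == 0:
            regions.append((pos, None))
            pos += 1
        else:
            c = C.concepts[lab - 1]
            regions.append((pos, c))
            pos += c.archetype.n
    if pos != n:
        raise ValueError("decoded labels do not tile the tableau")
    region_of = np.empty(n, dtype=int)
    region_start = {}
    concept_of = []
    for r, (start, c) in enumerate(regions):
        ln = 1 if c is None else c.archetype.n
        region_of[start:start + ln] = r
        region_start[r] = start
        concept_of.append(c)
    # SSE string
    kt = _KT()
    sse = []
    for i in range(n):
        c = concept_of[region_of[i]]
        if c is None:
            lo0, hi0, total = kt.bounds(0)
            tgt = dec.target(total)
            sym = 0 if tgt < hi0 else 1
            dec.update(*kt.bounds(sym))
        else:
            sym = _SSE_BIT[c.archetype.sse_string[i - region_start[region_of[i]]]]
        sse.append("HE"[sym])
        kt.update(sym)
    # contacts
    f0, f1 = _flip_freqs(spec)
    contacts = np.zeros((n, n), dtype=bool)
    kt = _KT()
    for i, j in upper_pairs(n):
        c = concept_of[region_of[i]] if region_of[i] == region_of[j] else None
        if c is not None:
            a = region_start[region_of[i]]
            tgt = dec.target(_FLIP_TOTAL)
            mism = 0 if tgt < f0 else 1
            dec.update(*((0, f0, _FLIP_TOTAL) if mism == 0
                         else (f0, _FLIP_TOTAL, _FLIP_TOTAL)))
            v = mism ^ int(c.archetype.contacts[i - a, j - a])
        else:
            lo0, hi0, total = kt.bounds(0)
            v = 0 if dec.target(total) < hi0 else 1
            dec.update(*kt.bounds(v))
        contacts[i, j] = contacts[j, i] = bool(v)
        kt.update(v)
    # angles
    nb = spec.n_angle_bins
    angles = np.zeros((n, n), dtype=float)
    for i, j in upper_pairs(n):
        if not contacts[i, j]:
            continue
        c = concept_of[region_of[i]] if region_of[i] == region_of[j] else None
        if c is not None:
            a = region_start[region_of[i]]
            if c.archetype.contacts[i - a, j - a]:
                cum = _vm_cumfreqs(c.kappa, spec)
                tgt = dec.target(int(cum[-1]))
                k = int(np.searchsorted(cum, tgt, side="right")) - 1
                dec.update(int(cum[k]), int(cum[k + 1]), int(cum[-1]))
                ang = wrap_angle(c.archetype.angles[i - a, j - a]
                                 + angle_bin_center(k, spec))
                angles[i, j] = angles[j, i] = ang
                continue
        k = dec.target(nb)
        dec.update(k, k + 1, nb)
        ang = angle_bin_center(k, spec)
        angles[i, j] = angles[j, i] = ang
    return Tableau(id=tableau_id, sse_string="".join(sse),
                   contacts=contacts, angles=angles)
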