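"""Tableau container and its plain-text serialization.

A tableau is the coded object of this package: the succession of secondary
structural elements (SSEs, helices ``H`` and strands ``E``) along a protein
chain, a symmetric boolean contact matrix over SSE pairs, and a symmetric
matrix of interaxial orientation angles in degrees, wrapped to (-180, 180].
Contacting pairs are the pairs whose geometry the codec transmits;
non-contacting angles are derived data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tableau", "wrap_angle", "read_tableau", "write_tableau",
           "read_tableau_file", "write_tableau_file"]

VALID_SSE = frozenset("HE")


def wrap_angle(x):
    """Wrap an angle in degrees onto (-180, 180]."""
    y = np.asarray(x, dtype=float)
    out = -((-y + 180.0) % 360.0 - 180.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


@dataclass
class Tableau:
    """Folding-pattern tableau over ``n`` secondary structural elements.

    Parameters
    ----------
    id : str
        Identifier (e.g. a domain or chain name).
    sse_string : str
        Sequence over ``{H, E}`` of length ``n``.
    contacts : (n, n) bool ndarray
        Symmetric contact matrix with a false diagonal.
    angles : (n, n) float ndarray
        Symmetric interaxial angles in degrees on (-180, 180]; defined for
        every off-diagonal pair, meaningful where ``contacts`` is true.
    """

    id: str
    sse_string: str
    contacts: np.ndarray = field(default=None)
    angles: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.sse_string)
        if self.contacts is None:
            self.contacts = np.zeros((n, n), dtype=bool)
        if self.angles is None:
            self.angles = np.zeros((n, n), dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=bool)
        self.angles = np.asarray(self.angles, dtype=float)
        self.validate()

    # -- basic protocol ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sse_string)

    def __len__(self) -> int:
        return self.n

    def validate(self):
        n = self.n
        if set(self.sse_string) - VALID_SSE:
            raise ValueError(
                f"tableau {self.id!r}: SSE string must be over {{H,E}}, "
                f"got {self.sse_string!r}")
        if self.contacts.shape != (n, n) or self.angles.shape != (n, n):
            raise ValueError(f"tableau {self.id!r}: matrix shape mismatch")
        if n and np.any(np.diag(self.contacts)):
            raise ValueError(f"tableau {self.id!r}: diagonal contact")
        if not np.array_equal(self.contacts, self.contacts.T):
            raise ValueError(f"tableau {self.id!r}: contacts not symmetric")
        if not np.allclose(self.angles, self.angles.T, atol=1e-9):
            raise ValueError(f"tableau {self.id!r}: angles not symmetric")
        off = ~np.eye(n, dtype=bool) if n else np.zeros((0, 0), bool)
        a = self.angles[off] if n else np.empty(0)
        if a.size and (np.any(a <= -180.0 - 1e-9) or np.any(a > 180.0 + 1e-9)):
            raise ValueError(f"tableau {self.id!r}: angle outside (-180, 180]")

    def subtableau(self, start: int, end: int, new_id: str | None = None) -> "Tableau":
        """Subtableau over 0-based SSE slice ``[start, end)``."""
        if not (0 <= start < end <= self.n):
            raise ValueError(f"bad span [{start}, {end}) for n={self.n}")
        sl = slice(start, end)
        return Tableau(
            id=new_id or f"{self.id}[{start + 1}-{end}]",
            sse_string=self.sse_string[sl],
            contacts=self.contacts[sl, sl].copy(),
            angles=self.angles[sl, sl].copy(),
        )

    def equals(self, other: "Tableau", angle_tol: float = 1e-9) -> bool:
        return (self.sse_string == other.sse_string
                and np.array_equal(self.contacts, other.contacts)
                and bool(np.all(np.abs(wrap_angle(self.angles - other.angles))
                                <= angle_tol)))

    def __eq__(self, other):
        if not isinstance(other, Tableau):
            return NotImplemented
        return self.id == other.id and self.equals(other)


# -- text format -----------------------------------------------------------
#
# Line 1:  "#TABLEAU <id> <n>"
# Line 2:  the SSE string (empty line when n == 0)
# Lines 3..n+2:  lower triangle, row i holding i-1 cells "angle/flag",
#                angle printed with 2 decimals, flag in {0,1}.
# Comment lines starting with "##" may precede the header and are ignored.

def write_tableau(t: Tableau) -> str:
    lines = [f"#TABLEAU {t.id} {t.n}", t.sse_string]
    for i in range(t.n):
        cells = [f"{t.angles[i, j]:.2f}/{int(t.contacts[i, j])}"
                 for j in range(i)]
        lines.append(" ".join(cells))
    return "\n".join(lines) + "\n"


def read_tableau(text) -> Tableau:
    raw = text.splitlines() if isinstance(text, str) else list(text)
    lines = [ln for ln in raw if not ln.startswith("##")]
    if not lines or not lines[0].startswith("#TABLEAU"):
        raise ValueError("not a tableau record: missing #TABLEAU header")
    header = lines[0].split()
    if len(header) != 3:
        raise ValueError(f"malformed tableau header: {lines[0]!r}")
    tid, n = header[1], int(header[2])
    if len(lines) < 2 + n:
        raise ValueError(f"tableau {tid!r}: expected {n} triangle rows")
    sse = lines[1].strip()
    if len(sse) != n:
        raise ValueError(f"tableau {tid!r}: SSE string length {len(sse)} != n={n}")
    contacts = np.zeros((n, n), dtype=bool)
    angles = np.zeros((n, n), dtype=float)
    for i in range(n):
        cells = lines[2 + i].split()
        if len(cells) != i:
            raise ValueError(
                f"tableau {tid!r}: row {i + 1} has {len(cells)} cells, expected {i}")
        for j, cell in enumerate(cells):
            try:
                a_s, f_s = cell.rsplit("/", 1)
                a, f = float(a_s), int(f_s)
            except ValueError as exc:
                raise ValueError(
                    f"tableau {tid!r}: bad cell {cell!r} at row {i + 1}") from exc
            angles[i, j] = angles[j, i] = a
            contacts[i, j] = contacts[j, i] = bool(f)
    return Tableau(id=tid, sse_string=sse, contacts=contacts, angles=angles)


def write_tableau_file(path, tableaux, header_comments=()):
    """Write one or more tableaux to ``path`` (concatenated records)."""
    if isinstance(tableaux, Tableau):
        tableaux = [tableaux]
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"## {c}\n")
        for t in tableaux:
            fh.write(write_tableau(t))


def read_tableau_file(path) -> list[Tableau]:
    with open(path) as fh:
        text = fh.read()
    records, cur = [], []
    for ln in text.splitlines():
        if ln.startswith("#TABLEAU") and cur:
            records.append(cur)
            cur = []
        cur.append(ln)
    if cur:
        records.append(cur)
    return [read_tableau(r) for r in records
            if any(ln.startswith("#TABLEAU") for ln in r)]
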