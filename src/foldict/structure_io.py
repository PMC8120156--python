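"""From protein coordinates to a tableau.

Reads PDB/mmCIF with gemmi, accepts externally assigned secondary
structure or assigns it from C-alpha geometry alone, fits a total
least-squares axis through each SSE's C-alpha trace, measures pairwise
interaxial dihedral angles about the mutual perpendicular, and calls two
SSEs in contact when any heavy-atom pair (one atom per residue, one
residue per SSE) lies closer than the sum of van der Waals radii plus a
small slack (default 1 A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tableau import Tableau, wrap_angle

__all__ = ["SSESegment", "Axis", "ChainModel", "Residue", "read_structure",
           "assign_sses", "fit_axis", "interaxial_angle", "sse_contact",
           "build_tableau", "read_sse_file", "VDW_RADII"]

# Bondi van der Waals radii (A); heavy atoms only, H excluded from contacts
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
FALLBACK_RADIUS = 1.70

# helix: d(i, i+3) window; strand: d(i, i+2) window (C-alpha only criteria)
HELIX_D13 = (4.7, 5.7)
STRAND_D02 = (6.0, 7.2)
MIN_LEN = {"H": 4, "E": 3}


@dataclass
class Residue:
    seq_id: int
    name: str
    atoms: list = field(default_factory=list)   # (atom_name, element, xyz)

    @property
    def ca(self):
        for name, _, xyz in self.atoms:
            if name == "CA":
                return np.asarray(xyz, dtype=float)
        return None

    def heavy_coords(self):
        out, radii = [], []
        for name, element, xyz in self.atoms:
            if element == "H":
                continue
            out.append(xyz)
            radii.append(VDW_RADII.get(element, None))
        return np.asarray(out, dtype=float).reshape(-1, 3), radii


@dataclass
class ChainModel:
    """Polymer residues of one chain, in sequence order."""

    chain_id: str
    residues: list = field(default_factory=list)

    def __len__(self):
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        cas = [r.ca for r in self.residues if r.ca is not None]
        return np.asarray(cas, dtype=float).reshape(-1, 3)


@dataclass
class SSESegment:
    """A helix or strand: 1-based inclusive residue span + C-alpha trace."""

    ordinal: int
    sse_type: str
    start_res: int
    end_res: int
    ca_coords: np.ndarray

    def __post_init__(self):
        if self.sse_type not in ("H", "E"):
            raise ValueError(f"sse_type must be H or E, got {self.sse_type!r}")
        if self.start_res > self.end_res:
            raise ValueError(f"segment span ({self.start_res}, {self.end_res}) "
                             "reversed")
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if len(self.ca_coords) < 3:
            raise ValueError("axis fit needs >= 3 C-alpha coordinates")


@dataclass
class Axis:
    """Directed least-squares line: centroid point and unit N->C direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")


# ---------------------------------------------------------------------------
# Reading coordinates
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str = "auto") -> dict:
    """Parse PDB/mmCIF into {chain_id: ChainModel} of polymer residues.

    First-listed altloc kept; waters and HETATM groups excluded.  Raises
    ValueError (with gemmi's line/record diagnostics) on unparsable input.
    """
    import gemmi
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    model = st[0]
    chains = {}
    for chain in model:
        cm = ChainModel(chain_id=chain.name)
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            seen = set()
            atoms = []
            for atom in res:
                if atom.name in seen:
                    continue              # keep first altloc only
                seen.add(atom.name)
                el = atom.element.name.upper()
                atoms.append((atom.name, el,
                              (atom.pos.x, atom.pos.y, atom.pos.z)))
            cm.residues.append(Residue(seq_id=res.seqid.num, name=res.name,
                                       atoms=atoms))
        chains[chain.name] = cm
    return chains


def read_sse_file(path) -> dict:
    """External SSE table: whitespace rows ``chain type start end``."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4 or parts[1] not in ("H", "E"):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"'chain type start end', got {line!r}")
            rows.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
    out: dict = {}
    for chain, typ, s, e in rows:
        out.setdefault(chain, []).append((typ, s, e))
    for chain, segs in out.items():
        segs.sort(key=lambda x: x[1])
        bad = [f"{t} {s} {e}" for (t, s, e), (t2, s2, e2)
               in zip(segs, segs[1:]) if e >= s2]
        if bad:
            raise ValueError(f"overlapping SSE rows in chain {chain}: "
                             + "; ".join(bad))
    return out


# ---------------------------------------------------------------------------
# Secondary-structure assignment
# ---------------------------------------------------------------------------

def _segments_from_spans(model: ChainModel, spans) -> list:
    by_seq = {r.seq_id: r for r in model.residues}
    segments = []
    for ordinal, (typ, s, e) in enumerate(spans, 1):
        cas = []
        for seq in range(s, e + 1):
            r = by_seq.get(seq)
            if r is not None and r.ca is not None:
                cas.append(r.ca)
        segments.append(SSESegment(ordinal=ordinal, sse_type=typ,
                                   start_res=s, end_res=e,
                                   ca_coords=np.asarray(cas)))
    return segments


def _runs(mask):
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def assign_sses(model: ChainModel, method: str = "ca_geometry",
                sse_spans=None) -> list:
    """Ordered, non-overlapping SSESegments for one chain.

    ``external_file`` passes through a validated span table (see
    :func:`read_sse_file`); ``ca_geometry`` applies C-alpha-only distance
    windows: residues in d(i,i+3) in [4.7, 5.7] A windows become helix,
    residues in d(i,i+2) in [6.0, 7.2] A windows become strand (helix wins
    conflicts), with minimum lengths H=4, E=3 residues.
    """
    if method == "external_file":
        if sse_spans is None:
            raise ValueError("method='external_file' requires sse_spans")
        spans = sorted(sse_spans, key=lambda x: x[1])
        for (t1, s1, e1), (t2, s2, e2) in zip(spans, spans[1:]):
            if e1 >= s2:
                raise ValueError(f"overlapping segments: {t1} {s1} {e1} and "
                                 f"{t2} {s2} {e2}")
        return _segments_from_spans(model, spans)
    if method != "ca_geometry":
        raise ValueError(f"unknown method {method!r}")
    resl = [r for r in model.residues if r.ca is not None]
    n = len(resl)
    if n < 5:
        raise ValueError("ca_geometry needs >= 5 consecutive C-alpha atoms")
    ca = np.asarray([r.ca for r in resl])
    seq = np.asarray([r.seq_id for r in resl])

    def contiguous(i, k):
        # window i..i+k must not bridge a numbering gap in the chain
        return seq[i + k] - seq[i] == k

    helix_mask = np.zeros(n, dtype=bool)
    strand_mask = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        d = np.linalg.norm(ca[i + 3] - ca[i])
        if contiguous(i, 3) and HELIX_D13[0] <= d <= HELIX_D13[1]:
            helix_mask[i:i + 4] = True
    for i in range(n - 2):
        d = np.linalg.norm(ca[i + 2] - ca[i])
        if contiguous(i, 2) and STRAND_D02[0] <= d <= STRAND_D02[1]:
            strand_mask[i:i + 3] = True
    strand_mask &= ~helix_mask      # helix precedence on conflict
    spans = []
    for typ, mask in (("H", helix_mask), ("E", strand_mask)):
        for a, b in _runs(mask):
            # split runs at residue-numbering gaps
            start = a
            for i in range(a, b):
                if seq[i + 1] - seq[i] != 1:
                    if i - start + 1 >= MIN_LEN[typ]:
                        spans.append((typ, resl[start].seq_id, resl[i].seq_id))
                    start = i + 1
            if b - start + 1 >= MIN_LEN[typ]:
                spans.append((typ, resl[start].seq_id, resl[b].seq_id))
    spans.sort(key=lambda x: x[1])
    return _segments_from_spans(model, spans)


# ---------------------------------------------------------------------------
# Axis fitting and interaxial angles
# ---------------------------------------------------------------------------

def fit_axis(segment: SSESegment) -> Axis:
    """Total-least-squares line through the C-alpha trace, oriented N->C."""
    pts = segment.ca_coords
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0, atol=1e-12):
        raise ValueError("degenerate geometry: all C-alpha points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    return Axis(point=centroid, direction=direction / np.linalg.norm(direction))


def _closest_points(a1: Axis, a2: Axis):
    """Feet of the common perpendicular between two non-parallel lines."""
    d1, d2 = a1.direction, a2.direction
    w0 = a1.point - a2.point
    aa, bb, cc = np.dot(d1, d1), np.dot(d1, d2), np.dot(d2, d2)
    dd, ee = np.dot(d1, w0), np.dot(d2, w0)
    den = aa * cc - bb * bb
    s = (bb * ee - cc * dd) / den
    u = (aa * ee - bb * dd) / den
    return a1.point + s * d1, a2.point + u * d2


def interaxial_angle(a1: Axis, a2: Axis) -> float:
    """Signed dihedral (degrees, (-180, 180]) between the planes spanned by
    each axis and the mutual perpendicular.

    Equivalent to the four-point torsion of (f1 - d1, f1, f2, f2 + d2)
    where f1, f2 are the feet of the common perpendicular.  Parallel axes
    give 0 (same direction) or 180 (antiparallel); coincident lines give 0
    with a degeneracy warning.
    """
    d1, d2 = a1.direction, a2.direction
    cr = np.cross(d1, d2)
    if np.linalg.norm(cr) < 1e-9:
        return 180.0 if np.dot(d1, d2) < 0 else 0.0
    f1, f2 = _closest_points(a1, a2)
    if np.linalg.norm(f2 - f1) < 1e-9:
        # intersecting lines: mutual perpendicular segment degenerates;
        # take its direction as the limit of the offset construction
        warnings.warn("interaxial_angle: axes intersect; using the common "
                      "perpendicular direction convention")
        f2 = f1 + cr / np.linalg.norm(cr)
    return wrap_angle(_torsion(f1 - d1, f1, f2, f2 + d2))


def _torsion(p0, p1, p2, p3) -> float:
    """IUPAC-sign torsion angle of four points, in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _segment_heavy(model: ChainModel, seg: SSESegment):
    coords, radii = [], []
    for r in model.residues:
        if seg.start_res <= r.seq_id <= seg.end_res:
            xyz, rr = r.heavy_coords()
            coords.extend(xyz)
            radii.extend(rr)
    out_r = []
    warned = False
    for rad in radii:
        if rad is None:
            if not warned:
                warnings.warn("unknown element in contact computation; using "
                              f"fallback van der Waals radius {FALLBACK_RADIUS} A")
                warned = True
            rad = FALLBACK_RADIUS
        out_r.append(rad)
    return np.asarray(coords, dtype=float).reshape(-1, 3), np.asarray(out_r)


def sse_contact(seg1: SSESegment, seg2: SSESegment, model: ChainModel,
                slack: float = 1.0) -> bool:
    """True iff any heavy-atom pair across the two segments is closer than
    the sum of the atoms' van der Waals radii plus ``slack``."""
    c1, r1 = _segment_heavy(model, seg1)
    c2, r2 = _segment_heavy(model, seg2)
    if not len(c1) or not len(c2):
        return False
    from scipy.spatial.distance import cdist
    d = cdist(c1, c2)
    thresh = r1[:, None] + r2[None, :] + slack
    return bool(np.any(d < thresh))


# ---------------------------------------------------------------------------
# Tableau construction
# ---------------------------------------------------------------------------

def build_tableau(model: ChainModel, segments: list, tableau_id: str = "",
                  slack: float = 1.0) -> Tableau:
    """Assemble the tableau: SSE string, interaxial angles for all pairs,
    contacts from the heavy-atom criterion."""
    segments = sorted(segments, key=lambda s: s.start_res)
    n = len(segments)
    sse = "".join(s.sse_type for s in segments)
    axes = [fit_axis(s) for s in segments]
    contacts = np.zeros((n, n), dtype=bool)
    angles = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a = interaxial_angle(axes[i], axes[j])
            angles[i, j] = angles[j, i] = a
            c = sse_contact(segments[i], segments[j], model, slack=slack)
            contacts[i, j] = contacts[j, i] = c
    return Tableau(id=tableau_id or model.chain_id, sse_string=sse,
                   contacts=contacts, angles=angles)
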