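"""Shared fixtures: random tableau/dictionary generators and tiny
synthetic coordinate sets (ideal helix / extended strand geometry)."""

from __future__ import annotations

import numpy as np
import pytest

from foldict.codec import CodeSpec
from foldict.synthetic import SynthParams, make_benchmark, random_tableau


@pytest.fixture
def spec():
    return CodeSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Random instances for oracle comparisons
# ---------------------------------------------------------------------------

def make_random_tableau(rng, spec, n_min=2, n_max=8, tableau_id="t"):
    params = SynthParams(n_tableaux=1, sse_range=(n_min, n_max),
                         plant_fraction=0.0, seed=0, spec=spec)
    return random_tableau(params, rng, tableau_id=tableau_id)


def make_random_dictionary(rng, spec, collection, max_concepts=4):
    """Extract up to max_concepts random valid candidates from a collection."""
    from foldict.synthetic import random_dictionary
    return random_dictionary(collection, rng, spec, max_concepts=max_concepts)


@pytest.fixture
def bench_small(spec):
    """A small planted-motif benchmark (fast; used across modules)."""
    params = SynthParams(n_tableaux=12, sse_range=(5, 8), seed=5, spec=spec)
    return make_benchmark(params)


# ---------------------------------------------------------------------------
# Synthetic coordinates
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # A


def helix_ca(n_res, origin=(0.0, 0.0, 0.0), axis_dir=(0.0, 0.0, 1.0)):
    """C-alpha trace of an ideal alpha helix whose axis is axis_dir."""
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_dir)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis_dir, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    pts = []
    for i in range(n_res):
        ang = np.radians(HELIX_TWIST * i)
        pts.append(np.asarray(origin)
                   + HELIX_RADIUS * (np.cos(ang) * u + np.sin(ang) * v)
                   + HELIX_RISE * i * axis_dir)
    return np.asarray(pts)


def strand_ca(n_res, origin=(0.0, 0.0, 0.0), axis_dir=(1.0, 0.0, 0.0),
              pleat_dir=(0.0, 1.0, 0.0)):
    """Extended-strand C-alpha trace: 3.4 A per residue with alternating
    0.95 A pleat, giving d(i, i+2) = 6.8 A."""
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    pleat = np.asarray(pleat_dir, float)
    pleat = pleat / np.linalg.norm(pleat)
    pts = [np.asarray(origin) + 3.4 * i * axis_dir
           + 0.95 * ((-1) ** i) * pleat for i in range(n_res)]
    return np.asarray(pts)


def pdb_text(ca_sets, chain="A", start_res=1, gap=4, element="C"):
    """Minimal PDB text with one CA atom per residue, one chain.

    ``ca_sets`` is a list of (n, 3) arrays; successive sets are separated
    by ``gap`` residue numbers (loop residues are simply absent).
    """
    lines = []
    serial = 1
    res = start_res
    for pts in ca_sets:
        for xyz in np.asarray(pts):
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{element:>2s}")
            serial += 1
            res += 1
        res += gap
    lines.append("END")
    return "\n".join(lines) + "\n"


def mmcif_text(ca_sets, chain="A", start_res=1, gap=4, element="C"):
    """The same content as :func:`pdb_text`, as a minimal mmCIF block."""
    header = """data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
"""
    rows = []
    serial = 1
    res = start_res
    for pts in ca_sets:
        for xyz in np.asarray(pts):
            x, y, z = xyz
            rows.append(f"ATOM {serial} {element} CA . ALA {chain} 1 {res} ? "
                        f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 {res} {chain}")
            serial += 1
            res += 1
        res += gap
    return header + "\n".join(rows) + "\n"
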