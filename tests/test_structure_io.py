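"""Coordinates-to-tableau pipeline: parsing, SSE assignment, axes, angles,
contacts, and rigid-motion invariance."""

import numpy as np
import pytest

from foldict.structure_io import (Axis, ChainModel, Residue, SSESegment,
                                  assign_sses, build_tableau, fit_axis,
                                  interaxial_angle, read_structure,
                                  sse_contact)
from foldict.tableau import wrap_angle

from conftest import helix_ca, mmcif_text, pdb_text, strand_ca


def _chain_from_ca(ca_sets, gap=4, element="C"):
    model = ChainModel(chain_id="A")
    res = 1
    for pts in ca_sets:
        for xyz in np.asarray(pts):
            model.residues.append(
                Residue(seq_id=res, name="ALA",
                        atoms=[("CA", element, tuple(xyz))]))
            res += 1
        res += gap
    return model


# ---------------------------------------------------------------------------
# Reading coordinates
# ---------------------------------------------------------------------------

def test_read_pdb_echoes_coordinates(tmp_path):
    pts = [np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])]
    p = tmp_path / "two.pdb"
    p.write_text(pdb_text(pts))
    chains = read_structure(p, fmt="pdb")
    model = chains["A"]
    assert len(model) == 2
    assert np.allclose(model.ca_coords(), pts[0])


def test_mmcif_gives_identical_model(tmp_path):
    pts = [helix_ca(6)]
    p1 = tmp_path / "fix.pdb"
    p2 = tmp_path / "fix.cif"
    p1.write_text(pdb_text(pts))
    p2.write_text(mmcif_text(pts))
    m1 = read_structure(p1, fmt="pdb")["A"]
    m2 = read_structure(p2, fmt="mmcif")["A"]
    assert [r.seq_id for r in m1.residues] == [r.seq_id for r in m2.residues]
    assert np.allclose(m1.ca_coords(), m2.ca_coords(), atol=1e-3)


def test_hetatm_only_file_gives_empty_model(tmp_path):
    text = ("HETATM    1  C1  LIG A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n")
    p = tmp_path / "het.pdb"
    p.write_text(text)
    chains = read_structure(p, fmt="pdb")
    assert all(len(m) == 0 for m in chains.values())


def test_unreadable_file_raises_parse_error(tmp_path):
    p = tmp_path / "bad.cif"
    p.write_text("this is not cif {{{{\n")
    with pytest.raises(ValueError, match="cannot parse"):
        read_structure(p, fmt="mmcif")


# ---------------------------------------------------------------------------
# SSE assignment
# ---------------------------------------------------------------------------

def test_external_file_segments_pass_through():
    model = _chain_from_ca([helix_ca(30)], gap=0)
    segs = assign_sses(model, "external_file",
                       sse_spans=[("H", 5, 17), ("E", 22, 27)])
    assert [(s.sse_type, s.start_res, s.end_res) for s in segs] == \
        [("H", 5, 17), ("E", 22, 27)]


def test_external_file_rejects_overlap():
    model = _chain_from_ca([helix_ca(30)], gap=0)
    with pytest.raises(ValueError, match="overlap"):
        assign_sses(model, "external_file",
                    sse_spans=[("H", 5, 17), ("E", 15, 20)])


def test_ca_geometry_finds_ideal_helix():
    model = _chain_from_ca([helix_ca(12)])
    segs = assign_sses(model, "ca_geometry")
    assert len(segs) == 1
    assert segs[0].sse_type == "H"
    assert segs[0].end_res - segs[0].start_res + 1 >= 8


def test_ca_geometry_finds_extended_strand():
    model = _chain_from_ca([strand_ca(10)])
    segs = assign_sses(model, "ca_geometry")
    assert len(segs) == 1
    assert segs[0].sse_type == "E"


# ---------------------------------------------------------------------------
# Axis fitting
# ---------------------------------------------------------------------------

def test_fit_axis_exact_line():
    seg = SSESegment(1, "E", 1, 3,
                     ca_coords=[(0, 0, 0), (0, 0, 1), (0, 0, 2)])
    ax = fit_axis(seg)
    assert np.allclose(ax.direction, [0, 0, 1])
    assert np.allclose(ax.point, [0, 0, 1])


def test_fit_axis_orientation_follows_chain_direction():
    seg = SSESegment(1, "E", 1, 3,
                     ca_coords=[(0, 0, 2), (0, 0, 1), (0, 0, 0)])
    assert np.allclose(fit_axis(seg).direction, [0, 0, -1])


def test_fit_axis_recovers_helix_generation_axis():
    for axis_dir in ([0, 0, 1], [1, 1, 0], [0.3, -0.5, 0.8]):
        d = np.asarray(axis_dir, float)
        d /= np.linalg.norm(d)
        seg = SSESegment(1, "H", 1, 12, ca_coords=helix_ca(12, axis_dir=d))
        got = fit_axis(seg).direction
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(got, d)), -1, 1)))
        assert ang < 5.0


def test_fit_axis_rejects_coincident_points():
    seg = SSESegment(1, "H", 1, 3,
                     ca_coords=[(1, 1, 1)] * 3)
    with pytest.raises(ValueError, match="degenerate"):
        fit_axis(seg)


# ---------------------------------------------------------------------------
# Interaxial angles
# ---------------------------------------------------------------------------

def _axis(point, direction):
    d = np.asarray(direction, float)
    return Axis(point=np.asarray(point, float), direction=d / np.linalg.norm(d))


def test_parallel_offset_axes_give_zero():
    assert interaxial_angle(_axis([0, 0, 0], [0, 0, 1]),
                            _axis([1, 0, 0], [0, 0, 1])) == 0.0


def test_antiparallel_axes_give_180():
    assert interaxial_angle(_axis([0, 0, 0], [0, 0, 1]),
                            _axis([1, 0, 0], [0, 0, -1])) == 180.0


def _four_point_dihedral(p0, p1, p2, p3):
    """Independent four-point torsion (praxeolitic formula)."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


def test_orthogonal_axes_match_four_point_dihedral():
    a1 = _axis([0, 0, 0], [0, 0, 1])
    a2 = _axis([1, 0, 0], [0, 1, 0])
    got = interaxial_angle(a1, a2)
    assert abs(abs(got) - 90.0) < 1e-9
    # the independent oracle: feet of the common perpendicular are the
    # origin and (1,0,0); torsion of (f1 - d1, f1, f2, f2 + d2)
    expected = _four_point_dihedral([0, 0, -1], [0, 0, 0], [1, 0, 0],
                                    [1, 1, 0])
    assert np.isclose(got, wrap_angle(expected), atol=1e-9)


def test_random_axes_match_four_point_dihedral():
    rng = np.random.default_rng(12)
    for _ in range(50):
        p1, p2 = rng.normal(size=3), rng.normal(size=3)
        d1, d2 = rng.normal(size=3), rng.normal(size=3)
        if np.linalg.norm(np.cross(d1, d2)) < 1e-6:
            continue
        a1, a2 = _axis(p1, d1), _axis(p2, d2)
        got = interaxial_angle(a1, a2)
        from foldict.structure_io import _closest_points
        f1, f2 = _closest_points(a1, a2)
        if np.linalg.norm(f2 - f1) < 1e-9:
            continue
        expected = _four_point_dihedral(f1 - a1.direction, f1, f2,
                                        f2 + a2.direction)
        assert np.isclose(wrap_angle(got - expected), 0.0, atol=1e-6)


def test_reversing_one_axis_shifts_angle_by_180():
    rng = np.random.default_rng(13)
    for _ in range(20):
        a1 = _axis(rng.normal(size=3), rng.normal(size=3))
        a2 = _axis(rng.normal(size=3), rng.normal(size=3))
        if np.linalg.norm(np.cross(a1.direction, a2.direction)) < 1e-6:
            continue
        ang = interaxial_angle(a1, a2)
        flipped = interaxial_angle(a1, Axis(point=a2.point,
                                            direction=-a2.direction))
        assert np.isclose(abs(wrap_angle(ang - flipped)), 180.0, atol=1e-6)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _two_atom_model(distance):
    model = ChainModel(chain_id="A")
    model.residues = [
        Residue(seq_id=1, name="ALA", atoms=[("CA", "C", (0.0, 0.0, 0.0))]),
        Residue(seq_id=5, name="ALA", atoms=[("CA", "C", (distance, 0.0, 0.0))]),
    ]
    return model


def _point_segment(res, xyz):
    # 3 coincident-free CAs just to satisfy the axis invariant; contacts only
    # use residue span membership
    return SSESegment(res, "H", res, res,
                      ca_coords=[xyz, np.add(xyz, [0, 0, 1]),
                                 np.add(xyz, [0, 0, 2])])


@pytest.mark.parametrize("distance,expected", [(5.0, False), (4.3, True)])
def test_carbon_contact_threshold(distance, expected):
    """C..C threshold is 1.7 + 1.7 + 1.0 = 4.4 A."""
    model = _two_atom_model(distance)
    s1 = _point_segment(1, (0.0, 0.0, 0.0))
    s2 = _point_segment(5, (distance, 0.0, 0.0))
    assert sse_contact(s1, s2, model) is expected


def test_unknown_element_warns_and_uses_fallback():
    model = _two_atom_model(4.3)
    model.residues[0].atoms = [("XX", "Q", (0.0, 0.0, 0.0))]
    s1 = _point_segment(1, (0.0, 0.0, 0.0))
    s2 = _point_segment(5, (4.3, 0.0, 0.0))
    with pytest.warns(UserWarning, match="fallback"):
        assert sse_contact(s1, s2, model) is True


def test_contact_equals_brute_force_atom_scan():
    """Contact decisions on a 3-SSE fixture equal an O(atoms^2) scan."""
    rng = np.random.default_rng(14)
    sets = [helix_ca(8, origin=(0, 0, 0)),
            strand_ca(6, origin=(4.0, 2.0, 0.0), axis_dir=(0, 0, 1)),
            helix_ca(8, origin=(40.0, 0, 0))]
    model = _chain_from_ca(sets)
    segs = []
    res = 1
    for pts in sets:
        segs.append(SSESegment(len(segs) + 1, "H", res, res + len(pts) - 1,
                               ca_coords=pts))
        res += len(pts) + 4
    for i in range(3):
        for j in range(i + 1, 3):
            # brute force: all CA pairs, carbon radii
            d = np.linalg.norm(sets[i][:, None, :] - sets[j][None, :, :],
                               axis=-1)
            expected = bool((d < 1.7 + 1.7 + 1.0).any())
            assert sse_contact(segs[i], segs[j], model) is expected


# ---------------------------------------------------------------------------
# Tableau construction and invariances
# ---------------------------------------------------------------------------

def _three_sse_fixture():
    sets = [helix_ca(10, origin=(0, 0, 0), axis_dir=(0, 0, 1)),
            helix_ca(10, origin=(6.0, 0, 0), axis_dir=(0, 1, 0)),
            helix_ca(10, origin=(9.0, 6.0, 3.0), axis_dir=(1, 0, 0))]
    model = _chain_from_ca(sets)
    segs = assign_sses(model, "external_file",
                       sse_spans=[("H", 1, 10), ("H", 15, 24), ("H", 29, 38)])
    return model, segs


def test_build_tableau_empty_and_orthogonal_geometry():
    model, segs = _three_sse_fixture()
    t0 = build_tableau(model, [], tableau_id="empty")
    assert t0.n == 0
    t = build_tableau(model, segs, tableau_id="toy")
    assert t.sse_string == "HHH"
    assert bool(t.contacts[0, 1]) and bool(t.contacts[1, 2])
    assert not t.contacts[0, 2]
    assert np.isclose(abs(t.angles[0, 1]), 90.0, atol=2.0)
    assert np.isclose(abs(t.angles[1, 2]), 90.0, atol=2.0)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _transform_model(model, R, shift):
    out = ChainModel(chain_id=model.chain_id)
    for r in model.residues:
        atoms = [(n, e, tuple(R @ np.asarray(xyz) + shift))
                 for n, e, xyz in r.atoms]
        out.residues.append(Residue(seq_id=r.seq_id, name=r.name, atoms=atoms))
    return out


def test_rigid_motion_invariance():
    model, segs = _three_sse_fixture()
    ref = build_tableau(model, segs, tableau_id="ref")
    rng = np.random.default_rng(15)
    for _ in range(5):
        R = _random_rotation(rng)
        shift = rng.normal(scale=30.0, size=3)
        m2 = _transform_model(model, R, shift)
        segs2 = assign_sses(m2, "external_file",
                            sse_spans=[("H", 1, 10), ("H", 15, 24),
                                       ("H", 29, 38)])
        t2 = build_tableau(m2, segs2, tableau_id="moved")
        assert np.array_equal(t2.contacts, ref.contacts)
        iu = np.triu_indices(ref.n, 1)
        assert np.max(np.abs(wrap_angle(t2.angles[iu] - ref.angles[iu]))) < 1e-6


def test_reversing_segment_order_flips_its_angles_by_180():
    model, segs = _three_sse_fixture()
    ref = build_tableau(model, segs, tableau_id="ref")
    rev = [SSESegment(s.ordinal, s.sse_type, s.start_res, s.end_res,
                      ca_coords=s.ca_coords[::-1]) if s.ordinal == 2 else s
           for s in segs]
    t2 = build_tableau(model, rev, tableau_id="rev")
    for j in (0, 2):
        assert np.isclose(abs(wrap_angle(t2.angles[1, j] - ref.angles[1, j])),
                          180.0, atol=1e-6)
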