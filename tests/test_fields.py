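"""Grid fields: closed-form checks and brute-force oracle equivalence."""

import numpy as np
import pytest

from fragqsar.fields import (
    COULOMB_CONSTANT,
    LJ_TABLE,
    FieldBlock,
    GridSpec,
    ProbeParams,
    UnsupportedElementError,
    build_descriptor_matrix,
    electrostatic_field,
    make_grid,
    steric_field,
    write_cube,
)
from fragqsar.align import topomer_pose
from rdkit import Chem

PROBE = ProbeParams()


def brute_force_fields(frag, grid, probe):
    """Naive per-point / per-atom double loop, independent of the engine."""
    pts = grid.points()
    elements = np.array(frag.elements)[frag.field_mask]
    xyz = frag.coords[frag.field_mask]
    q = frag.charges[frag.field_mask]
    ster = np.empty(len(pts))
    elec = np.empty(len(pts))
    for ip, p in enumerate(pts):
        s = 0.0
        e = 0.0
        for el, a, qa in zip(elements, xyz, q):
            d = float(np.linalg.norm(p - a))
            r, eps = LJ_TABLE[el]
            rmin = r + probe.lj_rmin
            epsij = np.sqrt(eps * probe.lj_epsilon)
            if d == 0:
                s = np.inf
                if qa != 0:
                    e += np.sign(qa * probe.probe_charge) * np.inf
            else:
                s += epsij * ((rmin / d) ** 12 - 2 * (rmin / d) ** 6)
                e += COULOMB_CONSTANT * qa * probe.probe_charge / d**2
        ster[ip] = min(s, probe.clamp)
        elec[ip] = np.sign(e) * min(abs(e), probe.clamp)
    return ster, elec


class TestGrid:
    def test_single_atom_default_padding(self, stub_fragment_factory):
        f = stub_fragment_factory([[0, 0, 0]], ["C"], [0.0])
        g = make_grid([f], spacing=2.0, padding=4.0)
        assert g.dims == (5, 5, 5)
        assert g.origin == (-4.0, -4.0, -4.0)

    def test_order_invariance(self, stub_fragment_factory):
        a = stub_fragment_factory([[0, 0, 0]], ["C"], [0.0])
        b = stub_fragment_factory([[3, 1, -2]], ["O"], [0.0])
        assert make_grid([a, b]) == make_grid([b, a])

    def test_interior_fragment_does_not_grow_grid(self, stub_fragment_factory):
        a = stub_fragment_factory([[0, 0, 0], [4, 4, 4]], ["C", "C"], [0, 0])
        inner = stub_fragment_factory([[2, 2, 2]], ["C"], [0.0])
        assert make_grid([a]) == make_grid([a, inner])

    def test_lattice_points_index_major(self):
        g = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))
        pts = g.points()
        assert np.array_equal(pts[0], [0, 0, 0])
        assert np.array_equal(pts[1], [0, 0, 1])  # k fastest
        assert np.array_equal(pts[-1], [1, 1, 1])

    def test_empty_and_invalid_inputs(self, stub_fragment_factory):
        with pytest.raises(ValueError):
            make_grid([])
        f = stub_fragment_factory([[0, 0, 0]], ["C"], [0.0])
        with pytest.raises(ValueError):
            make_grid([f], spacing=0)


class TestSteric:
    def test_lj_minimum_is_minus_epsilon(self, stub_fragment_factory):
        rmin = LJ_TABLE["C"][0] + PROBE.lj_rmin
        f = stub_fragment_factory([[0, 0, 0]], ["C"], [0.0])
        g = GridSpec(origin=(rmin, 0, 0), spacing=1.0, dims=(1, 1, 1))
        v = steric_field(f, g, PROBE)
        eps = np.sqrt(LJ_TABLE["C"][1] * PROBE.lj_epsilon)
        assert v[0] == pytest.approx(-eps, rel=1e-12)

    def test_far_field_negligible(self, stub_fragment_factory):
        f = stub_fragment_factory([[0, 0, 0]], ["C"], [0.0])
        g = GridSpec(origin=(20, 0, 0), spacing=1.0, dims=(1, 1, 1))
        assert abs(steric_field(f, g, PROBE)[0]) < 1e-3

    def test_atom_center_clamped(self, stub_fragment_factory):
        f = stub_fragment_factory([[0, 0, 0]], ["C"], [0.0])
        g = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(1, 1, 1))
        assert steric_field(f, g, PROBE)[0] == PROBE.clamp

    def test_unknown_element_rejected(self, stub_fragment_factory):
        f = stub_fragment_factory([[0, 0, 0]], ["Se"], [0.0])
        g = GridSpec(origin=(2, 0, 0), spacing=1.0, dims=(1, 1, 1))
        with pytest.raises(UnsupportedElementError):
            steric_field(f, g, PROBE)


class TestElectrostatic:
    def test_zero_charges_zero_field(self, stub_fragment_factory):
        f = stub_fragment_factory([[0, 0, 0], [1, 0, 0]], ["C", "O"], [0.0, 0.0])
        g = GridSpec(origin=(-2, -2, -2), spacing=2.0, dims=(3, 3, 3))
        assert np.all(electrostatic_field(f, g, PROBE) == 0)

    def test_point_charge_arithmetic(self, stub_fragment_factory):
        # q=0.1 at 10 Å with a +1 probe and ε=d: 332·0.1/100 = 0.332
        f = stub_fragment_factory([[0, 0, 0]], ["C"], [0.1])
        g = GridSpec(origin=(10, 0, 0), spacing=1.0, dims=(1, 1, 1))
        assert electrostatic_field(f, g, PROBE)[0] == pytest.approx(0.332, rel=1e-12)

    def test_sign_flip_linearity(self, stub_fragment_factory):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(4, 3))
        q = rng.normal(scale=0.2, size=4)
        g = GridSpec(origin=(-4, -4, -4), spacing=2.0, dims=(4, 4, 4))
        a = electrostatic_field(stub_fragment_factory(xyz, ["C"] * 4, q), g, PROBE)
        b = electrostatic_field(stub_fragment_factory(xyz, ["C"] * 4, -q), g, PROBE)
        assert np.allclose(a, -b, atol=1e-12)


class TestOracle:
    @pytest.mark.parametrize("smi", ["O[*:2]", "CO[*:2]", "CC(=O)O[*:2]"])
    def test_matches_brute_force_on_toy_grids(self, smi):
        pose = topomer_pose(Chem.MolFromSmiles(smi))
        g = GridSpec(origin=(-4, -4, -4), spacing=2.0, dims=(6, 6, 6))
        ster_o, elec_o = brute_force_fields(pose, g, PROBE)
        ster = steric_field(pose, g, PROBE)
        elec = electrostatic_field(pose, g, PROBE)
        assert np.allclose(ster, ster_o, rtol=1e-9, atol=1e-12)
        assert np.allclose(elec, elec_o, rtol=1e-9, atol=1e-12)


@pytest.fixture(scope="module")
def toy_series():
    poses = {
        "oh": topomer_pose(Chem.MolFromSmiles("O[*:2]")),
        "ome": topomer_pose(Chem.MolFromSmiles("CO[*:2]")),
        "me": topomer_pose(Chem.MolFromSmiles("C[*:1]")),
        "et": topomer_pose(Chem.MolFromSmiles("CC[*:1]")),
    }
    series = [
        {"R1": poses["me"], "R2": poses["oh"]},
        {"R1": poses["et"], "R2": poses["ome"]},
        {"R1": poses["me"], "R2": poses["oh"]},
    ]
    grids = {
        "R1": make_grid([poses["me"], poses["et"]]),
        "R2": make_grid([poses["oh"], poses["ome"]]),
    }
    return series, grids


class TestMatrixAssembly:
    def test_identical_compounds_identical_rows(self, toy_series):
        series, grids = toy_series
        X, _ = build_descriptor_matrix(series, grids)
        assert np.array_equal(X[0], X[2])

    def test_column_layout(self, toy_series):
        series, grids = toy_series
        X, meta = build_descriptor_matrix(series, grids)
        n1, n2 = grids["R1"].n_points, grids["R2"].n_points
        assert X.shape == (3, 2 * (n1 + n2))
        assert meta[0] == ("R1", "steric", 0)
        assert meta[n1] == ("R1", "electrostatic", 0)
        assert meta[2 * n1] == ("R2", "steric", 0)
        kinds = [m[1] for m in meta]
        assert kinds.count("steric") == kinds.count("electrostatic") == n1 + n2

    def test_values_clamped(self, toy_series):
        series, grids = toy_series
        X, _ = build_descriptor_matrix(series, grids)
        assert np.abs(X).max() <= PROBE.clamp + 1e-12

    def test_missing_fragment_reported(self, toy_series):
        series, grids = toy_series
        broken = [dict(series[0]), {"R1": series[1]["R1"]}]
        with pytest.raises(ValueError, match="R2"):
            build_descriptor_matrix(broken, grids)

    def test_inside_mask_imputed_with_column_mean(self, stub_fragment_factory):
        # one compound's atom sits on a lattice point (clamped), the other's
        # does not; the clamped electrostatic entry takes the column mean
        near = stub_fragment_factory([[0.0, 0.0, 0.0]], ["C"], [0.2])
        far = stub_fragment_factory([[5.0, 0.0, 0.0]], ["C"], [0.2])
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(1, 1, 1))
        series = [{"R1": near, "R2": near}, {"R1": far, "R2": far}]
        X, meta = build_descriptor_matrix(series, {"R1": grid, "R2": grid})
        j = next(i for i, m in enumerate(meta) if m == ("R1", "electrostatic", 0))
        assert X[0, j] == pytest.approx(X[1, j])


def test_cube_roundtrip_header(tmp_path):
    g = GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 3, 4))
    vals = np.arange(24, dtype=float)
    path = tmp_path / "f.cube"
    write_cube(path, vals, g, comment="test field")
    lines = path.read_text().splitlines()
    assert lines[0] == "test field"
    assert int(lines[3].split()[0]) == 2  # nx
    flat = [float(x) for ln in lines[6:] for x in ln.split()]
    assert flat == pytest.approx(list(vals))
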