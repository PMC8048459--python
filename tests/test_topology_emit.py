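import numpy as np
import pytest

from xlinkforge import topology_emit as te
from xlinkforge.bonded_params import AngleTerm, BondTerm, ParameterSet
from xlinkforge.qm_io import AtomRecord, MoleculeGeometry


def _chain_geometry(names=("A", "B", "C", "D")):
    atoms = [
        AtomRecord(index=i + 1, name=n, element="C", mass=12.011)
        for i, n in enumerate(names)
    ]
    coords = np.array([[0.15 * i, 0.0, 0.0] for i in range(len(names))])
    return MoleculeGeometry(atoms=atoms, coords=coords)


def _toy_topology(q_a=0.25, q_b=-0.25, b0=0.153):
    res_a = te.ResidueTemplate(name="XLA", atoms=[("A", "C", q_a), ("B", "C", 0.0)],
                               bonds=[("A", "B")])
    res_b = te.ResidueTemplate(name="XLB", atoms=[("C", "C", q_b), ("D", "C", 0.0)],
                               bonds=[("C", "D")])
    conn = [te.ConnectionBond(atom_a="B", atom_b="C", b0=b0, k_b=250000.0)]
    return te.CrosslinkTopology(residue_a=res_a, residue_b=res_b, connection_bonds=conn)


class TestSplitCrosslink:
    def test_four_atom_chain(self):
        geom = _chain_geometry()
        bonds = [("A", "B"), ("B", "C"), ("C", "D")]
        res_a, res_b, conn = te.split_crosslink(geom, [("B", "C")], bonds=bonds)
        assert res_a.atom_names() == {"A", "B"}
        assert res_b.atom_names() == {"C", "D"}
        assert conn == [("B", "C")]

    def test_boundary_not_a_bond(self):
        geom = _chain_geometry()
        bonds = [("A", "B"), ("B", "C"), ("C", "D")]
        with pytest.raises(te.TopologyError, match="not an existing bond"):
            te.split_crosslink(geom, [("A", "D")], bonds=bonds)

    def test_bad_split_lists_components(self):
        geom = _chain_geometry()
        bonds = [("A", "B"), ("B", "C"), ("C", "D")]
        with pytest.raises(te.TopologyError, match="3 components"):
            te.split_crosslink(geom, [("A", "B"), ("C", "D")], bonds=bonds)

    def test_crosslink_fixture_partition(self, crosslink_fixture):
        fx = crosslink_fixture
        res_a, res_b, conn = te.split_crosslink(
            fx.geometry, fx.boundary, bonds=fx.bonds,
            cap_atoms=fx.cap_atoms, charges=fx.charges,
        )
        lys_side, arg_side = fx.partition
        assert res_a.atom_names() == lys_side
        assert res_b.atom_names() == arg_side
        assert {"HN", "N"} <= res_a.atom_names()
        assert {"ND4", "ND5"} <= res_b.atom_names()
        # caps are excluded from both residues
        for cap in fx.cap_atoms:
            assert cap not in res_a.atom_names() | res_b.atom_names()
        # split + caps partition the atom set exactly
        all_names = set(fx.geometry.atom_names())
        assert res_a.atom_names() | res_b.atom_names() | set(fx.cap_atoms) == all_names

    def test_infer_bond_graph_by_covalent_distance(self):
        atoms = [
            AtomRecord(index=1, name="C1", element="C", mass=12.0),
            AtomRecord(index=2, name="C2", element="C", mass=12.0),
            AtomRecord(index=3, name="C3", element="C", mass=12.0),
        ]
        geom = MoleculeGeometry(
            atoms=atoms, coords=np.array([[0, 0, 0], [0.15, 0, 0], [0.9, 0, 0.0]])
        )
        assert te.infer_bond_graph(geom) == [("C1", "C2")]


class TestCheckNetCharge:
    def test_zero_sum_passes(self):
        report = te.check_net_charge(_toy_topology())
        assert report.passed
        assert report.total_charge == pytest.approx(0.0, abs=1e-12)

    def test_excess_reported(self):
        report = te.check_net_charge(_toy_topology(q_a=0.251))
        assert not report.passed
        assert report.total_charge == pytest.approx(0.001, abs=1e-9)

    def test_missing_charge_names_atom(self):
        topo = _toy_topology()
        topo.residue_a.atoms[1] = ("B", "C", None)
        with pytest.raises(te.TopologyError, match="B"):
            te.check_net_charge(topo)

    def test_generated_fixture_charges_pass(self, crosslink_fixture):
        fx = crosslink_fixture
        res_a, res_b, conn = te.split_crosslink(
            fx.geometry, fx.boundary, bonds=fx.bonds,
            cap_atoms=fx.cap_atoms, charges=fx.charges,
        )
        cap_charge = sum(fx.charges[c] for c in fx.cap_atoms)
        # fixture charges sum to zero over ALL atoms; shift the cap share
        # onto residue A so the emitted two-residue system is neutral
        name0 = res_a.atoms[0][0]
        res_a.atoms[0] = (name0, res_a.atoms[0][1], res_a.atoms[0][2] + cap_charge)
        topo = te.CrosslinkTopology(
            residue_a=res_a, residue_b=res_b,
            connection_bonds=[te.ConnectionBond(a, b, b0=0.153) for a, b in conn],
        )
        assert te.check_net_charge(topo).passed


class TestWriters:
    def test_residue_entries_roundtrip(self, tmp_path):
        topo = _toy_topology()
        path = tmp_path / "residues.rtp"
        te.write_residue_entries(topo, path)
        back = te.read_residue_entries(path)
        assert [t.name for t in back] == ["XLA", "XLB"]
        assert back[0].atoms == [("A", "C", 0.25), ("B", "C", 0.0)]
        assert back[0].bonds == [("A", "B")]

    def test_residue_entries_two_headers(self, tmp_path):
        path = tmp_path / "residues.rtp"
        te.write_residue_entries(_toy_topology(), path)
        headers = [
            ln for ln in path.read_text().splitlines()
            if ln.startswith("[") and ln.strip("[] ").strip() not in ("atoms", "bonds")
        ]
        assert len(headers) == 2

    def test_empty_residue_refused(self, tmp_path):
        topo = _toy_topology()
        topo.residue_a.atoms = []
        with pytest.raises(te.TopologyError, match="empty"):
            te.write_residue_entries(topo, tmp_path / "x.rtp")

    def test_nonzero_charge_refused(self, tmp_path):
        topo = _toy_topology(q_a=0.3)
        with pytest.raises(te.TopologyError, match="net charge"):
            te.write_residue_entries(topo, tmp_path / "x.rtp")

    def test_writers_deterministic(self, tmp_path):
        p1, p2 = tmp_path / "a.rtp", tmp_path / "b.rtp"
        te.write_residue_entries(_toy_topology(), p1)
        te.write_residue_entries(_toy_topology(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_specbond_single_line(self, tmp_path):
        path = tmp_path / "specbond.dat"
        te.write_specbond(_toy_topology(b0=0.153), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "1"
        assert "0.153" in lines[1]
        records = te.read_specbond(path)
        assert records[0]["length"] == pytest.approx(0.153)
        assert records[0]["atom_a"] == "B" and records[0]["atom_b"] == "C"

    def test_specbond_without_connections_refused(self, tmp_path):
        topo = _toy_topology()
        topo.connection_bonds = []
        with pytest.raises(te.TopologyError, match="no connection bonds"):
            te.write_specbond(topo, tmp_path / "sb.dat")

    def test_specbond_two_bonds_canonical_order(self, tmp_path):
        topo = _toy_topology()
        topo.connection_bonds = [
            te.ConnectionBond(atom_a="B", atom_b="C", b0=0.2),
            te.ConnectionBond(atom_a="A", atom_b="D", b0=0.3),
        ]
        path = tmp_path / "sb.dat"
        te.write_specbond(topo, path)
        records = te.read_specbond(path)
        assert [r["atom_a"] for r in records] == ["A", "B"]

    def test_bonded_parameters_roundtrip(self, tmp_path):
        pset = ParameterSet(
            bonds=[BondTerm(1, 2, k_b=123456.789012345, b0=0.1234567890123)],
            angles=[AngleTerm(1, 2, 3, k_theta=345.678901234567, theta0=109.4712345)],
        )
        path = tmp_path / "bonded.itp"
        te.write_bonded_parameters(pset, path)
        back = te.read_bonded_parameters(path)
        assert back.bonds[0].k_b == pytest.approx(pset.bonds[0].k_b, rel=1e-10)
        assert back.bonds[0].b0 == pytest.approx(pset.bonds[0].b0, rel=1e-10)
        assert back.angles[0].k_theta == pytest.approx(pset.angles[0].k_theta, rel=1e-10)
        assert back.angles[0].theta0 == pytest.approx(pset.angles[0].theta0, rel=1e-10)

    def test_bonded_parameters_sections_present(self, tmp_path):
        pset = ParameterSet(
            bonds=[BondTerm(1, 2, k_b=1000.0, b0=0.1)],
            angles=[AngleTerm(1, 2, 3, k_theta=300.0, theta0=104.5)],
        )
        path = tmp_path / "bonded.itp"
        te.write_bonded_parameters(pset, path)
        text = path.read_text()
        assert "[ bondtypes ]" in text and "[ angletypes ]" in text

    def test_empty_parameter_set_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            te.write_bonded_parameters(ParameterSet(), tmp_path / "e.itp")


class TestTopologyInvariants:
    def test_connection_bond_must_span_residues(self):
        res_a = te.ResidueTemplate(name="XLA", atoms=[("A", "C", 0.0), ("B", "C", 0.0)])
        res_b = te.ResidueTemplate(name="XLB", atoms=[("C", "C", 0.0)])
        with pytest.raises(te.TopologyError, match="join"):
            te.CrosslinkTopology(
                residue_a=res_a, residue_b=res_b,
                connection_bonds=[te.ConnectionBond("A", "B", b0=0.15)],
            )

    def test_duplicate_atom_names_rejected(self):
        with pytest.raises(te.TopologyError, match="duplicate"):
            te.ResidueTemplate(name="X", atoms=[("A", "C", 0.0), ("A", "C", 0.0)])

    def test_bond_endpoint_must_exist(self):
        with pytest.raises(te.TopologyError, match="missing atom"):
            te.ResidueTemplate(name="X", atoms=[("A", "C", 0.0)], bonds=[("A", "Z")])
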