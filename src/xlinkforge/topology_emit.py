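"""Cross-link partitioning into two residue templates and force-field emission.

A cross-link spans two peptide chains, so the single QM molecule must be
split into two residue entries joined by explicit inter-residue bond
records. The split removes a declared list of boundary bonds from the
molecular bond graph and requires exactly two connected components; capping
atoms (the methyl caps present only for charge fitting) belong to neither
residue. The two templates must carry a combined net charge of zero.

Writers emit deterministic text in the residue-template (.rtp-style),
special-bond (specbond.dat-style) and bonded-parameter (.itp-style)
dialects, each with a paired reader for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import COVALENT_RADII_NM
from .bonded_params import AngleTerm, BondTerm, ParameterSet
from .qm_io import MoleculeGeometry

CHARGE_TOLERANCE_E = 1e-6

#: covalent-distance slack for bond-graph inference
BOND_INFERENCE_SCALE = 1.2


class TopologyError(ValueError):
    """Inconsistent cross-link partition or emission request."""


@dataclass
class ResidueTemplate:
    """One residue entry: atoms as (name, type, charge) and internal bonds."""

    name: str
    atoms: list[tuple[str, str, float | None]]
    bonds: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        names = [a[0] for a in self.atoms]
        if len(set(names)) != len(names):
            raise TopologyError(f"residue {self.name}: duplicate atom names")
        name_set = set(names)
        for a, b in self.bonds:
            if a not in name_set or b not in name_set:
                raise TopologyError(
                    f"residue {self.name}: bond ({a}, {b}) references a missing atom"
                )

    def atom_names(self) -> set[str]:
        return {a[0] for a in self.atoms}

    def total_charge(self) -> float:
        total = 0.0
        for name, _, q in self.atoms:
            if q is None:
                raise TopologyError(f"atom {name} in residue {self.name} has no charge")
            total += q
        return total


@dataclass
class ConnectionBond:
    """Inter-residue bond: atom names, equilibrium length (nm), force constant."""

    atom_a: str
    atom_b: str
    b0: float
    k_b: float | None = None


@dataclass
class CrosslinkTopology:
    residue_a: ResidueTemplate
    residue_b: ResidueTemplate
    connection_bonds: list[ConnectionBond]
    parameters: ParameterSet = field(default_factory=ParameterSet)

    def __post_init__(self):
        names_a = self.residue_a.atom_names()
        names_b = self.residue_b.atom_names()
        for cb in self.connection_bonds:
            spans = (cb.atom_a in names_a and cb.atom_b in names_b) or (
                cb.atom_a in names_b and cb.atom_b in names_a
            )
            if not spans:
                raise TopologyError(
                    f"connection bond ({cb.atom_a}, {cb.atom_b}) does not join "
                    "one atom from each residue"
                )


@dataclass
class ChargeReport:
    total_charge: float
    tolerance: float
    passed: bool


# --- bond graph -------------------------------------------------------------


def infer_bond_graph(geom: MoleculeGeometry) -> list[tuple[str, str]]:
    """Bond list from a covalent-radius distance cutoff (sum of radii x 1.2)."""
    bonds = []
    coords = geom.coords
    for i in range(geom.n_atoms):
        ri = COVALENT_RADII_NM.get(geom.atoms[i].element)
        if ri is None:
            raise TopologyError(f"no covalent radius for {geom.atoms[i].element}")
        for j in range(i + 1, geom.n_atoms):
            rj = COVALENT_RADII_NM[geom.atoms[j].element]
            d = float(np.linalg.norm(coords[j] - coords[i]))
            if d <= BOND_INFERENCE_SCALE * (ri + rj):
                bonds.append((geom.atoms[i].name, geom.atoms[j].name))
    return bonds


# --- partitioning -----------------------------------------------------------


def split_crosslink(
    geom: MoleculeGeometry,
    boundary: list[tuple[str, str]],
    bonds: list[tuple[str, str]] | None = None,
    cap_atoms: list[str] | None = None,
    charges: dict[str, float] | None = None,
    atom_types: dict[str, str] | None = None,
    residue_names: tuple[str, str] = ("XLA", "XLB"),
) -> tuple[ResidueTemplate, ResidueTemplate, list[tuple[str, str]]]:
    """Partition a cross-link molecule into two residue templates.

    Removing the boundary bonds (and cap atoms, which join neither residue)
    must leave exactly two connected components; each becomes a template.
    Returns the two templates plus the boundary pairs ordered so the first
    atom of each pair sits in the first template.
    """
    bond_list = bonds if bonds is not None else infer_bond_graph(geom)
    caps = set(cap_atoms or [])
    names = geom.atom_names()
    name_set = set(names)

    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in bond_list:
        if a not in name_set or b not in name_set:
            raise TopologyError(f"bond ({a}, {b}) references an unknown atom")
        g.add_edge(a, b)
    if not nx.is_connected(g):
        raise TopologyError("molecular bond graph is not connected")

    edge_set = {frozenset(e) for e in g.edges}
    for a, b in boundary:
        if frozenset((a, b)) not in edge_set:
            raise TopologyError(f"boundary pair ({a}, {b}) is not an existing bond")

    work = g.copy()
    work.remove_nodes_from(caps)
    work.remove_edges_from(boundary)
    components = [set(c) for c in nx.connected_components(work)]
    if len(components) != 2:
        detail = "; ".join(
            "{" + ", ".join(sorted(c)) + "}" for c in components
        )
        raise TopologyError(
            f"removing boundary bonds yields {len(components)} components, "
            f"expected 2: {detail}"
        )

    # deterministic side assignment: the component holding the first
    # boundary atom (in geometry order) becomes residue A
    first = min(
        (names.index(a) for pair in boundary for a in pair if a not in caps),
        default=0,
    )
    anchor = names[first]
    if anchor in components[1]:
        components = [components[1], components[0]]

    def build(member_names: set[str], resname: str) -> ResidueTemplate:
        atoms = []
        for atom in geom.atoms:  # preserve geometry order
            if atom.name not in member_names:
                continue
            a_type = (atom_types or {}).get(atom.name, atom.element)
            q = (charges or {}).get(atom.name)
            atoms.append((atom.name, a_type, q))
        internal = sorted(
            tuple(sorted(e))
            for e in work.edges
            if e[0] in member_names and e[1] in member_names
        )
        return ResidueTemplate(name=resname, atoms=atoms, bonds=internal)

    res_a = build(components[0], residue_names[0])
    res_b = build(components[1], residue_names[1])

    connections = []
    for a, b in boundary:
        if a in components[0] and b in components[1]:
            connections.append((a, b))
        elif b in components[0] and a in components[1]:
            connections.append((b, a))
        # boundary bonds touching caps are dropped from the connection list
    return res_a, res_b, connections


# --- charge bookkeeping -----------------------------------------------------


def check_net_charge(
    t: CrosslinkTopology, tolerance: float = CHARGE_TOLERANCE_E
) -> ChargeReport:
    """Report the summed charge of both residues; pass iff |sum| <= tolerance."""
    total = t.residue_a.total_charge() + t.residue_b.total_charge()
    return ChargeReport(total_charge=total, tolerance=tolerance, passed=abs(total) <= tolerance)


# --- writers / readers ------------------------------------------------------


def write_residue_entries(t: CrosslinkTopology, path) -> None:
    """Emit both residue templates in the residue-template dialect.

    Refuses to write if either residue is empty or the combined net charge
    violates the zero-net-charge invariant.
    """
    for res in (t.residue_a, t.residue_b):
        if not res.atoms:
            raise TopologyError(f"residue {res.name} is empty")
    report = check_net_charge(t)
    if not report.passed:
        raise TopologyError(
            f"net charge {report.total_charge:+.6f} e exceeds "
            f"|{report.tolerance}| e; refusing to emit"
        )
    lines = []
    for res in (t.residue_a, t.residue_b):
        lines.append(f"[ {res.name} ]")
        lines.append(" [ atoms ]")
        for cgnr, (name, a_type, q) in enumerate(res.atoms, start=1):
            lines.append(f"  {name:<6s} {a_type:<6s} {q: .6f} {cgnr:4d}")
        lines.append(" [ bonds ]")
        for a, b in sorted(res.bonds):
            lines.append(f"  {a:<6s} {b:<6s}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_residue_entries(path) -> list[ResidueTemplate]:
    templates: list[ResidueTemplate] = []
    name = None
    atoms: list[tuple[str, str, float]] = []
    bonds: list[tuple[str, str]] = []
    section = None

    def flush():
        if name is not None:
            templates.append(ResidueTemplate(name=name, atoms=atoms[:], bonds=bonds[:]))

    with open(path) as fh:
        for raw in fh:
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                tag = line.strip("[] ").strip()
                if tag in ("atoms", "bonds"):
                    section = tag
                else:
                    flush()
                    name, atoms, bonds, section = tag, [], [], None
            elif section == "atoms":
                toks = line.split()
                atoms.append((toks[0], toks[1], float(toks[2])))
            elif section == "bonds":
                toks = line.split()
                bonds.append((toks[0], toks[1]))
    flush()
    return templates


def write_specbond(t: CrosslinkTopology, path, nbonds: tuple[int, int] = (1, 1)) -> None:
    """Emit one special-bond record per connection bond.

    Line format: resA atomA nbondsA resB atomB nbondsB length newresA newresB,
    preceded by the record count. Lengths (nm) come from each connection's b0.
    """
    if not t.connection_bonds:
        raise TopologyError("no connection bonds to emit")
    ordered = sorted(t.connection_bonds, key=lambda cb: (cb.atom_a, cb.atom_b))
    lines = [str(len(ordered))]
    for cb in ordered:
        if cb.b0 is None:
            raise TopologyError(
                f"connection bond ({cb.atom_a}, {cb.atom_b}) has no derived length"
            )
        lines.append(
            f"{t.residue_a.name} {cb.atom_a} {nbonds[0]} "
            f"{t.residue_b.name} {cb.atom_b} {nbonds[1]} "
            f"{cb.b0:.6f} {t.residue_a.name} {t.residue_b.name}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_specbond(path) -> list[dict]:
    records = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    count = int(lines[0])
    for line in lines[1 : 1 + count]:
        toks = line.split()
        records.append(
            {
                "res_a": toks[0],
                "atom_a": toks[1],
                "nbonds_a": int(toks[2]),
                "res_b": toks[3],
                "atom_b": toks[4],
                "nbonds_b": int(toks[5]),
                "length": float(toks[6]),
                "newres_a": toks[7],
                "newres_b": toks[8],
            }
        )
    return records


def write_bonded_parameters(
    p: ParameterSet, path, names: list[str] | None = None
) -> None:
    """Emit bondtypes/angletypes sections (function type 1, V = 1/2 k (x-x0)^2).

    Atom columns carry names when a 1-based name list is given, else indices.
    Scientific notation keeps the writer/reader round trip exact to 1e-10.
    """
    import warnings

    if not p.bonds and not p.angles:
        warnings.warn("empty ParameterSet: emitting empty sections")

    def label(idx: int) -> str:
        return names[idx - 1] if names else str(idx)

    lines = ["[ bondtypes ]"]
    for b in sorted(p.bonds, key=lambda b: (b.i, b.j)):
        lines.append(
            f"  {label(b.i):<6s} {label(b.j):<6s} 1 {b.b0:.12e} {b.k_b:.12e}"
        )
    lines.append("[ angletypes ]")
    for a in sorted(p.angles, key=lambda a: (a.i, a.j, a.k)):
        lines.append(
            f"  {label(a.i):<6s} {label(a.j):<6s} {label(a.k):<6s} 1 "
            f"{a.theta0:.12e} {a.k_theta:.12e}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bonded_parameters(path) -> ParameterSet:
    """Parse a bonded-parameter file written with index labels."""
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").strip()
                continue
            toks = line.split()
            if section == "bondtypes":
                bonds.append(
                    BondTerm(i=int(toks[0]), j=int(toks[1]), b0=float(toks[3]), k_b=float(toks[4]))
                )
            elif section == "angletypes":
                angles.append(
                    AngleTerm(
                        i=int(toks[0]),
                        j=int(toks[1]),
                        k=int(toks[2]),
                        theta0=float(toks[4]),
                        k_theta=float(toks[5]),
                    )
                )
    return ParameterSet(bonds=bonds, angles=angles)
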