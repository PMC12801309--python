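"""Layered graphitic carbon-dot (CD) model construction.

A CD is modelled as a stack of hexagonal polyaromatic flakes of the
coronene family (ring order n: n=1 benzene, n=2 coronene C24H12, n=3
circumcoronene C54H18, ... C(6n^2)H(6n)), optionally decorated with charged
edge groups (NH3+ or COO-) replacing edge hydrogens.  Geometry is idealized:
planar honeycomb layers at a fixed graphitic spacing, no relaxation — the
models are inputs to structural analysis, not to molecular dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomRecord, MolecularStructure, VDW_RADII
from .geometry import rotation_about

__all__ = [
    "FlakeSpec",
    "CDBuildSpec",
    "FunctionalizationSpec",
    "CDModel",
    "build_flake",
    "stack_layers",
    "functionalize",
    "cd_dimensions",
    "CARBON_VDW_DIAMETER",
]

# effective thickness added to atom-centre extents when reporting sizes
CARBON_VDW_DIAMETER = 0.34  # nm


@dataclass(frozen=True)
class FlakeSpec:
    """One polyaromatic layer: ring order n and bond lengths (nm)."""

    ring_order: int
    cc_bond: float = 0.142
    ch_bond: float = 0.109

    def __post_init__(self) -> None:
        if self.ring_order < 1:
            raise ValueError("ring_order must be >= 1")
        if self.cc_bond <= 0 or self.ch_bond <= 0:
            raise ValueError("bond lengths must be positive")


@dataclass(frozen=True)
class CDBuildSpec:
    """Stack of flakes: ring order per layer, spacing and in-plane registry."""

    layer_ring_orders: tuple[int, ...]
    interlayer_spacing: float = 0.35
    stacking: str = "AB"  # "AB": alternating half-bond offset, "AA": eclipsed
    cc_bond: float = 0.142
    ch_bond: float = 0.109

    def __post_init__(self) -> None:
        if not self.layer_ring_orders:
            raise ValueError("need at least one layer")
        if self.interlayer_spacing <= 0.30:
            raise ValueError("interlayer spacing must exceed 0.30 nm")
        if self.stacking not in ("AB", "AA"):
            raise ValueError("stacking must be 'AB' or 'AA'")


@dataclass(frozen=True)
class FunctionalizationSpec:
    """Edge functionalization: group, explicit count or edge coverage, seed.

    ``count`` is authoritative when given; otherwise the count is
    ``round(coverage * n_perimeter_carbons)`` where perimeter carbons include
    both H-bearing edge carbons and the junction carbons between them.
    """

    group: str  # "NH3+" or "COO-"
    count: int | None = None
    coverage: float | None = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("NH3+", "COO-"):
            raise ValueError("group must be 'NH3+' or 'COO-'")
        if self.count is None and self.coverage is None:
            raise ValueError("give either count or coverage")
        if self.count is not None and self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass
class CDModel:
    """A built CD: structure, per-atom layer membership, functional sites."""

    structure: MolecularStructure
    layer_of_atom: dict[int, int] = field(default_factory=dict)
    functional_sites: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return max(self.layer_of_atom.values()) + 1 if self.layer_of_atom else 0

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.structure.atoms)

    def layer_atoms(self, layer: int, element: str | None = None) -> list[AtomRecord]:
        out = []
        for a in self.structure.atoms:
            if self.layer_of_atom.get(a.serial) == layer:
                if element is None or a.element == element.upper():
                    out.append(a)
        return out


def _flake_carbons(n: int, cc_bond: float) -> np.ndarray:
    """Carbon positions (nm, z=0) of the ring-order-n hexagonal flake.

    Hexagon centres form the triangular lattice; keeping centres within
    hexagonal ring n-1 yields the centred-hexagonal flake with 6n^2 carbons.
    """
    s = cc_bond * np.sqrt(3.0)
    u = np.array([s, 0.0])
    v = np.array([0.5 * s, 0.5 * np.sqrt(3.0) * s])
    verts: dict[tuple[int, int], np.ndarray] = {}
    m = n - 1
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            if max(abs(i), abs(j), abs(i + j)) > m:
                continue
            c = i * u + j * v
            for k in range(6):
                ang = np.radians(90.0 + 60.0 * k)
                p = c + cc_bond * np.array([np.cos(ang), np.sin(ang)])
                key = (round(p[0] / cc_bond * 1e4), round(p[1] / cc_bond * 1e4))
                verts[key] = p
    xy = np.array(list(verts.values()))
    return np.column_stack([xy, np.zeros(len(xy))])


def _edge_info(carbons: np.ndarray, cc_bond: float):
    """Indices of H-bearing edge carbons, their H directions, and the
    perimeter-carbon count (edge + junction carbons)."""
    tree = cKDTree(carbons)
    pairs = tree.query_pairs(1.2 * cc_bond, output_type="ndarray")
    nbrs: dict[int, list[int]] = {i: [] for i in range(len(carbons))}
    for i, j in pairs:
        nbrs[i].append(j)
        nbrs[j].append(i)
    edge_idx = [i for i, nb in nbrs.items() if len(nb) == 2]
    h_dirs = {}
    for i in edge_idx:
        d = carbons[i] - carbons[list(nbrs[i])].mean(axis=0)
        h_dirs[i] = d / np.linalg.norm(d)
    junction = {
        i
        for i, nb in nbrs.items()
        if len(nb) == 3 and any(j in set(edge_idx) for j in nb)
    }
    return edge_idx, h_dirs, len(edge_idx) + len(junction)


def build_flake(spec: FlakeSpec) -> MolecularStructure:
    """Build one planar D6h flake at z=0 with edge hydrogens."""
    carbons = _flake_carbons(spec.ring_order, spec.cc_bond)
    edge_idx, h_dirs, _ = _edge_info(carbons, spec.cc_bond)
    atoms: list[AtomRecord] = []
    serial = 0
    for i, pos in enumerate(carbons):
        serial += 1
        tags = {"aromatic"}
        if i in h_dirs:
            tags.add("edge")
        atoms.append(
            AtomRecord(serial, f"C{serial}", "C", 1, "CDL", "X", pos,
                       vdw_radius=VDW_RADII["C"], tags=tags)
        )
    for i in sorted(h_dirs):
        serial += 1
        pos = carbons[i] + spec.ch_bond * h_dirs[i]
        atoms.append(
            AtomRecord(serial, f"H{serial}", "H", 1, "CDL", "X", pos,
                       vdw_radius=VDW_RADII["H"],
                       tags={"edge_h", f"on:{i + 1}"})
        )
    return MolecularStructure(atoms=atoms, title=f"flake n={spec.ring_order}")


def stack_layers(spec: CDBuildSpec) -> CDModel:
    """Stack flakes on a common z axis into a CD model.

    Layer k sits at z = (k - (L-1)/2) * spacing; with AB stacking every odd
    layer is shifted in-plane by one bond length.
    """
    n_layers = len(spec.layer_ring_orders)
    atoms: list[AtomRecord] = []
    layer_of_atom: dict[int, int] = {}
    serial = 0
    for k, n in enumerate(spec.layer_ring_orders):
        flake = build_flake(FlakeSpec(n, spec.cc_bond, spec.ch_bond))
        z = (k - (n_layers - 1) / 2.0) * spec.interlayer_spacing
        shift = np.zeros(3)
        if spec.stacking == "AB" and k % 2 == 1:
            shift = np.array([spec.cc_bond, 0.0, 0.0])
        remap: dict[int, int] = {}
        for a in flake.atoms:
            serial += 1
            remap[a.serial] = serial
            new = a.copy()
            new.serial = serial
            new.name = f"{a.element}{serial}"
            new.residue_index = k + 1
            new.position = a.position + np.array([0.0, 0.0, z]) + shift
            new.tags.add(f"layer:{k}")
            new.tags = {
                t if not t.startswith("on:") else f"on:{remap[int(t[3:])]}"
                for t in new.tags
            }
            atoms.append(new)
            layer_of_atom[serial] = k
    structure = MolecularStructure(
        atoms=atoms,
        title=f"CD layers={list(spec.layer_ring_orders)}",
        annotations={"kind": "carbon_dot",
                     "layer_ring_orders": list(spec.layer_ring_orders),
                     "interlayer_spacing": spec.interlayer_spacing},
    )
    return CDModel(structure=structure, layer_of_atom=layer_of_atom)


def _nh3_atoms(c_pos: np.ndarray, direction: np.ndarray, z_hint: np.ndarray):
    """NH3+ replacing an edge H: N on the former C-H vector, tetrahedral Hs."""
    n_pos = c_pos + 0.147 * direction
    perp = np.cross(direction, z_hint)
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(direction, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    out = [("N", n_pos, 1)]
    base = rotation_about(perp, 180.0 - 109.47) @ direction
    for k in range(3):
        h_dir = rotation_about(direction, 120.0 * k) @ base
        out.append((f"H{k + 1}", n_pos + 0.101 * h_dir, 0))
    return out


def _coo_atoms(c_pos: np.ndarray, direction: np.ndarray, z_hint: np.ndarray):
    """COO- replacing an edge H: carboxyl C on the C-H vector, two O at 120 deg."""
    cx = c_pos + 0.152 * direction
    perp = np.cross(direction, z_hint)
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(direction, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    o1 = cx + 0.126 * (rotation_about(perp, 120.0) @ direction)
    o2 = cx + 0.126 * (rotation_about(perp, -120.0) @ direction)
    return [("C", cx, 0), ("O1", o1, -1), ("O2", o2, 0)]


def functionalize(cd: CDModel, spec: FunctionalizationSpec) -> CDModel:
    """Replace randomly chosen edge hydrogens by charged groups.

    Site selection is uniform without replacement, driven only by
    ``spec.seed`` (bit-reproducible).  Returns a new CDModel; the input is
    not modified.
    """
    structure = cd.structure.copy()
    h_sites = [a for a in structure.atoms if "edge_h" in a.tags]
    # perimeter denominator for coverage: edge + junction carbons, all layers
    n_perimeter = 0
    for k in range(cd.n_layers):
        carbons = np.array([a.position for a in cd.layer_atoms(k, "C")])
        cc = cd.structure.annotations.get("interlayer_spacing", 0.35)  # noqa: F841
        _, _, n_per = _edge_info(carbons, 0.142)
        n_perimeter += n_per
    count = spec.count
    if count is None:
        count = int(round(spec.coverage * n_perimeter))
    if count > len(h_sites):
        raise ValueError(
            f"requested {count} groups but only {len(h_sites)} edge-H sites"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(len(h_sites), size=count, replace=False)
    chosen_atoms = [h_sites[i] for i in sorted(chosen)]

    layer_of_atom = dict(cd.layer_of_atom)
    sites = list(cd.functional_sites)
    serial = max(a.serial for a in structure.atoms)
    remove = {a.serial for a in chosen_atoms}
    new_atoms = [a for a in structure.atoms if a.serial not in remove]
    builder = _nh3_atoms if spec.group == "NH3+" else _coo_atoms
    for site_no, h in enumerate(chosen_atoms):
        carbon_serial = next(int(t[3:]) for t in h.tags if t.startswith("on:"))
        carbon = structure.atom_by_serial(carbon_serial)
        direction = h.position - carbon.position
        direction /= np.linalg.norm(direction)
        layer = layer_of_atom[carbon_serial]
        for name, pos, charge in builder(carbon.position, direction,
                                         np.array([0.0, 0.0, 1.0])):
            serial += 1
            el = name[0] if name[0] in ("N", "O", "C", "H") else name
            atom = AtomRecord(
                serial, name, el, carbon.residue_index, "CDL", "X", pos,
                formal_charge=charge, vdw_radius=VDW_RADII[el],
                tags={f"func:{spec.group}", f"site:{site_no}", f"layer:{layer}"},
            )
            new_atoms.append(atom)
            layer_of_atom[serial] = layer
        sites.append((layer, carbon_serial, spec.group))
    out_struct = MolecularStructure(
        atoms=new_atoms, title=structure.title,
        annotations=dict(structure.annotations),
    )
    out_struct.annotations["functional_group"] = spec.group
    out_struct.annotations["functional_count"] = count
    model = CDModel(out_struct, layer_of_atom, sites)
    return model


def cd_dimensions(cd: CDModel) -> tuple[float, float, int]:
    """Effective (height, diameter, net charge) of a built CD.

    Height spans the outermost layer mean planes plus one carbon vdW diameter
    (0.34 nm); diameter is the largest in-plane carbon-carbon distance of the
    widest layer plus the same vdW allowance.
    """
    if cd.n_layers < 1:
        raise ValueError("CD has no layers")
    mean_z = []
    max_span = 0.0
    for k in range(cd.n_layers):
        pos = np.array([a.position for a in cd.layer_atoms(k, "C")])
        mean_z.append(pos[:, 2].mean())
        xy = pos[:, :2]
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
        max_span = max(max_span, float(np.sqrt(d2.max())))
    height = (max(mean_z) - min(mean_z)) + CARBON_VDW_DIAMETER
    diameter = max_span + CARBON_VDW_DIAMETER
    return height, diameter, cd.net_charge
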