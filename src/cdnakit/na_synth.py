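"""Synthetic nucleic-acid structures, planted CD binding poses, and noisy
toy trajectories.

This module is the test bed for every analysis stage: it produces ideal
B-DNA/A-RNA duplexes (with controllable per-bp parameter overrides), a
nucleosomal DNA superhelix, a minimal two-tetrad guanine mock, rigid CD
placements in each catalogued binding mode, and seeded Gaussian-noise
trajectories with optional binding events.  Because it shares the base
templates and the mid-frame conventions with the analysis modules, every
imposed parameter is recoverable exactly on noise-free output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .cd_builder import CDModel
from .core import AtomRecord, MolecularStructure, Trajectory, VDW_RADII
from .geometry import rotation_about
from .helix import FLIP, assign_base_frames, bp_frame, midframe_compose, split_mid
from .templates import COMPLEMENT, RING_NAMES, nucleotide_template

__all__ = [
    "DuplexSpec",
    "SuperhelixSpec",
    "PoseSpec",
    "SynthTrajectorySpec",
    "build_duplex",
    "build_superhelix_dna",
    "build_two_tetrad_mock",
    "place_cd_pose",
    "synthesize_trajectory",
    "POSE_MODES",
]

POSE_MODES = (
    "minor_groove",
    "major_groove",
    "backbone",
    "terminal_stack",
    "unpaired_stack",
    "tetrad_stack",
    "unbound",
)

_BACKBONE_NAMES = {"P", "O5'", "C5'", "C4'", "C3'", "O3'"}
_SUGAR_NAMES = {"C1'", "C2'", "O4'"}

# defaults reproduce solution-state canonical helices (B: 10.5 bp/turn)
_FORM_DEFAULTS = {"B-DNA": (34.3, 0.338), "A-RNA": (32.7, 0.281)}


@dataclass(frozen=True)
class DuplexSpec:
    """Ideal antiparallel duplex: sequence of strand 1 (5'->3') and geometry."""

    sequence: str
    form: str = "B-DNA"
    twist: float | None = None  # deg per step
    rise: float | None = None  # nm per step
    intra_overrides: dict = field(default_factory=dict)  # bp -> {param: value}
    step_overrides: dict = field(default_factory=dict)  # step -> {param: value}
    overhang_3p: str = ""  # unpaired bases continuing strand 1

    def __post_init__(self) -> None:
        if self.form not in _FORM_DEFAULTS:
            raise ValueError("form must be 'B-DNA' or 'A-RNA'")
        seq = self.sequence.upper()
        for ch in seq + self.overhang_3p.upper():
            if ch not in "ACGTU":
                raise ValueError(f"invalid base letter {ch!r}")
            if self.form == "B-DNA" and ch == "U":
                raise ValueError("U is not a B-DNA base")
            if self.form == "A-RNA" and ch == "T":
                raise ValueError("T is not an A-RNA base")

    @property
    def twist_value(self) -> float:
        return self.twist if self.twist is not None else _FORM_DEFAULTS[self.form][0]

    @property
    def rise_value(self) -> float:
        return self.rise if self.rise is not None else _FORM_DEFAULTS[self.form][1]


@dataclass(frozen=True)
class SuperhelixSpec:
    """Left-handed nucleosomal DNA superhelix."""

    n_bp: int = 146
    radius: float = 4.18  # nm
    pitch: float = 2.39  # nm per superhelical turn
    turns: float = 1.7
    local_twist: float = 35.3  # deg per bp step

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("need at least 2 bp")
        if self.pitch <= 0 and self.turns != 0:
            raise ValueError("pitch must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PoseSpec:
    """Rigid CD placement in one of the catalogued binding modes."""

    mode: str
    anchor: int | None = None  # bp index (grooves/stacks) or residue index
    separation: float = 0.34  # nm, stacking plane distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in POSE_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SynthTrajectorySpec:
    """Noisy trajectory: frame count, per-atom Gaussian sigma, binding event."""

    n_frames: int
    noise_sigma: float = 0.0  # nm
    event_frame: int | None = None
    event_window: int = 10  # frames for the bulk -> pose interpolation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# duplex generation
# ---------------------------------------------------------------------------


def _residue_atoms(letter, form, triad, origin, chain, resi, serial0, with_p,
                   bare=False):
    tpl = nucleotide_template(letter)
    resn = ("D" + letter) if form == "B-DNA" else letter
    atoms = []
    serial = serial0
    order = ["P", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]
    order += [n for n in tpl if n not in order]
    for name in order:
        if name == "P" and not with_p:
            continue
        if bare and name in _BACKBONE_NAMES | {"C2'", "O4'"}:
            continue
        if name not in tpl:
            continue
        serial += 1
        pos = triad @ tpl[name] + origin
        el = name[0]
        tags = {"backbone"} if name in _BACKBONE_NAMES else (
            {"sugar"} if name in _SUGAR_NAMES else {"base"}
        )
        atoms.append(
            AtomRecord(serial, name, el, resi, resn, chain, pos,
                       vdw_radius=VDW_RADII[el], tags=tags)
        )
    return atoms, serial


def build_duplex(spec: DuplexSpec) -> MolecularStructure:
    """Build an ideal duplex from accumulated twist/rise with optional per-bp
    parameter overrides, annotated with its pairing and terminal bps."""
    seq = spec.sequence.upper()
    n = len(seq)
    if n < 1:
        raise ValueError("empty sequence")
    # bp mid frames along the helix axis
    T = np.eye(3)
    o = np.zeros(3)
    mids = [(T, o)]
    for i in range(n - 1 + len(spec.overhang_3p)):
        step = {"shift": 0.0, "slide": 0.0, "rise": spec.rise_value,
                "tilt": 0.0, "roll": 0.0, "twist": spec.twist_value}
        step.update(spec.step_overrides.get(i, {}))
        params = (step["shift"], step["slide"], step["rise"],
                  step["tilt"], step["roll"], step["twist"])
        T, o, _, _ = midframe_compose(*mids[-1], params)
        mids.append((T, o))

    atoms: list[AtomRecord] = []
    serial = 0
    strand2: list[tuple[int, np.ndarray, np.ndarray, str]] = []
    for i, letter in enumerate(seq):
        intra = {"shear": 0.0, "stretch": 0.0, "stagger": 0.0,
                 "buckle": 0.0, "propeller": 0.0, "opening": 0.0}
        intra.update(spec.intra_overrides.get(i, {}))
        params = (intra["shear"], intra["stretch"], intra["stagger"],
                  intra["buckle"], intra["propeller"], intra["opening"])
        T1, o1, T2f, o2 = split_mid(*mids[i], params)
        res_atoms, serial = _residue_atoms(
            letter, spec.form, T1, o1, "A", i + 1, serial, with_p=(i > 0)
        )
        atoms.extend(res_atoms)
        strand2.append((i, T2f @ FLIP, o2, COMPLEMENT[letter]))

    unpaired: list[tuple[str, int]] = []
    for k, letter in enumerate(spec.overhang_3p.upper()):
        T1, o1, _, _ = split_mid(*mids[n + k], (0.0,) * 6)
        # overhang bases are bare (base + C1' only), mimicking frayed ends
        res_atoms, serial = _residue_atoms(
            letter, spec.form, T1, o1, "A", n + 1 + k, serial,
            with_p=False, bare=True,
        )
        for a in res_atoms:
            a.tags.add("unpaired")
        atoms.extend(res_atoms)
        unpaired.append(("A", n + 1 + k))

    # chain B runs antiparallel: its residue 1 sits at bp n
    for j in range(n):
        i, triad, origin, letter = strand2[n - 1 - j]
        res_atoms, serial = _residue_atoms(
            letter, spec.form, triad, origin, "B", j + 1, serial, with_p=(j > 0)
        )
        atoms.extend(res_atoms)

    pairing = [(("A", i + 1), ("B", n - i)) for i in range(n)]
    return MolecularStructure(
        atoms=atoms,
        title=f"ideal {spec.form} duplex {seq}",
        annotations={
            "kind": "duplex",
            "form": spec.form,
            "sequence": seq,
            "pairing": pairing,
            "terminal_bps": [0, n - 1],
            "unpaired": unpaired,
            "rise": spec.rise_value,
            "twist": spec.twist_value,
        },
    )


def build_superhelix_dna(spec: SuperhelixSpec) -> MolecularStructure:
    """Duplex bent onto a left-handed superhelical path (nucleosomal DNA).

    Base-pair origins lie exactly on the parametric superhelix; base-pair
    z axes follow the local tangent and the in-plane orientation accumulates
    ``local_twist`` per step.
    """
    n = spec.n_bp
    seq = ("ACGT" * (n // 4 + 1))[:n]
    total = 2.0 * np.pi * spec.turns
    atoms: list[AtomRecord] = []
    serial = 0
    strand2 = []
    straight = spec.turns == 0
    for i in range(n):
        if straight:
            origin = np.array([0.0, 0.0, i * 0.338])
            tangent = np.array([0.0, 0.0, 1.0])
            e1 = np.array([1.0, 0.0, 0.0])
        else:
            th = total * i / (n - 1)
            origin = np.array([
                spec.radius * np.cos(th),
                spec.radius * np.sin(th),
                -spec.pitch * th / (2.0 * np.pi),
            ])
            tangent = np.array([
                -spec.radius * np.sin(th),
                spec.radius * np.cos(th),
                -spec.pitch / (2.0 * np.pi),
            ])
            tangent /= np.linalg.norm(tangent)
            inward = -np.array([np.cos(th), np.sin(th), 0.0])
            e1 = inward - (inward @ tangent) * tangent
            e1 /= np.linalg.norm(e1)
        e2 = np.cross(tangent, e1)
        alpha = np.radians(spec.local_twist * i)
        x = np.cos(alpha) * e1 + np.sin(alpha) * e2
        triad = np.column_stack([x, np.cross(tangent, x), tangent])
        T1, o1, T2f, o2 = split_mid(triad, origin, (0.0,) * 6)
        letter = seq[i]
        res_atoms, serial = _residue_atoms(
            letter, "B-DNA", T1, o1, "A", i + 1, serial, with_p=(i > 0)
        )
        atoms.extend(res_atoms)
        strand2.append((T2f @ FLIP, o2, COMPLEMENT[letter]))
    for j in range(n):
        triad, origin, letter = strand2[n - 1 - j]
        res_atoms, serial = _residue_atoms(
            letter, "B-DNA", triad, origin, "B", j + 1, serial, with_p=(j > 0)
        )
        atoms.extend(res_atoms)
    pairing = [(("A", i + 1), ("B", n - i)) for i in range(n)]
    return MolecularStructure(
        atoms=atoms,
        title=f"superhelical DNA {n} bp, {spec.turns} turns",
        annotations={
            "kind": "superhelix",
            "pairing": pairing,
            "terminal_bps": [0, n - 1],
            "superhelix": {
                "radius": spec.radius, "pitch": spec.pitch,
                "turns": spec.turns, "degenerate_straight": straight,
            },
        },
    )


def build_two_tetrad_mock(separation: float = 0.34, ring_radius: float = 0.45
                          ) -> MolecularStructure:
    """Minimal two-tetrad guanine mock (8 G bases, two stacked C4 quartets).

    Not a physical G-quadruplex (no Hoogsteen hydrogen-bond geometry, no
    backbone) — just enough planar aromatic surface with quartet annotations
    to exercise tetrad-stacking placement and classification.
    """
    atoms: list[AtomRecord] = []
    serial = 0
    quartets = []
    for level in range(2):
        members = []
        for k in range(4):
            resi = 4 * level + k + 1
            rot = rotation_about([0, 0, 1], 90.0 * k + 30.0 * level)
            # x axis inward so the O6 edge faces the channel
            triad = rot @ rotation_about([0, 0, 1], 180.0)
            origin = rot @ np.array([ring_radius, 0.0, 0.0])
            origin[2] = level * separation
            tpl = nucleotide_template("G")
            for name in RING_NAMES["G"] + ("O6", "N2", "C1'"):
                serial += 1
                pos = triad @ tpl[name] + origin
                el = name[0]
                atoms.append(
                    AtomRecord(serial, name, el, resi, "DG", "Q", pos,
                               vdw_radius=VDW_RADII[el],
                               tags={"base", "quartet"})
                )
            members.append(("Q", resi))
        quartets.append(members)
    return MolecularStructure(
        atoms=atoms,
        title="two-tetrad guanine mock",
        annotations={"kind": "tetrad_mock", "pairing": [],
                     "terminal_bps": [], "quartets": quartets},
    )


# ---------------------------------------------------------------------------
# CD placement
# ---------------------------------------------------------------------------


def _align_z(direction: np.ndarray) -> np.ndarray:
    """Rotation taking +z onto ``direction``."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    axis = np.cross(z, d)
    if np.linalg.norm(axis) < 1e-12:
        return np.eye(3) if d[2] > 0 else rotation_about([1, 0, 0], 180.0)
    ang = np.degrees(np.arccos(np.clip(z @ d, -1.0, 1.0)))
    return rotation_about(axis, ang)


def _min_gap_ratio(cd_xyz, cd_r, na_xyz, na_r):
    d = cdist(cd_xyz, na_xyz)
    rsum = cd_r[:, None] + na_r[None, :]
    return float((d / rsum).min())


def _approach(cd_xyz, cd_r, na_xyz, na_r, direction, start, t_max=8.0):
    """Slide the CD along ``direction`` until vdW contact (gap ratio 1.0)."""
    u = direction / np.linalg.norm(direction)

    def ratio(t):
        return _min_gap_ratio(cd_xyz + (start + t * u), cd_r, na_xyz, na_r)

    lo, hi = 0.0, t_max
    if ratio(lo) > 1.0:
        lo = -t_max
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if ratio(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    t = hi  # first non-overlapping offset
    if ratio(t) < 0.8:
        raise ValueError("unresolvable steric clash in pose placement")
    return start + t * u


def _ring_atoms(structure, residue_keys):
    out = []
    for chain, resi in residue_keys:
        for a in structure.residue_atoms(chain, resi):
            from .helix import base_letter

            letter = base_letter(a.residue_name)
            if letter and a.name in RING_NAMES[letter]:
                out.append(a)
    return out


def place_cd_pose(
    na: MolecularStructure, cd: CDModel, pose: PoseSpec
) -> MolecularStructure:
    """Rigidly place a CD on a nucleic acid in the requested binding mode.

    Returns a combined structure (NA chains + CD on chain 'Z') annotated with
    the CD serial set, layer membership, and the planted ground-truth mode.
    """
    ann = dict(na.annotations)
    cd_struct = cd.structure
    cd_xyz0 = cd_struct.coordinates()
    cd_xyz0 = cd_xyz0 - cd_xyz0.mean(axis=0)
    cd_r = np.array([a.vdw_radius for a in cd_struct.atoms])
    na_xyz = na.coordinates()
    na_r = np.array([a.vdw_radius for a in na.atoms])
    na_centroid = na_xyz.mean(axis=0)

    frames = assign_base_frames(na)
    pairing = ann.get("pairing", [])
    n_bp = len(pairing)
    # distance from the (all-atom) CD centroid to the mean plane of the
    # lowest layer: functional groups shift the centroid, so measure rather
    # than assume a symmetric stack
    half_stack = 0.0
    if cd.n_layers > 0:
        layer_z = []
        centred_z = {a.serial: p[2] for a, p in zip(cd_struct.atoms, cd_xyz0)}
        for k in range(cd.n_layers):
            zs = [centred_z[a.serial] for a in cd.layer_atoms(k, "C")]
            layer_z.append(np.mean(zs))
        half_stack = -min(layer_z)

    def bp_mid(i):
        lookup = {(f.chain_id, f.residue_index): f for f in frames}
        fa = lookup[tuple(pairing[i][0])]
        fb = lookup[tuple(pairing[i][1])]
        _, Tm, om = bp_frame(fa, fb)
        return Tm, om

    mode = pose.mode
    if mode in ("minor_groove", "major_groove"):
        i = pose.anchor if pose.anchor is not None else n_bp // 2
        Tm, om = bp_mid(i)
        direction = -Tm[:, 0] if mode == "minor_groove" else Tm[:, 0]
        R = _align_z(direction)
        xyz = cd_xyz0 @ R.T
        centre = _approach(xyz, cd_r, na_xyz, na_r, direction, om + 4.0 * direction)
    elif mode == "backbone":
        resi = pose.anchor if pose.anchor is not None else max(2, n_bp // 2)
        Tm, om = bp_mid(resi - 1)
        p_atom = next(
            a for a in na.residue_atoms("A", resi) if a.name == "P"
        )
        direction = p_atom.position - om
        direction -= (direction @ Tm[:, 2]) * Tm[:, 2]
        direction /= np.linalg.norm(direction)
        # edge-on: stacking axis along the helix so the flake rim, not the
        # face, rides the phosphate ridge
        R = _align_z(Tm[:, 2])
        xyz = cd_xyz0 @ R.T
        centre = _approach(xyz, cd_r, na_xyz, na_r, direction,
                           p_atom.position + 3.0 * direction)
    elif mode == "terminal_stack":
        i = pose.anchor if pose.anchor is not None else n_bp - 1
        Tm, om = bp_mid(i)
        sgn = 1.0 if i >= n_bp // 2 else -1.0
        direction = sgn * Tm[:, 2]
        rings = _ring_atoms(na, list(pairing[i]))
        c = np.array([a.position for a in rings]).mean(axis=0)
        R = _align_z(direction)
        xyz = cd_xyz0 @ R.T
        centre = c + direction * (pose.separation + half_stack)
    elif mode == "unpaired_stack":
        unpaired = ann.get("unpaired") or []
        if not unpaired:
            raise ValueError("structure has no annotated unpaired bases")
        idx = 0 if pose.anchor is None else min(pose.anchor, len(unpaired) - 1)
        key = tuple(unpaired[idx])
        rings = _ring_atoms(na, [key])
        c = np.array([a.position for a in rings]).mean(axis=0)
        lookup = {(f.chain_id, f.residue_index): f for f in frames}
        normal = lookup[key].triad[:, 2]
        if (c - na_centroid) @ normal < 0:
            normal = -normal
        R = _align_z(normal)
        xyz = cd_xyz0 @ R.T
        centre = c + normal * (pose.separation + half_stack)
    elif mode == "tetrad_stack":
        quartets = ann.get("quartets")
        if not quartets:
            raise ValueError("tetrad_stack requires quartet annotations")
        top = quartets[-1]
        rings = _ring_atoms(na, top)
        c = np.array([a.position for a in rings]).mean(axis=0)
        other = np.array(
            [a.position for a in _ring_atoms(na, quartets[0])]
        ).mean(axis=0)
        normal = c - other
        if np.linalg.norm(normal) < 1e-9:
            normal = np.array([0.0, 0.0, 1.0])
        normal /= np.linalg.norm(normal)
        R = _align_z(normal)
        xyz = cd_xyz0 @ R.T
        centre = c + normal * (pose.separation + half_stack)
    elif mode == "unbound":
        rng = np.random.default_rng(pose.seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        xyz = cd_xyz0
        span = np.abs(na_xyz - na_centroid).max() + np.abs(cd_xyz0).max()
        centre = na_centroid + direction * (span + 2.5)
        while cdist(xyz + centre, na_xyz).min() < 2.0:
            centre = centre + direction
    else:  # pragma: no cover
        raise ValueError(mode)

    placed = xyz + centre
    ratio = _min_gap_ratio(placed, cd_r, na_xyz, na_r)
    if ratio < 0.8 and mode in ("terminal_stack", "unpaired_stack",
                                "tetrad_stack"):
        # azimuthal registry is free for stacking: spin the CD about the
        # stacking axis until edge groups clear the substrate
        axis = direction
        best_ratio, best_placed = ratio, placed
        for spin in range(15, 360, 15):
            spun = (xyz @ rotation_about(axis, float(spin)).T) + centre
            r_spin = _min_gap_ratio(spun, cd_r, na_xyz, na_r)
            if r_spin > best_ratio:
                best_ratio, best_placed = r_spin, spun
            if best_ratio >= 0.85:
                break
        ratio, placed = best_ratio, best_placed
    if ratio < 0.8:
        raise ValueError(f"pose {mode}: steric overlap ratio {ratio:.2f} < 0.8")

    out = na.copy()
    offset = max(a.serial for a in na.atoms)
    cd_serials = []
    layer_of_atom = {}
    resi_base = max(a.residue_index for a in na.atoms if a.chain_id != "Z")
    for a, pos in zip(cd_struct.atoms, placed):
        new = a.copy()
        new.serial = a.serial + offset
        new.chain_id = "Z"
        new.residue_index = a.residue_index + resi_base
        new.position = pos
        out.atoms.append(new)
        cd_serials.append(new.serial)
        layer_of_atom[new.serial] = cd.layer_of_atom[a.serial]
    out.annotations.update(
        cd_serials=cd_serials,
        cd_layer_of_atom=layer_of_atom,
        pose_mode=mode,
        pose_separation=pose.separation,
    )
    out.title = f"{na.title} + CD ({mode})"
    return MolecularStructure(out.atoms, out.bonds, out.title, out.annotations)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def synthesize_trajectory(
    complex_structure: MolecularStructure, spec: SynthTrajectorySpec
) -> Trajectory:
    """Seeded noisy trajectory around a (complex) structure.

    Frame 0 is noise-free.  With ``event_frame`` set, the CD starts at an
    unbound position and moves linearly into its pose over
    ``event_window`` frames beginning at ``event_frame``; Gaussian noise of
    ``noise_sigma`` is superimposed on frames 1..n-1.
    """
    rng = np.random.default_rng(spec.seed)
    base = complex_structure.coordinates()
    n_atoms = base.shape[0]
    cd_idx = None
    offset_vec = np.zeros(3)
    if spec.event_frame is not None:
        serials = complex_structure.annotations.get("cd_serials")
        if not serials:
            raise ValueError("event_frame requires a placed CD (cd_serials)")
        serial_set = set(serials)
        cd_idx = np.array(
            [k for k, a in enumerate(complex_structure.atoms)
             if a.serial in serial_set]
        )
        na_idx = np.array([k for k in range(n_atoms) if k not in serial_set and
                           complex_structure.atoms[k].serial not in serial_set])
        cd_centroid = base[cd_idx].mean(axis=0)
        na_centroid = base[na_idx].mean(axis=0)
        u = cd_centroid - na_centroid
        u /= np.linalg.norm(u)
        # bulk start: far enough that the CD is unambiguously unbound
        d = cdist(base[cd_idx], base[na_idx]).min()
        offset_vec = u * (max(0.0, 2.5 - d) + 2.0)

    frames = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        coords = base.copy()
        if cd_idx is not None:
            t0, w = spec.event_frame, spec.event_window
            if f < t0:
                lam = 0.0
            elif f >= t0 + w:
                lam = 1.0
            else:
                lam = (f - t0) / w
            coords[cd_idx] += (1.0 - lam) * offset_vec
        if f > 0 and spec.noise_sigma > 0:
            coords += rng.normal(scale=spec.noise_sigma, size=(n_atoms, 3))
        elif f > 0:
            rng.normal(size=(n_atoms, 3))  # keep the stream position fixed
        frames[f] = coords
    return Trajectory(complex_structure, frames)
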