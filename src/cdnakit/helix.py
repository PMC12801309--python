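"""Nucleic-acid helical-parameter analysis.

Base reference frames are obtained by least-squares fitting the embedded
standard base templates onto observed ring atoms; intra-base-pair and
base-pair-step parameters follow the mid-frame (CEHS / 3DNA-style)
decomposition, so signs are comparable to the common trajectory-analysis
tools.  Distances in nm, angles in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MolecularStructure, Trajectory
from .geometry import dihedral, kabsch, rotation_about, signed_angle
from .templates import (
    BASE_ATOMS,
    CHI_REF,
    GLYCOSIDIC_N,
    SUGAR_RING_ORDER,
    frame_fit_names,
    ring_pucker,
)

__all__ = [
    "BaseFrame",
    "IntraBpParams",
    "StepParams",
    "BackboneState",
    "assign_base_frames",
    "bp_and_step_params",
    "bp_per_turn",
    "backbone_state",
    "groove_widths",
    "heatmap_table",
    "duplex_params",
]

# 180 deg rotation about the frame's own x axis, applied to the second strand
# so both bases of a pair share (approximately) the same z direction
FLIP = np.diag([1.0, -1.0, -1.0])

INTRA_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
STEP_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")


@dataclass
class BaseFrame:
    chain_id: str
    residue_index: int
    letter: str
    origin: np.ndarray  # nm
    triad: np.ndarray  # 3x3, columns x (major groove), y (sugar), z (stack)
    fit_rmsd: float


@dataclass(frozen=True)
class IntraBpParams:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float


@dataclass(frozen=True)
class StepParams:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float


@dataclass
class BackboneState:
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None
    pucker_phase: float | None = None
    pucker_amplitude: float | None = None


# ---------------------------------------------------------------------------
# mid-frame decomposition and its inverse
# ---------------------------------------------------------------------------


def midframe_decompose(Ta, oa, Tb, ob):
    """Six rigid-body parameters of frame b relative to frame a.

    Returns ``((dx, dy, dz, rx, ry, rz), Tm, om)`` where translations are the
    origin difference in the mid frame and rotations are the hinge
    decomposition (rx about x ~ tilt/buckle, ry ~ roll/propeller, rz ~
    twist/opening).
    """
    za, zb = Ta[:, 2], Tb[:, 2]
    cr = np.cross(za, zb)
    # atan2 form: well-conditioned for near-parallel z axes
    gamma = np.degrees(np.arctan2(np.linalg.norm(cr), float(za @ zb)))
    if np.linalg.norm(cr) < 1e-12:
        rt = Ta[:, 1]
    else:
        rt = cr / np.linalg.norm(cr)
    Ta2 = rotation_about(rt, gamma / 2.0) @ Ta
    Tb2 = rotation_about(rt, -gamma / 2.0) @ Tb
    zm = Ta2[:, 2] + Tb2[:, 2]
    zm /= np.linalg.norm(zm)
    twist = signed_angle(Ta2[:, 0], Tb2[:, 0], zm)
    xm = Ta2[:, 0] + Tb2[:, 0]
    xm -= (xm @ zm) * zm
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    Tm = np.column_stack([xm, ym, zm])
    phi = signed_angle(rt, ym, zm)
    roll = gamma * np.cos(np.radians(phi))
    tilt = gamma * np.sin(np.radians(phi))
    om = 0.5 * (oa + ob)
    d = Tm.T @ (ob - oa)
    return (float(d[0]), float(d[1]), float(d[2]), tilt, roll, twist), Tm, om


def midframe_compose(Ta, oa, params, n_iter: int = 40):
    """Inverse of :func:`midframe_decompose`: frame b from frame a + params."""
    dx, dy, dz, tilt, roll, twist = params
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.degrees(np.arctan2(tilt, roll)))
    Tm = Ta.copy()
    for _ in range(n_iter):
        zm, ym = Tm[:, 2], Tm[:, 1]
        rt = rotation_about(zm, -phi) @ ym
        Tm_new = rotation_about(zm, twist / 2.0) @ rotation_about(rt, gamma / 2.0) @ Ta
        # re-orthonormalise drift and test convergence
        if np.max(np.abs(Tm_new - Tm)) < 1e-14:
            Tm = Tm_new
            break
        Tm = Tm_new
    zm, ym = Tm[:, 2], Tm[:, 1]
    rt = rotation_about(zm, -phi) @ ym
    Tb = rotation_about(rt, gamma / 2.0) @ rotation_about(zm, twist / 2.0) @ Tm
    d = np.array([dx, dy, dz])
    om = oa + Tm @ (d / 2.0)
    ob = oa + Tm @ d
    return Tb, ob, Tm, om


def split_mid(Tm, om, params):
    """Split a mid frame into the two flanking frames realising ``params``."""
    dx, dy, dz, tilt, roll, twist = params
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.degrees(np.arctan2(tilt, roll)))
    zm, ym = Tm[:, 2], Tm[:, 1]
    rt = rotation_about(zm, -phi) @ ym
    Ta = rotation_about(rt, -gamma / 2.0) @ rotation_about(zm, -twist / 2.0) @ Tm
    Tb = rotation_about(rt, gamma / 2.0) @ rotation_about(zm, twist / 2.0) @ Tm
    d = Tm @ np.array([dx, dy, dz])
    return Ta, om - d / 2.0, Tb, om + d / 2.0


# ---------------------------------------------------------------------------
# base frames
# ---------------------------------------------------------------------------


def base_letter(residue_name: str) -> str | None:
    name = residue_name.strip().upper()
    for prefix in ("D", "R"):
        if len(name) == 2 and name.startswith(prefix):
            name = name[1:]
    return name if name in ("A", "C", "G", "T", "U") else None


def assign_base_frames(structure: MolecularStructure) -> list[BaseFrame]:
    """Fit the standard base template to every nucleotide residue.

    Residues missing ring atoms are skipped with a warning.  The fit RMSD is
    reported per frame; on generator output it is zero to machine precision.
    """
    frames: list[BaseFrame] = []
    for chain, resi, resn in structure.residues():
        letter = base_letter(resn)
        if letter is None:
            continue
        atoms = {a.name: a.position for a in structure.residue_atoms(chain, resi)}
        names = [n for n in frame_fit_names(letter) if n in atoms]
        if len(names) < len(frame_fit_names(letter)):
            warnings.warn(
                f"residue {chain}:{resi} {resn}: missing ring atoms, skipped"
            )
            continue
        template = BASE_ATOMS(letter)
        mobile = np.array([template[n] for n in names])
        observed = np.array([atoms[n] for n in names])
        R, t, rmsd, _ = kabsch(mobile, observed)
        frames.append(BaseFrame(chain, resi, letter, t, R, rmsd))
    return frames


def _pair_indices(frames: list[BaseFrame], pairing) -> list[tuple[int, int]]:
    """Resolve pairing given either frame indices or (chain, resi) keys."""
    lookup = {(f.chain_id, f.residue_index): k for k, f in enumerate(frames)}
    out = []
    for a, b in pairing:
        ka = lookup[tuple(a)] if not isinstance(a, (int, np.integer)) else int(a)
        kb = lookup[tuple(b)] if not isinstance(b, (int, np.integer)) else int(b)
        out.append((ka, kb))
    seen = [k for ab in out for k in ab]
    if len(set(seen)) != len(seen):
        raise ValueError("pairing assigns a residue more than once")
    return out


def bp_frame(fa: BaseFrame, fb: BaseFrame):
    """Base-pair frame: flip the partner 180 deg about x, then half-average."""
    Tb_f = fb.triad @ FLIP
    params, Tm, om = midframe_decompose(fa.triad, fa.origin, Tb_f, fb.origin)
    intra = IntraBpParams(*params)
    return intra, Tm, om


def bp_and_step_params(
    frames: list[BaseFrame], pairing
) -> tuple[list[IntraBpParams], list[StepParams]]:
    """Intra-bp parameters per pair and step parameters per successive pair."""
    idx = _pair_indices(frames, pairing)
    intras: list[IntraBpParams] = []
    mids: list[tuple[np.ndarray, np.ndarray]] = []
    for ka, kb in idx:
        intra, Tm, om = bp_frame(frames[ka], frames[kb])
        intras.append(intra)
        mids.append((Tm, om))
    steps: list[StepParams] = []
    for (T1, o1), (T2, o2) in zip(mids[:-1], mids[1:]):
        params, _, _ = midframe_decompose(T1, o1, T2, o2)
        steps.append(StepParams(*params))
    return intras, steps


def bp_per_turn(step_twists) -> float:
    """Base pairs per helical turn, 360 / mean(twist)."""
    twists = np.asarray(list(step_twists), dtype=float)
    if twists.size == 0:
        raise ValueError("need at least one step twist")
    mean = twists.mean()
    if abs(mean) < 1e-9:
        return float("nan")
    return float(360.0 / mean)


# ---------------------------------------------------------------------------
# backbone torsions and sugar pucker
# ---------------------------------------------------------------------------


def backbone_state(
    structure: MolecularStructure, chain_id: str, residue_index: int
) -> BackboneState:
    """Backbone torsions alpha..zeta, glycosidic chi, and sugar pucker.

    Fields whose defining atoms are absent (chain termini, reduced models)
    are left as None.
    """
    def res_atoms(ri):
        return {a.name: a.position for a in structure.residue_atoms(chain_id, ri)}

    cur = res_atoms(residue_index)
    if not cur:
        raise ValueError(f"no residue {chain_id}:{residue_index}")
    prev = res_atoms(residue_index - 1)
    nxt = res_atoms(residue_index + 1)

    def tors(*specs):
        pts = []
        for where, name in specs:
            if name not in where:
                return None
            pts.append(where[name])
        return dihedral(*pts)

    state = BackboneState(
        alpha=tors((prev, "O3'"), (cur, "P"), (cur, "O5'"), (cur, "C5'")),
        beta=tors((cur, "P"), (cur, "O5'"), (cur, "C5'"), (cur, "C4'")),
        gamma=tors((cur, "O5'"), (cur, "C5'"), (cur, "C4'"), (cur, "C3'")),
        delta=tors((cur, "C5'"), (cur, "C4'"), (cur, "C3'"), (cur, "O3'")),
        epsilon=tors((cur, "C4'"), (cur, "C3'"), (cur, "O3'"), (nxt, "P")),
        zeta=tors((cur, "C3'"), (cur, "O3'"), (nxt, "P"), (nxt, "O5'")),
    )
    resn = next(
        rn for c, ri, rn in structure.residues()
        if c == chain_id and ri == residue_index
    )
    letter = base_letter(resn)
    if letter is not None:
        n_name, c_ref = GLYCOSIDIC_N[letter], CHI_REF[letter]
        if all(n in cur for n in ("O4'", "C1'", n_name, c_ref)):
            state.chi = dihedral(cur["O4'"], cur["C1'"], cur[n_name], cur[c_ref])
    if all(n in cur for n in SUGAR_RING_ORDER):
        ring = np.array([cur[n] for n in SUGAR_RING_ORDER])
        state.pucker_phase, state.pucker_amplitude = ring_pucker(ring)
    return state


# ---------------------------------------------------------------------------
# groove widths
# ---------------------------------------------------------------------------

P_VDW_CORRECTION = 0.58  # nm, twice the phosphate group radius


def groove_widths(
    structure: MolecularStructure, pairing=None, register: int = 3
) -> pd.DataFrame:
    """Per-bp minor/major groove widths from cross-strand P-P distances.

    For bp i the two cross-strand phosphate distances at sequence register
    +/-``register`` are computed; the smaller (minus a 0.58 nm phosphate vdW
    correction) is reported as the minor groove, the larger as the major.
    Base pairs whose register partner lacks a phosphate get NaN.
    """
    pairing = pairing if pairing is not None else structure.annotations["pairing"]

    def p_atom(key):
        chain, resi = key
        for a in structure.residue_atoms(chain, resi):
            if a.name == "P":
                return a.position
        return None

    p1 = [p_atom(a) for a, _ in pairing]
    p2 = [p_atom(b) for _, b in pairing]
    n = len(pairing)
    rows = []
    for i in range(n):
        widths = []
        for off in (register, -register):
            j = i + off
            if 0 <= j < n and p1[i] is not None and p2[j] is not None:
                widths.append(float(np.linalg.norm(p1[i] - p2[j])))
        if len(widths) == 2:
            minor = min(widths) - P_VDW_CORRECTION
            major = max(widths) - P_VDW_CORRECTION
        else:
            minor = major = float("nan")
        rows.append({"bp": i, "minor": minor, "major": major})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-frame tables
# ---------------------------------------------------------------------------


def duplex_params(structure: MolecularStructure, pairing=None) -> pd.DataFrame:
    """All intra-bp and step parameters of an annotated duplex as one table."""
    pairing = pairing if pairing is not None else structure.annotations["pairing"]
    frames = assign_base_frames(structure)
    intras, steps = bp_and_step_params(frames, pairing)
    rows = []
    for i, p in enumerate(intras):
        row = {"bp": i, **{k: getattr(p, k) for k in INTRA_NAMES}}
        if i < len(steps):
            row.update({k: getattr(steps[i], k) for k in STEP_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_table(
    trajectory: Trajectory,
    parameter: str,
    pairing=None,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Long-format (frame, bp, value) table of one helical parameter.

    ``parameter`` is any intra-bp or step parameter name; step parameters are
    indexed by their first bp.  ``window=(lo, hi)`` restricts to a frame
    range (half-open), e.g. for averaging over a late, equilibrated stretch.
    """
    if parameter not in INTRA_NAMES + STEP_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    pairing = (
        pairing if pairing is not None else trajectory.topology.annotations["pairing"]
    )
    lo, hi = window if window is not None else (0, trajectory.n_frames)
    rows = []
    for f in range(lo, hi):
        table = duplex_params(trajectory.frame_structure(f), pairing)
        for _, r in table.iterrows():
            v = r.get(parameter, float("nan"))
            rows.append({"frame": f, "bp": int(r["bp"]), "value": v})
    return pd.DataFrame(rows)


def window_average(table: pd.DataFrame) -> pd.DataFrame:
    """Per-bp mean of a heatmap table over its frame range."""
    return table.groupby("bp", as_index=False)["value"].mean()
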