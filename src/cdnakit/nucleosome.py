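"""Nucleosome-oriented trajectory metrics.

Gyre-centre distances (closest base-pair centre-of-mass distance excluding a
sequence neighbourhood), per-residue RMSF after Kabsch superposition, and
per-residue RMSD profiles aligned on a binding event taken from a
classifier timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MolecularStructure, Trajectory
from .geometry import kabsch

__all__ = [
    "GyreConfig",
    "EventSpec",
    "gyre_distances",
    "per_residue_rmsf",
    "event_aligned_rmsd",
    "detect_binding_event",
]

# element masses for centre-of-mass bookkeeping (u)
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
         "S": 32.06}


@dataclass(frozen=True)
class GyreConfig:
    """Sequence exclusion for cross-gyre distance minimisation."""

    sequence_exclusion: int = 10  # bp

    def __post_init__(self) -> None:
        if self.sequence_exclusion < 1:
            raise ValueError("exclusion must be >= 1 bp")


@dataclass(frozen=True)
class EventSpec:
    """Event-aligned analysis window around a binding event."""

    half_width: int  # frames before/after the event
    persistence: int = 10  # frames a bound state must last to count
    alignment: str = ""  # selection query for superposition (empty: all)


def _bp_centres(structure: MolecularStructure, pairing) -> np.ndarray:
    """Centre of mass of each base pair (all atoms of both residues)."""
    centres = np.zeros((len(pairing), 3))
    for i, (a_key, b_key) in enumerate(pairing):
        atoms = structure.residue_atoms(*a_key) + structure.residue_atoms(*b_key)
        if not atoms:
            raise ValueError(f"pair {i}: residues not found")
        m = np.array([_MASS.get(x.element, 12.0) for x in atoms])
        pos = np.array([x.position for x in atoms])
        centres[i] = (m[:, None] * pos).sum(axis=0) / m.sum()
    return centres


def gyre_distances(
    obj: MolecularStructure | Trajectory,
    pairing=None,
    config: GyreConfig = GyreConfig(),
) -> pd.DataFrame:
    """Minimum cross-gyre distance per bp: d(i) = min over |i-j| > exclusion
    of the bp centre-of-mass separation.

    For a trajectory, one row per (frame, bp); for a structure, frame 0.
    """
    if isinstance(obj, Trajectory):
        structures = (obj.frame_structure(f) for f in range(obj.n_frames))
        pairing = pairing or obj.topology.annotations["pairing"]
    else:
        structures = (obj,)
        pairing = pairing or obj.annotations["pairing"]
    n = len(pairing)
    excl = config.sequence_exclusion
    if n < 2 * excl + 2:
        raise ValueError(
            f"{n} bp cannot support a {excl}-bp sequence exclusion"
        )
    rows = []
    for f, s in enumerate(structures):
        centres = _bp_centres(s, pairing)
        d = np.linalg.norm(centres[:, None, :] - centres[None, :, :], axis=-1)
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        d[np.abs(ii - jj) <= excl] = np.inf
        dmin = d.min(axis=1)
        for i in range(n):
            rows.append({"frame": f, "bp": i, "distance": float(dmin[i])})
    return pd.DataFrame(rows)


def _align_frames(trajectory: Trajectory, selection: str,
                  exclude_cd: bool = True) -> np.ndarray:
    """Frames superposed (Kabsch) on the raw time-average of the selection.

    Using the mean structure as reference makes the result invariant to
    frame-order permutation.  With an empty selection the alignment uses all
    non-CD atoms (the nucleic acid), so a CD flying in does not drag the
    superposition.
    """
    from .core import select

    topo = trajectory.topology
    if selection:
        serials = {a.serial for a in select(topo, selection)}
    else:
        serials = {a.serial for a in topo.atoms}
        if exclude_cd:
            serials -= set(topo.annotations.get("cd_serials", ()))
    idx = np.array([k for k, a in enumerate(topo.atoms) if a.serial in serials])
    if len(idx) < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    ref = trajectory.frames[:, idx].mean(axis=0)
    out = np.empty_like(trajectory.frames)
    for f in range(trajectory.n_frames):
        R, t, _, _ = kabsch(trajectory.frames[f][idx], ref)
        out[f] = trajectory.frames[f] @ R.T + t
    return out


def per_residue_rmsf(trajectory: Trajectory, alignment: str = "") -> pd.DataFrame:
    """Per-residue RMSF (nm) about the time-average structure.

    Frames are first superposed on the alignment selection; the RMSF of a
    residue is the root mean (over frames and its atoms) squared deviation
    from the atoms' time-averaged positions.  Isotropic per-coordinate noise
    of width sigma gives RMSF = sigma * sqrt(3).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    aligned = _align_frames(trajectory, alignment)
    mean = aligned.mean(axis=0)
    sq = ((aligned - mean) ** 2).sum(axis=-1)  # (frames, atoms)
    msd = sq.mean(axis=0)  # per atom
    topo = trajectory.topology
    rows = []
    seen = {}
    for k, a in enumerate(topo.atoms):
        seen.setdefault((a.chain_id, a.residue_index), []).append(k)
    for (chain, resi), idx in seen.items():
        rows.append(
            {"chain": chain, "residue": resi,
             "rmsf": float(np.sqrt(msd[idx].mean()))}
        )
    return pd.DataFrame(rows)


def detect_binding_event(timeline, persistence: int = 10) -> int | None:
    """First frame of a bound state lasting >= ``persistence`` frames."""
    labels = timeline.labels if hasattr(timeline, "labels") else list(timeline)
    run = 0
    for f, lab in enumerate(labels):
        if lab != "unbound":
            run += 1
            if run == persistence:
                return f - persistence + 1
        else:
            run = 0
    return None


def event_aligned_rmsd(
    trajectory: Trajectory, timeline, spec: EventSpec
) -> pd.DataFrame:
    """Per-residue RMSD change across a binding event.

    The event frame t0 is the onset of the first persistent bound state in
    ``timeline``.  Frames in [t0 - half_width, t0) and [t0, t0 + half_width]
    are superposed on the alignment selection; each window's per-residue
    RMSD is computed against the pre-event window average, and
    ``delta = after - before`` localises binding-induced deformation.
    Returns an empty frame (with ``.attrs['event'] = None``) when no event
    qualifies.
    """
    t0 = detect_binding_event(timeline, spec.persistence)
    if t0 is None:
        out = pd.DataFrame(columns=["chain", "residue", "before", "after", "delta"])
        out.attrs["event"] = None
        return out
    if t0 - spec.half_width < 0 or t0 + spec.half_width > trajectory.n_frames:
        raise ValueError("event window exceeds trajectory bounds")
    aligned = _align_frames(trajectory, spec.alignment)
    pre = aligned[t0 - spec.half_width : t0]
    post = aligned[t0 : t0 + spec.half_width]
    ref = pre.mean(axis=0)
    topo = trajectory.topology
    groups: dict[tuple[str, int], list[int]] = {}
    cd_serials = set(topo.annotations.get("cd_serials", ()))
    for k, a in enumerate(topo.atoms):
        if a.serial in cd_serials:
            continue
        groups.setdefault((a.chain_id, a.residue_index), []).append(k)
    rows = []
    for (chain, resi), idx in groups.items():
        before = float(np.sqrt(((pre[:, idx] - ref[idx]) ** 2).sum(-1).mean()))
        after = float(np.sqrt(((post[:, idx] - ref[idx]) ** 2).sum(-1).mean()))
        rows.append({"chain": chain, "residue": resi, "before": before,
                     "after": after, "delta": after - before})
    out = pd.DataFrame(rows)
    out.attrs["event"] = t0
    return out
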