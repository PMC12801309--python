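"""Per-frame CD binding-mode classification and trajectory summaries.

Modes follow the groove / backbone / stacking taxonomy used for CD-nucleic
acid complexes: ``minor_groove``, ``major_groove``, ``backbone``,
``terminal_stack``, ``unpaired_stack``, ``tetrad_stack`` and ``unbound``.
The decision procedure is this module's own operationalisation (visual
assignment does not transfer to code): a distance gate for unbound frames;
stacking geometry against annotated special ring systems (tetrad >
unpaired > terminal precedence); then the azimuth of the contact centroid
in the nearest base-pair frame.  A flat, rigid CD resting on a duplex
touches mostly phosphates whichever groove it faces, so raw contact counts
against groove-edge atoms cannot separate the wide major groove from the
backbone — the azimuth (x axis points into the major groove, the phosphates
sit near +-75 deg) can.  Edge-atom contact counts are still reported as
evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import ContactConfig, detect_stacking, min_heavy_distance
from .core import MolecularStructure, Trajectory
from .helix import assign_base_frames, base_letter, bp_frame
from .templates import RING_NAMES

__all__ = [
    "ModeLabel",
    "ClassifierConfig",
    "ModeTimeline",
    "GROOVE_ATOM_MAP",
    "classify_frame",
    "classify_trajectory",
    "summarize_modes",
]

MODE_LABELS = (
    "minor_groove",
    "major_groove",
    "backbone",
    "terminal_stack",
    "unpaired_stack",
    "tetrad_stack",
    "unbound",
)
ModeLabel = str

# chemical edge definitions per base: which atoms a groove-bound ligand can
# actually touch (sugar O4' counts as a minor-groove floor atom)
GROOVE_ATOM_MAP: dict[str, dict[str, set[str]]] = {
    "A": {"minor": {"C2", "N3"}, "major": {"N6", "N7", "C8"}},
    "G": {"minor": {"N3", "N2"}, "major": {"O6", "N7", "C8"}},
    "C": {"minor": {"O2"}, "major": {"N4", "C5", "C6"}},
    "T": {"minor": {"O2"}, "major": {"O4", "C5", "C7"}},
    "U": {"minor": {"O2"}, "major": {"O4", "C5"}},
}
MINOR_SUGAR = {"O4'"}
BACKBONE_NAMES = {"P", "OP1", "OP2", "O5'", "O3'", "C5'", "C4'", "C3'"}


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the mode decision procedure."""

    unbound_cutoff: float = 0.50  # nm; above vdW contact (~0.34 nm) by a
    # few noise lengths, far below any genuinely detached CD
    contact_cutoff: float = 0.45  # nm, contact-shell distance
    major_halfwidth: float = 50.0  # deg, azimuth band around +x (major)
    minor_halfwidth: float = 65.0  # deg, azimuth band around 180 (minor)
    stacking: ContactConfig = field(default_factory=ContactConfig)
    dominant_window: float = 0.20  # trailing fraction of frames


@dataclass
class ModeTimeline:
    labels: list[ModeLabel]
    evidence: list[dict]
    fractions: dict[ModeLabel, float]
    dominant: ModeLabel

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": range(len(self.labels)), "mode": self.labels})


def _split_atoms(structure: MolecularStructure):
    serials = set(structure.annotations.get("cd_serials", ()))
    if not serials:
        raise ValueError("structure has no placed CD (cd_serials annotation)")
    cd = [a for a in structure.atoms if a.serial in serials]
    na = [a for a in structure.atoms if a.serial not in serials]
    return cd, na


def _na_groups(na_atoms):
    """Partition NA atoms into minor-edge / major-edge / backbone sets."""
    groups: dict[str, list] = {"minor": [], "major": [], "backbone": []}
    for a in na_atoms:
        letter = base_letter(a.residue_name)
        if a.name in BACKBONE_NAMES:
            groups["backbone"].append(a)
        elif letter is not None:
            if a.name in MINOR_SUGAR or a.name in GROOVE_ATOM_MAP[letter]["minor"]:
                groups["minor"].append(a)
            elif a.name in GROOVE_ATOM_MAP[letter]["major"]:
                groups["major"].append(a)
    return groups


def _ring_positions(structure, residue_keys):
    out = []
    for chain, resi in residue_keys:
        for a in structure.residue_atoms(chain, resi):
            letter = base_letter(a.residue_name)
            if letter and a.name in RING_NAMES[letter]:
                out.append(a)
    return out


def _cd_extreme_layer(structure, cd_atoms, target_centroid):
    """Carbon atoms of the CD layer closest to the target ring system."""
    layer_of = structure.annotations.get("cd_layer_of_atom", {})
    if not layer_of:
        return [a for a in cd_atoms if a.element == "C"]
    layers: dict[int, list] = {}
    for a in cd_atoms:
        if a.element != "C":
            continue
        layers.setdefault(layer_of.get(a.serial, 0), []).append(a)
    best, best_d = None, np.inf
    for atoms in layers.values():
        c = np.mean([a.position for a in atoms], axis=0)
        d = np.linalg.norm(c - target_centroid)
        if d < best_d:
            best, best_d = atoms, d
    return best


def classify_frame(
    structure: MolecularStructure, config: ClassifierConfig = ClassifierConfig()
) -> tuple[ModeLabel, dict]:
    """Assign one binding-mode label to a CD/NA snapshot, with evidence.

    Requires the annotations written by the pose generator (or equivalent):
    ``cd_serials``, and for the stacking branches ``terminal_bps`` /
    ``unpaired`` / ``quartets`` residue bookkeeping.
    """
    ann = structure.annotations
    cd, na = _split_atoms(structure)
    evidence: dict = {}
    dmin = min_heavy_distance(cd, na)
    evidence["min_heavy_distance"] = dmin
    if dmin > config.unbound_cutoff:
        return "unbound", evidence

    # stacking branches, in precedence order tetrad > unpaired > terminal
    pairing = ann.get("pairing", [])
    candidates: list[tuple[str, list]] = []
    for quartet in ann.get("quartets") or []:
        candidates.append(("tetrad_stack", [tuple(k) for k in quartet]))
    for key in ann.get("unpaired") or []:
        candidates.append(("unpaired_stack", [tuple(key)]))
    for i in ann.get("terminal_bps") or []:
        if pairing:
            candidates.append(("terminal_stack", [tuple(k) for k in pairing[i]]))
    stack_hits = []
    for label, keys in candidates:
        rings = _ring_positions(structure, keys)
        if len(rings) < 3:
            continue
        centroid = np.mean([a.position for a in rings], axis=0)
        layer = _cd_extreme_layer(structure, cd, centroid)
        geom = detect_stacking(layer, rings, config.stacking)
        if geom.stacked:
            stack_hits.append((label, geom))
    if stack_hits:
        order = {"tetrad_stack": 0, "unpaired_stack": 1, "terminal_stack": 2}
        stack_hits.sort(key=lambda lg: (order[lg[0]], lg[1].offset))
        label, geom = stack_hits[0]
        evidence["stacking"] = geom
        return label, evidence

    # evidence: edge-atom contact counts (diagnostic, not decisive)
    groups = _na_groups(na)
    cd_heavy = np.array([a.position for a in cd if a.element != "H"])
    tree = cKDTree(cd_heavy)
    counts = {}
    for name, atoms in groups.items():
        if atoms:
            pos = np.array([a.position for a in atoms])
            counts[name] = int(
                sum(len(m) for m in tree.query_ball_point(pos, config.contact_cutoff))
            )
        else:
            counts[name] = 0
    evidence["contact_counts"] = counts

    if not pairing:
        # no duplex frames to define grooves: take the nearest-to-passing
        # stacking candidate, else give up as backbone contact
        best, best_score = None, np.inf
        for label, keys in candidates:
            rings = _ring_positions(structure, keys)
            if len(rings) < 3:
                continue
            centroid = np.mean([a.position for a in rings], axis=0)
            layer = _cd_extreme_layer(structure, cd, centroid)
            g = detect_stacking(layer, rings, config.stacking)
            lo, hi = config.stacking.stack_separation
            score = (
                max(0.0, g.angle - config.stacking.stack_angle) / 30.0
                + max(0.0, lo - g.separation, g.separation - hi) / 0.1
                + max(0.0, g.offset - config.stacking.stack_offset) / 0.1
            )
            if score < best_score:
                best, best_score = label, score
        evidence["fallback_stacking_score"] = best_score
        return best or "backbone", evidence

    # groove vs backbone: azimuth of the contact centroid in the nearest
    # base-pair frame (x points into the major groove)
    na_heavy = np.array([a.position for a in na if a.element != "H"])
    d_to_na = cKDTree(na_heavy).query(cd_heavy)[0]
    shell = cd_heavy[d_to_na <= max(config.contact_cutoff, d_to_na.min() + 0.05)]
    centroid = shell.mean(axis=0)
    frames = assign_base_frames(structure)
    lookup = {(f.chain_id, f.residue_index): f for f in frames}
    best_az, best_d = 0.0, np.inf
    for a_key, b_key in pairing:
        fa, fb = lookup.get(tuple(a_key)), lookup.get(tuple(b_key))
        if fa is None or fb is None:
            continue
        _, Tm, om = bp_frame(fa, fb)
        v = centroid - om
        d = float(np.linalg.norm(v))
        if d < best_d:
            best_d = d
            best_az = float(np.degrees(np.arctan2(v @ Tm[:, 1], v @ Tm[:, 0])))
    evidence["contact_azimuth"] = best_az
    if abs(best_az) <= config.major_halfwidth:
        return "major_groove", evidence
    if abs(best_az) >= 180.0 - config.minor_halfwidth:
        return "minor_groove", evidence
    return "backbone", evidence


def classify_trajectory(
    trajectory: Trajectory, config: ClassifierConfig = ClassifierConfig()
) -> ModeTimeline:
    """Label every frame and summarise the run.

    The dominant mode is the modal label over the trailing
    ``dominant_window`` fraction of frames, echoing late-window averaging of
    long simulations.
    """
    labels, evidence = [], []
    work = trajectory.topology.copy()  # one mutable snapshot, reused per frame
    for f in range(trajectory.n_frames):
        work.set_coordinates(trajectory.frames[f])
        lab, ev = classify_frame(work, config)
        labels.append(lab)
        evidence.append(ev)
    n = len(labels)
    fractions = {m: labels.count(m) / n for m in MODE_LABELS}
    tail = labels[int(np.ceil(n * (1.0 - config.dominant_window))):] or labels[-1:]
    dominant = Counter(tail).most_common(1)[0][0]
    return ModeTimeline(labels, evidence, fractions, dominant)


def summarize_modes(timelines: list[ModeTimeline]) -> pd.DataFrame:
    """Percentage of simulations per dominant mode (co-dominant split evenly)."""
    if not timelines:
        raise ValueError("need at least one timeline")
    shares: Counter = Counter()
    for tl in timelines:
        counts = Counter(
            tl.labels[int(np.ceil(len(tl.labels) * 0.8)):] or tl.labels[-1:]
        )
        top = max(counts.values())
        winners = [m for m, c in counts.items() if c == top]
        for m in winners:
            shares[m] += 1.0 / len(winners)
    n = len(timelines)
    rows = [
        {"mode": m, "percent": 100.0 * shares.get(m, 0.0) / n} for m in MODE_LABELS
    ]
    return pd.DataFrame(rows)
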