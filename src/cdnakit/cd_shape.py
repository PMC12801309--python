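"""Per-frame CD structural descriptors.

Each graphitic layer is fitted with a least-squares plane; relative to the
middle reference layer the module reports interlayer distances, tilts,
in-plane rotations (against an internal marker direction, so the
descriptors are invariant under global rigid motion), lateral offsets and
undulation (out-of-plane RMS), plus layer-detachment events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MolecularStructure, Trajectory
from .geometry import fit_plane, signed_angle

__all__ = [
    "LayerGeometry",
    "ShapeTimeline",
    "DetachmentEvent",
    "fit_layers",
    "shape_descriptors",
    "detect_detachment",
]


@dataclass
class LayerGeometry:
    layer: int
    centroid: np.ndarray  # nm
    normal: np.ndarray  # unit vector, sign-aligned to the reference layer
    fit_rms: float  # nm, out-of-plane RMS (undulation)


@dataclass
class DetachmentEvent:
    layer: int
    frame: int  # first frame of the persistent excursion


@dataclass
class ShapeTimeline:
    """Per-frame layer descriptors relative to the middle reference layer."""

    table: pd.DataFrame  # long format: frame, layer, metric columns
    interlayer: pd.DataFrame  # frame, pair (k,k+1), distance
    reference_layer: int
    events: list[DetachmentEvent] = field(default_factory=list)


def _layer_membership(structure: MolecularStructure, membership=None):
    membership = membership or structure.annotations.get("cd_layer_of_atom") or {}
    if not membership:
        # fall back on layer:k tags
        for a in structure.atoms:
            for t in a.tags:
                if t.startswith("layer:"):
                    membership[a.serial] = int(t.split(":")[1])
    if not membership:
        raise ValueError("no layer membership available")
    return {int(k): int(v) for k, v in membership.items()}


def _layer_carbon_indices(structure, membership):
    layers: dict[int, list[int]] = {}
    for idx, a in enumerate(structure.atoms):
        if a.serial in membership and a.element == "C":
            layers.setdefault(membership[a.serial], []).append(idx)
    return {k: np.array(v) for k, v in sorted(layers.items())}


def fit_layers(
    structure: MolecularStructure, membership=None, reference: int | None = None
) -> list[LayerGeometry]:
    """SVD plane fit per layer; normals sign-aligned to the reference layer."""
    membership = _layer_membership(structure, membership)
    coords = structure.coordinates()
    layers = _layer_carbon_indices(structure, membership)
    if reference is None:
        keys = sorted(layers)
        reference = keys[len(keys) // 2]
    geoms: list[LayerGeometry] = []
    ref_normal = None
    # fit the reference first to fix the sign convention
    order = [reference] + [k for k in sorted(layers) if k != reference]
    tmp = {}
    for k in order:
        pts = coords[layers[k]]
        c, n, rms = fit_plane(pts)
        if ref_normal is None:
            if n[2] < 0:  # deterministic sign for the reference itself
                n = -n
            ref_normal = n
        elif n @ ref_normal < 0:
            n = -n
        tmp[k] = LayerGeometry(k, c, n, rms)
    for k in sorted(layers):
        geoms.append(tmp[k])
    return geoms


def _marker_direction(structure, membership, coords):
    """Per-layer marker: centroid -> lowest-serial perimeter (edge) carbon."""
    markers = {}
    serial_to_idx = {a.serial: i for i, a in enumerate(structure.atoms)}
    for a in structure.atoms:
        if a.serial in membership and "edge" in a.tags:
            k = membership[a.serial]
            if k not in markers or a.serial < markers[k]:
                markers[k] = a.serial
    return {k: serial_to_idx[s] for k, s in markers.items()}


def shape_descriptors(
    trajectory: Trajectory, membership=None, reference: int | None = None
) -> ShapeTimeline:
    """Shape timeline of a CD trajectory.

    Per layer and frame: tilt vs the middle layer, in-plane rotation of the
    marker direction relative to the middle layer's marker (change vs frame
    0), lateral offset perpendicular to the middle normal, undulation.
    Interlayer distances are adjacent-centroid separations projected on the
    middle-layer normal.
    """
    topo = trajectory.topology
    membership = _layer_membership(topo, membership)
    layers = _layer_carbon_indices(topo, membership)
    keys = sorted(layers)
    if reference is None:
        if len(keys) % 2 == 0:
            raise ValueError("even layer count: give an explicit reference")
        reference = keys[len(keys) // 2]
    markers = _marker_direction(topo, membership, None)

    rows, inter_rows = [], []
    rot0: dict[int, float] = {}
    for f in range(trajectory.n_frames):
        coords = trajectory.frames[f]
        geoms = {}
        for k in keys:
            c, n, rms = fit_plane(coords[layers[k]])
            geoms[k] = (c, n, rms)
        c_mid, n_mid, _ = geoms[reference]
        # internal sign convention: the reference normal points along the
        # stacking direction (first -> last layer), so every descriptor is
        # invariant under global rigid motion
        if len(keys) > 1:
            stack_dir = geoms[keys[-1]][0] - geoms[keys[0]][0]
            if n_mid @ stack_dir < 0:
                n_mid = -n_mid
        elif n_mid[2] < 0:
            n_mid = -n_mid
        # reference marker direction projected into the mid plane
        m_mid = coords[markers[reference]] - c_mid
        m_mid -= (m_mid @ n_mid) * n_mid
        for k in keys:
            c, n, rms = geoms[k]
            if n @ n_mid < 0:
                n = -n
            tilt = float(
                np.degrees(np.arccos(np.clip(abs(n @ n_mid), -1.0, 1.0)))
            )
            dv = c - c_mid
            lateral = float(np.linalg.norm(dv - (dv @ n_mid) * n_mid))
            m_k = coords[markers[k]] - c
            m_k -= (m_k @ n_mid) * n_mid
            rot = signed_angle(m_mid, m_k, n_mid)
            if f == 0:
                rot0[k] = rot
            rot_rel = ((rot - rot0[k] + 180.0) % 360.0) - 180.0
            rows.append(
                {"frame": f, "layer": k, "tilt": tilt, "rotation": rot_rel,
                 "lateral_offset": lateral, "undulation": rms}
            )
        for ka, kb in zip(keys[:-1], keys[1:]):
            dist = float(abs((geoms[kb][0] - geoms[ka][0]) @ n_mid))
            inter_rows.append(
                {"frame": f, "lower": ka, "upper": kb, "distance": dist}
            )
    timeline = ShapeTimeline(
        table=pd.DataFrame(rows),
        interlayer=pd.DataFrame(inter_rows),
        reference_layer=reference,
    )
    timeline.events = detect_detachment(trajectory, membership)
    return timeline


def detect_detachment(
    trajectory: Trajectory,
    membership=None,
    threshold: float = 0.60,
    persistence: int = 5,
) -> list[DetachmentEvent]:
    """Outer-layer detachment: nearest-neighbour centroid distance above
    ``threshold`` for at least ``persistence`` consecutive frames."""
    topo = trajectory.topology
    membership = _layer_membership(topo, membership)
    layers = _layer_carbon_indices(topo, membership)
    keys = sorted(layers)
    spacing = topo.annotations.get("interlayer_spacing", 0.35)
    if threshold <= spacing:
        raise ValueError("threshold must exceed the built interlayer spacing")
    events: list[DetachmentEvent] = []
    for k in (keys[0], keys[-1]) if len(keys) > 1 else []:
        neighbour = keys[1] if k == keys[0] else keys[-2]
        run_start = None
        run = 0
        for f in range(trajectory.n_frames):
            c_k = trajectory.frames[f][layers[k]].mean(axis=0)
            c_n = trajectory.frames[f][layers[neighbour]].mean(axis=0)
            if np.linalg.norm(c_k - c_n) > threshold:
                if run == 0:
                    run_start = f
                run += 1
                if run == persistence:
                    events.append(DetachmentEvent(layer=k, frame=run_start))
            else:
                run = 0
    return events
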