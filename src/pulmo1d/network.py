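"""Arterial tree data model: segments, validation, serialization, geometry.

A :class:`VesselNetwork` is a strictly bifurcating, directed tree of
straight cylindrical segments.  Each segment carries a length ``L`` (cm)
and a reference radius ``r0`` (cm), the radius at diastolic pressure, so
the diastolic lumen area is ``Adia = pi * r0**2``.  The three extralobar
vessels (MPA root plus LPA/RPA children) are flagged so they can be
rescaled to imaging-derived areas and reported separately from the
intralobar crown.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "VesselSegment",
    "VesselNetwork",
    "NetworkValidationError",
    "load_network",
    "save_network",
    "validate_network",
    "scale_extralobar_areas",
    "poiseuille_resistance",
    "terminal_segments",
]

NETWORK_FORMAT = "pulmo1d-network"
NETWORK_VERSION = 1


class NetworkValidationError(ValueError):
    """Raised when a network violates structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid network: " + "; ".join(self.violations))


@dataclass(frozen=True)
class VesselSegment:
    """One straight cylindrical vessel.

    Parameters
    ----------
    id : str
        Unique identifier within the network.
    length : float
        Segment length in cm, > 0.
    radius : float
        Reference (diastolic) radius r0 in cm, > 0.
    parent : str or None
        Parent segment id; ``None`` for the root only.
    children : tuple of str
        Exactly 0 (terminal) or 2 (bifurcation) child ids.
    name : str, optional
        Label, e.g. ``"MPA"``/``"LPA"``/``"RPA"``.
    is_extralobar : bool
        Whether the segment belongs to the extralobar crown.
    stiffness : float or None
        Wall stiffness Eh/r0 in dyn/cm^2; may be unset until assigned.
    """

    id: str
    length: float
    radius: float
    parent: str | None = None
    children: tuple[str, ...] = ()
    name: str = ""
    is_extralobar: bool = False
    stiffness: float | None = None

    @property
    def area(self) -> float:
        """Diastolic lumen area pi*r0^2 in cm^2."""
        return math.pi * self.radius**2

    @property
    def is_terminal(self) -> bool:
        return len(self.children) == 0


@dataclass
class VesselNetwork:
    """Directed bifurcating tree of :class:`VesselSegment`."""

    segments: dict[str, VesselSegment] = field(default_factory=dict)
    root_id: str = ""

    def __post_init__(self) -> None:
        violations = validate_network(self)
        if violations:
            raise NetworkValidationError(violations)

    @property
    def root(self) -> VesselSegment:
        return self.segments[self.root_id]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.ordered_segments())

    def ordered_segments(self) -> list[VesselSegment]:
        """All segments in deterministic id-sorted order."""
        return [self.segments[k] for k in sorted(self.segments)]

    def children_of(self, seg_id: str) -> tuple[VesselSegment, ...]:
        return tuple(self.segments[c] for c in self.segments[seg_id].children)

    def path_to_root(self, seg_id: str) -> list[VesselSegment]:
        """Segments from ``seg_id`` up to and including the root."""
        out = []
        cur: str | None = seg_id
        while cur is not None:
            seg = self.segments[cur]
            out.append(seg)
            cur = seg.parent
        return out

    def subtree_ids(self, seg_id: str) -> set[str]:
        """Ids of ``seg_id`` and all of its descendants."""
        out: set[str] = set()
        stack = [seg_id]
        while stack:
            sid = stack.pop()
            out.add(sid)
            stack.extend(self.segments[sid].children)
        return out

    def with_segments(self, new_segments: Iterable[VesselSegment]) -> "VesselNetwork":
        """Copy of the network with some segments replaced (matched by id)."""
        segs = dict(self.segments)
        for seg in new_segments:
            segs[seg.id] = seg
        return VesselNetwork(segments=segs, root_id=self.root_id)


def _check_structure(segments: Mapping[str, VesselSegment], root_id: str) -> list[str]:
    v: list[str] = []
    if not segments:
        return ["network has no segments"]
    if root_id not in segments:
        return [f"root id {root_id!r} not among segments"]
    roots = [s.id for s in segments.values() if s.parent is None]
    if roots != [root_id] and set(roots) != {root_id}:
        v.append(f"expected exactly one parentless segment ({root_id!r}), found {sorted(roots)}")
    for seg in segments.values():
        if not seg.length > 0:
            v.append(f"segment {seg.id}: nonpositive length {seg.length}")
        if not seg.radius > 0:
            v.append(f"segment {seg.id}: nonpositive radius {seg.radius}")
        if seg.stiffness is not None and not seg.stiffness > 0:
            v.append(f"segment {seg.id}: nonpositive stiffness {seg.stiffness}")
        if len(seg.children) not in (0, 2):
            v.append(
                f"segment {seg.id}: has {len(seg.children)} children "
                "(only strict bifurcations or terminals allowed)"
            )
        for c in seg.children:
            if c not in segments:
                v.append(f"segment {seg.id}: unknown child id {c!r}")
            elif segments[c].parent != seg.id:
                v.append(f"segment {c}: parent field does not match child link from {seg.id}")
        if seg.parent is not None and seg.parent not in segments:
            v.append(f"segment {seg.id}: unknown parent id {seg.parent!r}")
    # reachability / acyclicity from root via child links
    seen: set[str] = set()
    stack = [root_id]
    while stack:
        sid = stack.pop()
        if sid in seen:
            v.append(f"cycle detected at segment {sid}")
            break
        seen.add(sid)
        stack.extend(c for c in segments[sid].children if c in segments)
    unreachable = sorted(set(segments) - seen)
    for sid in unreachable:
        v.append(f"segment {sid}: unreachable from root")
    # extralobar crown must be connected and contain the root
    extra = [s for s in segments.values() if s.is_extralobar]
    if extra:
        if not segments[root_id].is_extralobar:
            v.append("extralobar crown does not contain the root")
        for seg in extra:
            if seg.parent is not None and seg.parent in segments:
                if not segments[seg.parent].is_extralobar:
                    v.append(f"segment {seg.id}: extralobar but parent {seg.parent} is not")
    return v


def validate_network(net: VesselNetwork | Mapping[str, VesselSegment]) -> list[str]:
    """Return the list of invariant violations (empty iff the network is valid)."""
    if isinstance(net, VesselNetwork):
        return _check_structure(net.segments, net.root_id)
    return _check_structure(net, next(iter(net), ""))


def build_network(segments: Iterable[VesselSegment], root_id: str | None = None) -> VesselNetwork:
    """Assemble and validate a network from a flat segment list."""
    segs = {s.id: s for s in segments}
    if root_id is None:
        roots = [s.id for s in segs.values() if s.parent is None]
        if len(roots) != 1:
            raise NetworkValidationError(
                [f"expected exactly one parentless segment, found {sorted(roots)}"]
            )
        root_id = roots[0]
    return VesselNetwork(segments=segs, root_id=root_id)


# ---------------------------------------------------------------------------
# serialization


def _segment_to_record(seg: VesselSegment) -> dict:
    rec = {
        "id": seg.id,
        "name": seg.name,
        "parent": seg.parent,
        "length_cm": seg.length,
        "radius_cm": seg.radius,
        "extralobar": seg.is_extralobar,
    }
    if seg.stiffness is not None:
        rec["eh_r0_dyn_cm2"] = seg.stiffness
    return rec


def save_network(net: VesselNetwork, path: str | Path) -> None:
    """Write a network to the package JSON dialect (or CSV if suffix is .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "name", "parent", "length_cm", "radius_cm", "extralobar"])
            for seg in net.ordered_segments():
                writer.writerow(
                    [
                        seg.id,
                        seg.name,
                        seg.parent if seg.parent is not None else "",
                        repr(float(seg.length)),
                        repr(float(seg.radius)),
                        int(seg.is_extralobar),
                    ]
                )
        return
    doc = {
        "format": NETWORK_FORMAT,
        "version": NETWORK_VERSION,
        "units": {"length": "cm", "radius": "cm", "eh_r0": "dyn/cm^2"},
        "root": net.root_id,
        "segments": [_segment_to_record(s) for s in net.ordered_segments()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _parse_float(rec: Mapping, key: str, seg_id: str) -> float:
    try:
        return float(rec[key])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"segment {seg_id!r}: missing or malformed field {key!r}") from exc


def _records_to_network(records: list[Mapping], root_id: str | None) -> VesselNetwork:
    children: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in records:
        sid = str(rec.get("id", "")).strip()
        if not sid:
            raise ValueError("segment record without an 'id' field")
        order.append(sid)
        parent = rec.get("parent")
        parent = None if parent in (None, "", "None", "null") else str(parent)
        children.setdefault(sid, [])
        if parent is not None:
            children.setdefault(parent, []).append(sid)
    segs = []
    for rec in records:
        sid = str(rec["id"]).strip()
        parent = rec.get("parent")
        parent = None if parent in (None, "", "None", "null") else str(parent)
        stiffness = rec.get("eh_r0_dyn_cm2")
        extral = rec.get("extralobar", False)
        if isinstance(extral, str):
            extral = extral.strip().lower() in ("1", "true", "yes")
        segs.append(
            VesselSegment(
                id=sid,
                name=str(rec.get("name", "") or ""),
                parent=parent,
                children=tuple(children[sid]),
                length=_parse_float(rec, "length_cm", sid),
                radius=_parse_float(rec, "radius_cm", sid),
                is_extralobar=bool(extral),
                stiffness=float(stiffness) if stiffness not in (None, "") else None,
            )
        )
    return build_network(segs, root_id)


def load_network(path: str | Path) -> VesselNetwork:
    """Load a network from the package JSON dialect or the CSV edge list.

    Raises
    ------
    ValueError
        On malformed files (naming the offending field).
    NetworkValidationError
        When the file parses but violates a structural invariant.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
        return _records_to_network(records, None)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "segments" not in doc:
        raise ValueError(f"{path}: missing 'segments' field")
    return _records_to_network(doc["segments"], doc.get("root"))


# ---------------------------------------------------------------------------
# geometry operations


def scale_extralobar_areas(
    net: VesselNetwork, measured_diastolic_areas: Mapping[str, float]
) -> VesselNetwork:
    """Rescale named extralobar vessels so pi*r0^2 matches measured areas (cm^2).

    Intralobar segments are untouched; the map keys must name extralobar
    segments (typically MPA/LPA/RPA).
    """
    by_name = {s.name: s for s in net.segments.values() if s.is_extralobar and s.name}
    updated = []
    for name, area in measured_diastolic_areas.items():
        if name not in by_name:
            raise KeyError(f"no extralobar vessel named {name!r}")
        if not area > 0:
            raise ValueError(f"nonpositive measured area for {name!r}: {area}")
        seg = by_name[name]
        updated.append(replace(seg, radius=math.sqrt(area / math.pi)))
    return net.with_segments(updated)


def poiseuille_resistance(segment: VesselSegment, mu: float) -> float:
    """Poiseuille resistance 8*mu*L/(pi*r0^4) in dyn*s/cm^5 (mu in dyn*s/cm^2)."""
    if not mu > 0:
        raise ValueError(f"viscosity must be positive, got {mu}")
    return 8.0 * mu * segment.length / (math.pi * segment.radius**4)


def terminal_segments(net: VesselNetwork) -> list[VesselSegment]:
    """All childless segments, deterministically id-sorted."""
    return [s for s in net.ordered_segments() if s.is_terminal]
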