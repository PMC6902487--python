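"""Programmatic noise/bead gating and deterministic stride subsampling.

Technical noise, cell debris and calibration beads are removed with
rectangle or polygon gates before clustering; the clean event stream is
then thinned by taking every n-th event, which preserves the (unordered)
acquisition distribution while cutting EM cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .core import EventTable

__all__ = ["GateSpec", "apply_gate", "apply_gates", "subsample_stride"]


@dataclass
class GateSpec:
    """A rectangle or polygon gate on a channel pair.

    ``shape`` is "rectangle" (vertices = two opposite corners) or "polygon"
    (>= 3 ordered vertices, channel units). ``mode`` is "keep-inside" or
    "remove-inside". Points exactly on an edge count as inside, so
    saturated edge events are never silently dropped.
    """

    channels: tuple[str, str]
    shape: str
    vertices: np.ndarray
    mode: str = "keep-inside"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.shape not in ("rectangle", "polygon"):
            raise ValueError(f"unknown gate shape {self.shape!r}")
        if self.mode not in ("keep-inside", "remove-inside"):
            raise ValueError(f"unknown gate mode {self.mode!r}")
        if self.shape == "rectangle":
            if self.vertices.shape != (2, 2):
                raise ValueError("rectangle gates take exactly two corner points")
            lo = self.vertices.min(axis=0)
            hi = self.vertices.max(axis=0)
            if np.any(lo >= hi):
                raise ValueError("rectangle corners define an empty area")
        elif len(self.vertices) < 3:
            raise ValueError("polygon gates need at least 3 vertices")

    @classmethod
    def from_dict(cls, doc: dict) -> "GateSpec":
        verts = doc.get("vertices", doc.get("corners"))
        return cls(
            channels=tuple(doc["channels"]),
            shape=doc["shape"],
            vertices=np.asarray(verts, dtype=np.float64),
            mode=doc.get("mode", "keep-inside"),
        )


def _inside(gate: GateSpec, values: np.ndarray) -> np.ndarray:
    if gate.shape == "rectangle":
        lo = gate.vertices.min(axis=0)
        hi = gate.vertices.max(axis=0)
        return np.all((values >= lo) & (values <= hi), axis=1)
    poly = shapely.Polygon(gate.vertices)
    pts = shapely.points(values)
    # covers() includes the boundary, unlike contains()
    return shapely.covers(poly, pts)


def apply_gate(events: EventTable, gate: GateSpec) -> EventTable:
    """Filter events through one gate, preserving event order."""
    if tuple(c.lower() for c in gate.channels) != tuple(
        c.lower() for c in events.channel_names
    ):
        raise ValueError(
            f"gate channels {gate.channels} do not match event channels "
            f"{events.channel_names}"
        )
    inside = _inside(gate, events.values)
    keep = inside if gate.mode == "keep-inside" else ~inside
    return EventTable(events.values[keep], events.channel_names, source=events.source)


def apply_gates(events: EventTable, gates) -> EventTable:
    for gate in gates:
        events = apply_gate(events, gate)
    return events


def subsample_stride(events: EventTable, stride: int) -> EventTable:
    """Every stride-th event (1-based indices stride, 2*stride, ...).

    Deterministic, no randomness: yields floor(n/stride) events. With
    stride 1 this is the identity.
    """
    stride = int(stride)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return EventTable(
        events.values[stride - 1 :: stride],
        events.channel_names,
        source=events.source,
    )
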