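"""Vascular network container types.

An aortic tree is represented as a directed graph of cylindrical vessel
segments with a single inlet (ascending aorta) and named outlet branches.
Branch names follow the conventional 12-branch vocabulary for an aorta
reconstructed from the ascending aorta down to the internal/external
iliac arteries:

    BT   brachiocephalic trunk        CT   celiac trunk
    LCC  left common carotid          SMA  superior mesenteric artery
    LSA  left subclavian artery       LRA / RRA  left / right renal artery
    IMA  inferior mesenteric artery   LEIA / LIIA left ext. / int. iliac
                                      REIA / RIIA right ext. / int. iliac

Dissected trunks carry parallel true-lumen (TL) / false-lumen (FL)
segment chains connected through TEAR segments across the intimal flap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "BRANCH_NAMES",
    "LumenTag",
    "StenosisSpec",
    "VesselSegment",
    "AorticNetwork",
    "ValidationError",
    "TopologyError",
]

#: Canonical branch-name vocabulary (the 12 aortic branches).
BRANCH_NAMES = (
    "BT", "LCC", "LSA", "CT", "SMA", "LRA", "RRA", "IMA",
    "REIA", "RIIA", "LEIA", "LIIA",
)

#: Branches the empirical flow-division rule cannot do without.
MANDATORY_BRANCHES = tuple(b for b in BRANCH_NAMES if b != "IMA")


class ValidationError(ValueError):
    """A network, lesion or configuration field violates its contract."""


class TopologyError(ValueError):
    """The network graph is not solvable (disconnected outlet etc.)."""


class LumenTag(str, Enum):
    NONE = "NONE"
    TL = "TL"      # true lumen
    FL = "FL"      # false lumen
    TEAR = "TEAR"  # intimal-flap tear cross-link


@dataclass(frozen=True)
class StenosisSpec:
    """Ostial/segmental narrowing expressed as an area ratio.

    Parameters
    ----------
    area_ratio : float
        Stenotic lumen area divided by the reference area, in (0, 1].
    kt : float
        Dimensionless turbulent/expansion loss coefficient of the
        quadratic pressure-loss term (classic empirical value 1.52 for
        blunt stenoses).
    """

    area_ratio: float
    kt: float = 1.52

    def __post_init__(self):
        if not (0.0 < self.area_ratio <= 1.0):
            raise ValidationError(
                f"stenosis area_ratio must be in (0, 1], got {self.area_ratio}"
            )
        if self.kt < 0:
            raise ValidationError(f"stenosis kt must be >= 0, got {self.kt}")


@dataclass
class VesselSegment:
    """One cylindrical vessel segment (the 0D analogue of a lumen reach)."""

    id: str
    from_node: str
    to_node: str
    length: float   # cm
    radius: float   # cm
    lumen_tag: LumenTag = LumenTag.NONE
    stenosis: Optional[StenosisSpec] = None

    def __post_init__(self):
        if isinstance(self.lumen_tag, str):
            self.lumen_tag = LumenTag(self.lumen_tag)
        if self.radius <= 0:
            raise ValidationError(f"segment {self.id}: radius must be > 0")
        if self.length <= 0:
            raise ValidationError(f"segment {self.id}: length must be > 0")
        if self.from_node == self.to_node:
            raise ValidationError(f"segment {self.id}: from_node == to_node")

    @property
    def area(self) -> float:
        """Lumen cross-sectional area, cm²."""
        return math.pi * self.radius**2


@dataclass
class AorticNetwork:
    """Directed vascular graph with one inlet and named outlet branches."""

    nodes: set[str]
    segments: list[VesselSegment]
    inlet_node: str
    outlets: dict[str, str]              # branch name -> outlet node
    branch_inlet_area: dict[str, float] = field(default_factory=dict)  # cm²

    def __post_init__(self):
        if not self.branch_inlet_area:
            self.branch_inlet_area = {
                b: self.first_branch_segment(b).area for b in self.outlets
            }
        self.validate()

    # -- structure ---------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s in self.segments:
            g.add_edge(s.from_node, s.to_node, segment=s)
        return g

    def segment(self, seg_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def branch_path(self, branch: str) -> list[str]:
        """Node path from the inlet to a named outlet."""
        if branch not in self.outlets:
            raise ValidationError(f"unknown branch {branch!r}")
        return nx.shortest_path(self.graph(), self.inlet_node,
                                self.outlets[branch])

    def first_branch_segment(self, branch: str) -> VesselSegment:
        """The ostial segment of a branch: the first segment past the last
        node its inlet-to-outlet path shares with any other outlet's path."""
        path = self.branch_path(branch)
        g = self.graph()
        shared: set[str] = set()
        for other, node in self.outlets.items():
            if other == branch:
                continue
            shared.update(nx.shortest_path(g, self.inlet_node, node))
        origin_idx = 0
        for i, n in enumerate(path):
            if n in shared:
                origin_idx = i
        if origin_idx + 1 >= len(path):
            raise TopologyError(f"branch {branch!r} has no private segment")
        return g.edges[path[origin_idx], path[origin_idx + 1]]["segment"]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.inlet_node not in self.nodes:
            raise ValidationError("inlet node missing from node set")
        seen_ids: set[str] = set()
        for s in self.segments:
            if s.id in seen_ids:
                raise ValidationError(f"duplicate segment id {s.id!r}")
            seen_ids.add(s.id)
            for n in (s.from_node, s.to_node):
                if n not in self.nodes:
                    raise ValidationError(
                        f"segment {s.id}: node {n!r} not in node set")
        for b, n in self.outlets.items():
            if b not in BRANCH_NAMES:
                raise ValidationError(f"unknown branch name {b!r}")
            if n not in self.nodes:
                raise ValidationError(f"outlet {b}: node {n!r} missing")
        if len(set(self.outlets.values())) != len(self.outlets):
            raise ValidationError("outlet nodes must be distinct")
        g = self.graph()
        if not nx.is_weakly_connected(g):
            raise TopologyError("network graph is not connected")
        for b, n in self.outlets.items():
            if not nx.has_path(g, self.inlet_node, n):
                raise TopologyError(f"outlet {b} unreachable from inlet")
        for b, a in self.branch_inlet_area.items():
            if a <= 0:
                raise ValidationError(f"branch {b}: inlet area must be > 0")

    # -- convenience -------------------------------------------------------

    def copy(self) -> "AorticNetwork":
        return AorticNetwork(
            nodes=set(self.nodes),
            segments=[replace(s) for s in self.segments],
            inlet_node=self.inlet_node,
            outlets=dict(self.outlets),
            branch_inlet_area=dict(self.branch_inlet_area),
        )

    def lumen_tags(self) -> set[LumenTag]:
        return {s.lumen_tag for s in self.segments}

    def stenosed_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.stenosis is not None]
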