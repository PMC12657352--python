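"""Synthetic aortic anatomy: healthy template, lesions, digital repair.

The healthy template is an abstract aortic tree covering the trunk from
the ascending aorta (station 0) to the aortic bifurcation, with the 12
named branches attached at fixed trunk stations and a left/right common
iliac segment feeding the iliac branches.  Stations are 0-based axial
indices along the trunk; there is no 3D embedding.  The trunk radius
tapers linearly with station index, which makes the repair rule
(re-interpolating a lesioned reach from the flanking unaffected
stations) exact on template-derived networks.

Lesions of three kinds can be applied:

* ``OSTIAL_STENOSIS`` — a :class:`~aortaflow.network.StenosisSpec` is
  attached to the ostial (first) segment of the named branch.  The
  stored radius is untouched; the narrowing acts purely through the
  quadratic pressure-loss law of the steady solver.
* ``FUSIFORM_ANEURYSM`` — radii over a trunk-station extent (or a
  branch's ostial segment) are multiplied by a dilation factor.
* ``DISSECTION`` — a trunk-station extent is split into parallel
  true-lumen / false-lumen chains that share the original lumen area
  and communicate through TEAR segments at specified stations; branches
  can be re-attached to the false lumen.

``repair`` is the digital analogue of the manual construction of a
near-healthy reference geometry: tears are removed, the false lumen is
merged away, lesioned radii are restored by interpolation from adjacent
unaffected stations (optionally followed by a global contraction
factor), and stenosis specs are deleted.  Bifurcation nodes and branch
names are always preserved.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .network import (
    BRANCH_NAMES,
    AorticNetwork,
    LumenTag,
    StenosisSpec,
    ValidationError,
    VesselSegment,
)

__all__ = [
    "MorphParams",
    "LesionKind",
    "LesionSpec",
    "build_healthy_template",
    "apply_lesion",
    "repair",
    "generate_cohort",
    "DEFAULT_BRANCH_MORPHOMETRY",
]

N_TRUNK_SEGMENTS = 10

#: Default branch morphometry: (radius cm, half-length cm).  Each branch
#: is built as two equal-radius segments (ostial + distal) so that the
#: ostial segment always has an unaffected neighbour for repair.
DEFAULT_BRANCH_MORPHOMETRY: dict[str, tuple[float, float]] = {
    "BT": (0.65, 2.0),
    "LCC": (0.40, 5.0),
    "LSA": (0.50, 4.0),
    "CT": (0.40, 1.5),
    "SMA": (0.45, 3.0),
    "LRA": (0.30, 2.0),
    "RRA": (0.30, 2.0),
    "IMA": (0.20, 2.5),
    "LEIA": (0.45, 6.0),
    "LIIA": (0.35, 5.0),
    "REIA": (0.45, 6.0),
    "RIIA": (0.35, 5.0),
}

#: Trunk station at which each branch originates.
BRANCH_STATIONS: dict[str, int] = {
    "BT": 1, "LCC": 2, "LSA": 3, "CT": 6, "SMA": 7,
    "LRA": 8, "RRA": 8, "IMA": 9,
}

_TRUNK_SEG_RE = re.compile(r"^T(\d+)$")
_FL_NODE_RE = re.compile(r"^fl(\d+)$")


@dataclass
class MorphParams:
    """Morphometry of the synthetic healthy template (all lengths cm)."""

    trunk_radius_in: float = 1.5    # ascending aorta
    trunk_radius_out: float = 0.85  # at the aortic bifurcation
    trunk_length: float = 35.0      # total trunk length
    common_iliac_radius: float = 0.55
    common_iliac_length: float = 5.0
    branches: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_MORPHOMETRY))
    include_ima: bool = True
    #: lognormal sigma applied (seeded) to trunk scale and per-branch
    #: radii/lengths; 0 gives the canonical deterministic template.
    jitter: float = 0.0

    def validate(self) -> None:
        for name, v in (("trunk_radius_in", self.trunk_radius_in),
                        ("trunk_radius_out", self.trunk_radius_out),
                        ("trunk_length", self.trunk_length),
                        ("common_iliac_radius", self.common_iliac_radius),
                        ("common_iliac_length", self.common_iliac_length)):
            if v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")
        for b, (r, hl) in self.branches.items():
            if b not in BRANCH_NAMES:
                raise ValidationError(f"unknown branch {b!r}")
            if r <= 0 or hl <= 0:
                raise ValidationError(
                    f"branch {b}: radius/length must be > 0, got {(r, hl)}")


class LesionKind(str, Enum):
    OSTIAL_STENOSIS = "OSTIAL_STENOSIS"
    FUSIFORM_ANEURYSM = "FUSIFORM_ANEURYSM"
    DISSECTION = "DISSECTION"


@dataclass
class LesionSpec:
    """Parameters of a single lesion; ranges enforced on use.

    ``target`` is a branch name for stenosis (and optionally for an
    aneurysm of a branch ostium) or ``"trunk"`` with a ``stations``
    extent for trunk aneurysms and dissections.
    """

    kind: LesionKind
    target: str = "trunk"
    area_ratio: Optional[float] = None    # stenosis
    kt: float = 1.52
    dilation: Optional[float] = None      # aneurysm, > 1
    stations: Optional[tuple[int, int]] = None   # [a, b) trunk extent
    tear_stations: tuple[int, ...] = ()
    tear_radius: float = 0.35
    fl_area_fraction: float = 0.55
    fl_branches: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.kind, str):
            self.kind = LesionKind(self.kind)


def _rebuild(nodes, segments, inlet, outlets) -> AorticNetwork:
    # branch_inlet_area left empty so it is recomputed from the radii
    return AorticNetwork(nodes=set(nodes), segments=list(segments),
                         inlet_node=inlet, outlets=dict(outlets))


def build_healthy_template(morph_params: MorphParams | None = None,
                           seed: int = 0) -> AorticNetwork:
    """Construct the synthetic 12-branch healthy aortic tree.

    With ``morph_params.jitter == 0`` (default) the template is a fixed,
    documented geometry; with positive jitter, a seeded lognormal factor
    perturbs the trunk scale and each branch's radius and length (the
    linear trunk taper and within-branch radius uniformity are kept, so
    repair stays exact on cohort members).
    """
    p = morph_params or MorphParams()
    p.validate()
    rng = np.random.default_rng(seed)

    def jit() -> float:
        return float(np.exp(rng.normal(0.0, p.jitter))) if p.jitter > 0 else 1.0

    trunk_scale = jit()
    n = N_TRUNK_SEGMENTS
    seg_len = p.trunk_length / n
    nodes = {f"t{i}" for i in range(n + 1)}
    segments: list[VesselSegment] = []
    for i in range(n):
        frac = i / (n - 1)
        r = (p.trunk_radius_in
             + frac * (p.trunk_radius_out - p.trunk_radius_in)) * trunk_scale
        segments.append(VesselSegment(f"T{i}", f"t{i}", f"t{i+1}",
                                      length=seg_len, radius=r))

    outlets: dict[str, str] = {}

    def add_branch(name: str, attach: str) -> None:
        r, hl = p.branches[name]
        s = jit()
        r, hl = r * s, hl * jit()
        mid, out = f"{name}_m", f"{name}_o"
        nodes.update((mid, out))
        segments.append(VesselSegment(f"{name}_1", attach, mid, hl, r))
        segments.append(VesselSegment(f"{name}_2", mid, out, hl, r))
        outlets[name] = out

    for b, st in BRANCH_STATIONS.items():
        if b == "IMA" and not p.include_ima:
            continue
        add_branch(b, f"t{st}")

    for side, tag in (("l", "L"), ("r", "R")):
        ci = f"ci{side}"
        nodes.add(ci)
        segments.append(VesselSegment(f"CI{tag}", f"t{n}", ci,
                                      p.common_iliac_length,
                                      p.common_iliac_radius * trunk_scale))
        add_branch(f"{tag}EIA", ci)
        add_branch(f"{tag}IIA", ci)

    return _rebuild(nodes, segments, "t0", outlets)


# ---------------------------------------------------------------------------
# lesions


def _trunk_segments(net: AorticNetwork) -> list[VesselSegment]:
    found = [(int(m.group(1)), s) for s in net.segments
             if (m := _TRUNK_SEG_RE.match(s.id))]
    return [s for _, s in sorted(found, key=lambda t: t[0])]


def apply_lesion(network: AorticNetwork, lesion: LesionSpec) -> AorticNetwork:
    """Return a new network with the lesion applied; input is untouched."""
    net = network.copy()
    if lesion.kind is LesionKind.OSTIAL_STENOSIS:
        if lesion.target not in net.outlets:
            raise ValidationError(f"unknown stenosis target {lesion.target!r}")
        if lesion.area_ratio is None:
            raise ValidationError("stenosis lesion requires area_ratio")
        ostial = network.first_branch_segment(lesion.target)
        for s in net.segments:
            if s.id == ostial.id:
                s.stenosis = StenosisSpec(lesion.area_ratio, lesion.kt)
        return _rebuild(net.nodes, net.segments, net.inlet_node, net.outlets)

    if lesion.kind is LesionKind.FUSIFORM_ANEURYSM:
        if lesion.dilation is None or not (1.0 < lesion.dilation <= 3.0):
            raise ValidationError("aneurysm dilation must be in (1, 3]")
        if lesion.target == "trunk":
            a, b = _check_extent(net, lesion.stations, interior=True)
            for s in _trunk_segments(net):
                i = int(_TRUNK_SEG_RE.match(s.id).group(1))
                if a <= i < b:
                    s.radius *= lesion.dilation
        else:
            if lesion.target not in net.outlets:
                raise ValidationError(
                    f"unknown aneurysm target {lesion.target!r}")
            ostial = network.first_branch_segment(lesion.target)
            for s in net.segments:
                if s.id == ostial.id:
                    s.radius *= lesion.dilation
        return _rebuild(net.nodes, net.segments, net.inlet_node, net.outlets)

    if lesion.kind is LesionKind.DISSECTION:
        return _apply_dissection(network, lesion)
    raise ValidationError(f"unknown lesion kind {lesion.kind!r}")


def _check_extent(net, stations, interior=False) -> tuple[int, int]:
    n = len(_trunk_segments(net))
    if stations is None:
        raise ValidationError("trunk lesion requires a stations extent")
    a, b = stations
    lo = 1 if interior else 0
    hi = n - 1 if interior else n
    if not (lo <= a < b <= hi):
        raise ValidationError(
            f"station extent {stations} outside valid range [{lo}, {hi}]")
    return a, b


def _apply_dissection(network: AorticNetwork, lesion: LesionSpec
                      ) -> AorticNetwork:
    net = network.copy()
    a, b = _check_extent(net, lesion.stations, interior=True)
    if not lesion.tear_stations:
        raise ValidationError("dissection requires at least one tear station")
    for s in lesion.tear_stations:
        if not (a <= s <= b):
            raise ValidationError(
                f"tear station {s} outside flap extent [{a}, {b}]")
    if not (0.0 < lesion.fl_area_fraction < 1.0):
        raise ValidationError("fl_area_fraction must be in (0, 1)")

    flf = lesion.fl_area_fraction
    ostials = {br: network.first_branch_segment(br).id
               for br in lesion.fl_branches}

    segments = net.segments
    for i in range(a, b + 1):
        net.nodes.add(f"fl{i}")
    new_segments: list[VesselSegment] = []
    for s in segments:
        m = _TRUNK_SEG_RE.match(s.id)
        if m and a <= int(m.group(1)) < b:
            i = int(m.group(1))
            # split the lumen area between TL and FL
            new_segments.append(replace(
                s, radius=s.radius * math.sqrt(1.0 - flf),
                lumen_tag=LumenTag.TL))
            new_segments.append(VesselSegment(
                f"F{i}", f"fl{i}", f"fl{i+1}", s.length,
                s.radius * math.sqrt(flf), lumen_tag=LumenTag.FL))
        else:
            new_segments.append(s)
    for s_station in sorted(set(lesion.tear_stations)):
        new_segments.append(VesselSegment(
            f"TEAR{s_station}", f"t{s_station}", f"fl{s_station}",
            length=0.2, radius=lesion.tear_radius, lumen_tag=LumenTag.TEAR))

    for br, seg_id in ostials.items():
        for s in new_segments:
            if s.id == seg_id:
                m = re.match(r"^t(\d+)$", s.from_node)
                if not m or not (a <= int(m.group(1)) <= b):
                    raise ValidationError(
                        f"branch {br} does not originate inside the flap "
                        f"extent; cannot perfuse it from the FL")
                s.from_node = f"fl{m.group(1)}"
    return _rebuild(net.nodes, new_segments, net.inlet_node, net.outlets)


# ---------------------------------------------------------------------------
# repair


def repair(diseased: AorticNetwork, contraction: float = 1.0,
           detect_margin: float = 0.05) -> AorticNetwork:
    """Digitally repair a diseased network into its near-healthy reference.

    Dissections: TEAR segments are removed, the FL chain is merged away
    and the TL radii over the flap extent are re-interpolated linearly
    (in station index) between the flanking unaffected trunk segments,
    then multiplied by ``contraction`` (default 1.0 — no contraction).
    Aneurysmal runs are detected as radii exceeding the same neighbour
    interpolation by more than ``detect_margin`` and restored likewise.
    Stenosis specs are deleted.  Branch names, outlets and bifurcation
    nodes are preserved.
    """
    for tag in diseased.lumen_tags():
        if not isinstance(tag, LumenTag):
            raise ValidationError(f"unrecognised lumen tag {tag!r}")
    net = diseased.copy()

    # --- merge dissection ------------------------------------------------
    segments = [s for s in net.segments if s.lumen_tag is not LumenTag.TEAR]
    fl_nodes = {s.from_node for s in segments if s.lumen_tag is LumenTag.FL}
    fl_nodes |= {s.to_node for s in segments if s.lumen_tag is LumenTag.FL}
    segments = [s for s in segments if s.lumen_tag is not LumenTag.FL]
    for s in segments:  # re-attach FL-perfused branches to the trunk
        m = _FL_NODE_RE.match(s.from_node)
        if m:
            s.from_node = f"t{m.group(1)}"
    nodes = net.nodes - fl_nodes

    tl_stations = sorted(int(_TRUNK_SEG_RE.match(s.id).group(1))
                         for s in segments if s.lumen_tag is LumenTag.TL)
    trunk = {int(_TRUNK_SEG_RE.match(s.id).group(1)): s
             for s in segments if _TRUNK_SEG_RE.match(s.id)}
    if tl_stations:
        a, b = tl_stations[0], tl_stations[-1] + 1
        interp = _neighbour_interp(trunk, a, b)
        for i in tl_stations:
            trunk[i].radius = interp(i) * contraction
            trunk[i].lumen_tag = LumenTag.NONE

    # --- remove stenoses -------------------------------------------------
    for s in segments:
        s.stenosis = None

    # --- detect and revert aneurysmal dilation ---------------------------
    _revert_trunk_dilation(trunk, detect_margin)
    intermediate = _rebuild(nodes, segments, net.inlet_node, net.outlets)
    _revert_branch_dilation(intermediate, detect_margin)

    return _rebuild(intermediate.nodes, intermediate.segments,
                    intermediate.inlet_node, intermediate.outlets)


def _neighbour_interp(trunk: dict[int, VesselSegment], a: int, b: int):
    """Linear radius interpolation over stations [a, b) from the flanking
    unaffected segments (constant extrapolation at the trunk ends)."""
    lo, hi = a - 1, b
    r_lo = trunk[lo].radius if lo in trunk else None
    r_hi = trunk[hi].radius if hi in trunk else None
    if r_lo is None and r_hi is None:
        raise ValidationError("lesion extent covers the entire trunk")
    if r_lo is None:
        return lambda i: r_hi
    if r_hi is None:
        return lambda i: r_lo
    return lambda i: r_lo + (i - lo) / (hi - lo) * (r_hi - r_lo)


def _revert_trunk_dilation(trunk: dict[int, VesselSegment],
                           margin: float) -> None:
    """Find maximal interior runs of radii exceeding the neighbour
    interpolation by the margin and restore them to the interpolation."""
    stations = sorted(trunk)
    a_i = 1
    while a_i < len(stations) - 1:
        reverted = False
        for b_i in range(len(stations) - 1, a_i, -1):  # widest run first
            run = stations[a_i:b_i]
            interp = _neighbour_interp(trunk, run[0], run[-1] + 1)
            if all(trunk[k].radius > interp(k) * (1 + margin) for k in run):
                for k in run:
                    trunk[k].radius = interp(k)
                a_i = b_i
                reverted = True
                break
        if not reverted:
            a_i += 1


def _revert_branch_dilation(net: AorticNetwork, margin: float) -> None:
    """Restore a dilated ostial branch segment from its unaffected
    distal neighbour (branches are two equal-radius segments)."""
    for br in net.outlets:
        s1 = net.first_branch_segment(br)
        s2 = next((s for s in net.segments
                   if s.from_node == s1.to_node and s.id != s1.id), None)
        if s2 is None:
            continue
        if s1.radius > s2.radius * (1 + margin):
            s1.radius = s2.radius


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(n: int,
                    lesion_menu: Sequence[LesionKind] | None = None,
                    seed: int = 0,
                    jitter: float = 0.03,
                    ) -> list[tuple[AorticNetwork, AorticNetwork]]:
    """Generate ``n`` (diseased, repaired-reference) network pairs.

    Each member starts from a jittered healthy template, receives one
    randomly drawn lesion from ``lesion_menu`` (default: all three
    kinds) and is paired with its digital repair.  Deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    menu = list(lesion_menu) if lesion_menu else list(LesionKind)
    if not menu:
        raise ValidationError("lesion_menu must not be empty")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        healthy = build_healthy_template(MorphParams(jitter=jitter), seed=sub)
        kind = menu[int(rng.integers(len(menu)))]
        if kind is LesionKind.OSTIAL_STENOSIS:
            lesion = LesionSpec(
                kind, target=str(rng.choice(["LCC", "CT", "SMA", "LRA",
                                             "LIIA"])),
                area_ratio=float(rng.uniform(0.15, 0.6)))
        elif kind is LesionKind.FUSIFORM_ANEURYSM:
            lesion = LesionSpec(kind, target="trunk", stations=(4, 6),
                                dilation=float(rng.uniform(1.3, 1.8)))
        else:
            fl = ("RRA",) if rng.random() < 0.5 else ()
            lesion = LesionSpec(kind, target="trunk", stations=(4, 8),
                                tear_stations=(4, 8), tear_radius=0.35,
                                fl_area_fraction=float(rng.uniform(0.45, 0.65)),
                                fl_branches=fl)
        diseased = apply_lesion(healthy, lesion)
        pairs.append((diseased, repair(diseased)))
    return pairs
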