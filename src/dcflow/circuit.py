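"""Translation of neural-circuit descriptors into chip layouts.

The framework runs in three steps: (i) a formal JSON description of the in
vivo circuit -- brain-region nodes with target neuron counts and directed
connections -- is parsed and validated; (ii) every node becomes an
inverse-designed deposition chamber, the chambers are placed on a chip whose
reservoirs snap to the 9 mm well pitch of the ANSI/SLAS microplate standard,
and every connection becomes a microchannel array between chamber borders;
(iii) ``validate_layout`` re-checks the geometric invariants so manual edits
can be iterated against it.

``allocate_electrodes`` apportions the electrodes of a substrate MEA (256 by
default) to the chambers proportionally to floor area (largest-remainder
rounding) and places them on a uniform grid inside each chamber.

The packaged worked example is the five-node basal ganglia direct pathway
(Cortex -> Striatum -> GPi/SNr -> Thalamus -> Cortex, with SNc -> Striatum),
with per-region neuron counts taken from a rat-brain volumetric table.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .designer import DesignConstraints, DeviceDesign, InfeasibleDesignError, design_device

__all__ = [
    "SCHEMA_VERSION",
    "CircuitNode",
    "CircuitEdge",
    "CircuitDescriptor",
    "CircuitValidationError",
    "PlateSpec",
    "ANSI_SLAS_96",
    "NodePlacement",
    "RealizedEdge",
    "ChipLayout",
    "parse_circuit",
    "load_circuit",
    "bg5_circuit",
    "translate",
    "allocate_electrodes",
    "validate_layout",
    "layout_to_svg",
]

SCHEMA_VERSION = "dcflow-circuit/1"
DEFAULT_MICROCHANNEL_LENGTH = 450.0e-6


@dataclass(frozen=True)
class CircuitNode:
    name: str
    target_cell_count: float
    region_volume_mm3: float | None = None


@dataclass(frozen=True)
class CircuitEdge:
    source: str
    target: str
    directionality: str = "uni"
    n_microchannels: int = 1
    microchannel_length: float = DEFAULT_MICROCHANNEL_LENGTH


@dataclass(frozen=True)
class CircuitDescriptor:
    nodes: tuple[CircuitNode, ...]
    edges: tuple[CircuitEdge, ...]
    metadata: dict = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node.name, target_cell_count=node.target_cell_count)
        for e in self.edges:
            g.add_edge(e.source, e.target)
            if e.directionality == "bi":
                g.add_edge(e.target, e.source)
        return g

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "metadata": dict(self.metadata),
            "nodes": [
                {
                    "name": n.name,
                    "target_cell_count": n.target_cell_count,
                    **(
                        {"region_volume_mm3": n.region_volume_mm3}
                        if n.region_volume_mm3 is not None
                        else {}
                    ),
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "directionality": e.directionality,
                    "n_microchannels": e.n_microchannels,
                    "microchannel_length": e.microchannel_length,
                }
                for e in self.edges
            ],
        }


class CircuitValidationError(ValueError):
    """All schema violations of a descriptor, each with its JSON-pointer path."""

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        detail = "; ".join(f"{ptr}: {msg}" for ptr, msg in errors)
        super().__init__(f"invalid circuit descriptor: {detail}")


def parse_circuit(document: str | dict) -> CircuitDescriptor:
    """Parse and validate a JSON circuit descriptor (``dcflow-circuit/1``).

    Collects *all* violations before raising, each tagged with the JSON
    pointer of the offending element.  A descriptor whose graph is not
    weakly connected is legal but triggers a warning, since a disconnected
    chip is usually a descriptor mistake.
    """
    doc = json.loads(document) if isinstance(document, str) else document
    errors: list[tuple[str, str]] = []
    if not isinstance(doc, dict):
        raise CircuitValidationError([("", "descriptor must be a JSON object")])

    schema = doc.get("schema")
    if schema is not None and schema != SCHEMA_VERSION:
        errors.append(("/schema", f"expected {SCHEMA_VERSION!r}, got {schema!r}"))

    nodes: list[CircuitNode] = []
    seen: dict[str, int] = {}
    raw_nodes = doc.get("nodes", [])
    if not isinstance(raw_nodes, list):
        errors.append(("/nodes", "must be a list"))
        raw_nodes = []
    for i, raw in enumerate(raw_nodes):
        ptr = f"/nodes/{i}"
        if not isinstance(raw, dict):
            errors.append((ptr, "node must be an object"))
            continue
        name = raw.get("name")
        if not isinstance(name, str) or not name:
            errors.append((f"{ptr}/name", "node name must be a non-empty string"))
            continue
        if name in seen:
            errors.append((f"{ptr}/name", f"duplicate node name {name!r} (first at /nodes/{seen[name]})"))
            continue
        seen[name] = i
        count = raw.get("target_cell_count")
        if not isinstance(count, (int, float)) or count < 1:
            errors.append((f"{ptr}/target_cell_count", "must be a number >= 1"))
            continue
        nodes.append(CircuitNode(name, float(count), raw.get("region_volume_mm3")))

    edges: list[CircuitEdge] = []
    raw_edges = doc.get("edges", [])
    if not isinstance(raw_edges, list):
        errors.append(("/edges", "must be a list"))
        raw_edges = []
    for i, raw in enumerate(raw_edges):
        ptr = f"/edges/{i}"
        if not isinstance(raw, dict):
            errors.append((ptr, "edge must be an object"))
            continue
        src, tgt = raw.get("source"), raw.get("target")
        ok = True
        for key, val in (("source", src), ("target", tgt)):
            if val not in seen:
                errors.append((f"{ptr}/{key}", f"unknown node {val!r}"))
                ok = False
        if ok and src == tgt:
            errors.append((ptr, f"self-loop on node {src!r}"))
            ok = False
        directionality = raw.get("directionality", "uni")
        if directionality not in ("uni", "bi"):
            errors.append((f"{ptr}/directionality", "must be 'uni' or 'bi'"))
            ok = False
        n_mc = raw.get("n_microchannels", 1)
        if not isinstance(n_mc, int) or n_mc < 1:
            errors.append((f"{ptr}/n_microchannels", "must be an integer >= 1"))
            ok = False
        mc_len = raw.get("microchannel_length", DEFAULT_MICROCHANNEL_LENGTH)
        if not isinstance(mc_len, (int, float)) or mc_len <= 0:
            errors.append((f"{ptr}/microchannel_length", "must be a positive number"))
            ok = False
        if ok:
            edges.append(CircuitEdge(src, tgt, directionality, n_mc, float(mc_len)))

    if errors:
        raise CircuitValidationError(errors)

    descriptor = CircuitDescriptor(tuple(nodes), tuple(edges), doc.get("metadata", {}))
    if len(nodes) > 1 and not nx.is_weakly_connected(descriptor.graph()):
        warnings.warn("circuit graph is not weakly connected", stacklevel=2)
    return descriptor


def load_circuit(path) -> CircuitDescriptor:
    with open(path) as fh:
        return parse_circuit(fh.read())


def bg5_circuit() -> CircuitDescriptor:
    """The packaged basal-ganglia direct-pathway worked example (5 nodes)."""
    text = importlib.resources.files("dcflow").joinpath("data/bg5_circuit.json").read_text()
    return parse_circuit(text)


@dataclass(frozen=True)
class PlateSpec:
    """ANSI/SLAS microplate footprint with a regular well grid.

    Defaults: 127.76 x 85.48 mm footprint, 96-well 9 mm pitch with well A1
    at (14.38, 11.24) mm -- the public standard's dimensions.
    """

    width: float = 0.12776
    height: float = 0.08548
    pitch: float = 0.009
    a1: tuple[float, float] = (0.01438, 0.01124)
    rows: int = 8
    cols: int = 12

    def wells(self) -> list[tuple[float, float]]:
        return [
            (self.a1[0] + j * self.pitch, self.a1[1] + i * self.pitch)
            for i in range(self.rows)
            for j in range(self.cols)
        ]


ANSI_SLAS_96 = PlateSpec()


@dataclass(frozen=True)
class NodePlacement:
    """A designed deposition chamber placed on the chip.

    ``(x, y)`` is the chamber's minimum corner; the chamber extends
    ``length`` along x (the flow direction) and ``width`` along y.
    """

    name: str
    design: DeviceDesign
    x: float
    y: float
    length: float
    width: float
    inlet_reservoir_xy: tuple[float, float]
    outlet_reservoir_xy: tuple[float, float]

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.length / 2.0, self.y + self.width / 2.0)


@dataclass(frozen=True)
class RealizedEdge:
    source: str
    target: str
    directionality: str
    n_microchannels: int
    microchannel_length: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]


@dataclass(frozen=True)
class ChipLayout:
    plate: PlateSpec
    placements: tuple[NodePlacement, ...]
    edges: tuple[RealizedEdge, ...]
    electrodes: tuple[dict, ...] | None = None
    n_electrodes: int | None = None

    def placement(self, name: str) -> NodePlacement:
        for p in self.placements:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "plate": {
                "width": self.plate.width,
                "height": self.plate.height,
                "pitch": self.plate.pitch,
                "a1": list(self.plate.a1),
                "rows": self.plate.rows,
                "cols": self.plate.cols,
            },
            "placements": [
                {
                    "name": p.name,
                    "x": p.x,
                    "y": p.y,
                    "length": p.length,
                    "width": p.width,
                    "inlet_reservoir_xy": list(p.inlet_reservoir_xy),
                    "outlet_reservoir_xy": list(p.outlet_reservoir_xy),
                    "design": p.design.to_dict(),
                }
                for p in self.placements
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "directionality": e.directionality,
                    "n_microchannels": e.n_microchannels,
                    "microchannel_length": e.microchannel_length,
                    "start_xy": list(e.start_xy),
                    "end_xy": list(e.end_xy),
                }
                for e in self.edges
            ],
            "electrodes": list(self.electrodes) if self.electrodes is not None else None,
            "n_electrodes": self.n_electrodes,
            "coordinate_convention": "origin at plate top-left corner; x along the flow/row axis, y down",
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _node_order(circuit: CircuitDescriptor) -> list[str]:
    """Topological order of the condensed graph; declaration order breaks ties
    and orders members within a strongly connected component."""
    decl = {n.name: i for i, n in enumerate(circuit.nodes)}
    g = circuit.graph()
    cond = nx.condensation(g)
    order: list[str] = []
    for scc in nx.lexicographical_topological_sort(
        cond, key=lambda s: min(decl[m] for m in cond.nodes[s]["members"])
    ):
        members = sorted(cond.nodes[scc]["members"], key=decl.__getitem__)
        order.extend(members)
    return order


def _snap_reservoir(desired: tuple[float, float], plate: PlateSpec, used: set) -> tuple[float, float]:
    """Nearest free well-grid point; ties broken by well declaration order."""
    best = None
    best_d = math.inf
    for well in plate.wells():
        if well in used:
            continue
        d = (well[0] - desired[0]) ** 2 + (well[1] - desired[1]) ** 2
        if d < best_d - 1e-18:
            best, best_d = well, d
    if best is None:
        raise InfeasibleDesignError("translate", "plate has no free reservoir positions left")
    used.add(best)
    return best


def translate(
    circuit: CircuitDescriptor,
    constraints: DesignConstraints | None = None,
    plate: PlateSpec = ANSI_SLAS_96,
) -> ChipLayout:
    """Generate a chip layout: one designed chamber per node, single row.

    Chambers are placed left-to-right following the topological order of the
    condensed circuit graph (declaration order inside cycles), spaced to fit
    the microchannel arrays; each node's reservoirs snap to the nearest free
    wells of the plate grid.  Edges are realized as straight microchannel
    arrays between the facing chamber borders.  The output is a pure
    function of the inputs (deterministic).
    """
    designs = {
        node.name: design_device(node.target_cell_count, constraints) for node in circuit.nodes
    }
    order = _node_order(circuit)

    gap = 2.0e-3
    if circuit.edges:
        gap = max(gap, max(e.microchannel_length for e in circuit.edges) + 1.0e-3)
    margin = 0.015
    y_center = plate.height / 2.0

    used_wells: set = set()
    placements: list[NodePlacement] = []
    cursor = margin
    for name in order:
        design = designs[name]
        chamber = design.network.chamber
        length = chamber.footprint_length
        width = chamber.footprint_width
        x0, y0 = cursor, y_center - width / 2.0
        if x0 + length > plate.width - margin:
            raise InfeasibleDesignError(
                "translate",
                f"chamber for node {name!r} overflows the plate footprint at x={x0 + length:.4g} m",
            )
        inlet_xy = _snap_reservoir((x0, y0 - plate.pitch), plate, used_wells)
        outlet_xy = _snap_reservoir((x0 + length, y0 + width + plate.pitch), plate, used_wells)
        placements.append(
            NodePlacement(name, design, x0, y0, length, width, inlet_xy, outlet_xy)
        )
        cursor += length + gap

    by_name = {p.name: p for p in placements}
    in_index: dict[str, int] = {}
    edges: list[RealizedEdge] = []
    for e in circuit.edges:
        src, tgt = by_name[e.source], by_name[e.target]
        k = in_index.get(e.target, 0)
        in_index[e.target] = k + 1
        off = (k % 5 - 2) * 2.0e-4  # spread parallel arrays on the border

        def _y_on(p: NodePlacement) -> float:
            lo, hi = p.y + 0.05 * p.width, p.y + 0.95 * p.width
            return min(max(p.center[1] + off, lo), hi)

        if src.center[0] <= tgt.center[0]:
            start = (src.x + src.length, _y_on(src))
            end = (tgt.x, _y_on(tgt))
        else:
            start = (src.x, _y_on(src))
            end = (tgt.x + tgt.length, _y_on(tgt))
        edges.append(
            RealizedEdge(
                e.source, e.target, e.directionality, e.n_microchannels,
                e.microchannel_length, start, end,
            )
        )
    return ChipLayout(plate, tuple(placements), tuple(edges))


def allocate_electrodes(layout: ChipLayout, n_electrodes: int = 256) -> ChipLayout:
    """Apportion MEA electrodes to chambers by floor area, largest remainder.

    Each chamber receives electrodes on a uniform rectangular sub-grid of
    its footprint; the assignment sums to exactly ``n_electrodes`` and the
    per-node count deviates from exact area proportionality by less than
    one electrode.
    """
    n_nodes = len(layout.placements)
    if n_electrodes < n_nodes:
        raise ValueError(
            f"n_electrodes={n_electrodes} is below the node count {n_nodes}"
        )
    if n_nodes == 0:
        return replace(layout, electrodes=(), n_electrodes=n_electrodes)

    areas = np.array([p.length * p.width for p in layout.placements])
    quota = n_electrodes * areas / areas.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_electrodes - counts.sum()
    for i in sorted(range(n_nodes), key=lambda i: (-remainder[i], i))[:short]:
        counts[i] += 1

    electrodes: list[dict] = []
    eid = 0
    for p, k in zip(layout.placements, counts):
        if k == 0:
            continue
        cols = max(1, math.ceil(math.sqrt(k * p.length / p.width)))
        rows = math.ceil(k / cols)
        placed = 0
        for i in range(rows):
            for j in range(cols):
                if placed >= k:
                    break
                electrodes.append(
                    {
                        "id": eid,
                        "x": p.x + (j + 0.5) * p.length / cols,
                        "y": p.y + (i + 0.5) * p.width / rows,
                        "node": p.name,
                    }
                )
                eid += 1
                placed += 1
    return replace(layout, electrodes=tuple(electrodes), n_electrodes=n_electrodes)


def _rects_overlap(a: NodePlacement, b: NodePlacement) -> bool:
    return not (
        a.x + a.length <= b.x
        or b.x + b.length <= a.x
        or a.y + a.width <= b.y
        or b.y + b.width <= a.y
    )


def _on_border(point: tuple[float, float], p: NodePlacement, tol: float = 1e-9) -> bool:
    x, y = point
    on_v = (abs(x - p.x) <= tol or abs(x - (p.x + p.length)) <= tol) and (
        p.y - tol <= y <= p.y + p.width + tol
    )
    on_h = (abs(y - p.y) <= tol or abs(y - (p.y + p.width)) <= tol) and (
        p.x - tol <= x <= p.x + p.length + tol
    )
    return on_v or on_h


def validate_layout(layout: ChipLayout) -> dict:
    """Machine-readable pass/fail per geometric invariant; never raises.

    Intended as the feedback loop of the framework's verification step, so
    hand-edited layouts can be re-checked against the same rules the
    generator guarantees.
    """
    report: dict[str, dict] = {}

    overlaps = [
        (a.name, b.name)
        for i, a in enumerate(layout.placements)
        for b in layout.placements[i + 1 :]
        if _rects_overlap(a, b)
    ]
    report["overlap"] = {
        "passed": not overlaps,
        "detail": f"overlapping chambers: {overlaps}" if overlaps else "no chamber overlap",
    }

    plate = layout.plate
    off_grid = []
    for p in layout.placements:
        for xy in (p.inlet_reservoir_xy, p.outlet_reservoir_xy):
            dx = (xy[0] - plate.a1[0]) / plate.pitch
            dy = (xy[1] - plate.a1[1]) / plate.pitch
            if abs(dx - round(dx)) > 1e-9 or abs(dy - round(dy)) > 1e-9:
                off_grid.append((p.name, xy))
    report["grid_snap"] = {
        "passed": not off_grid,
        "detail": f"reservoirs off the {plate.pitch * 1e3:g} mm grid: {off_grid}"
        if off_grid
        else "all reservoirs on the well grid",
    }

    outside = [
        p.name
        for p in layout.placements
        if p.x < 0 or p.y < 0 or p.x + p.length > plate.width or p.y + p.width > plate.height
    ]
    for p in layout.placements:
        for xy in (p.inlet_reservoir_xy, p.outlet_reservoir_xy):
            if not (0 <= xy[0] <= plate.width and 0 <= xy[1] <= plate.height):
                outside.append(p.name)
    report["footprint"] = {
        "passed": not outside,
        "detail": f"elements outside the footprint: {sorted(set(outside))}"
        if outside
        else "all elements inside the plate footprint",
    }

    bad_edges = []
    names = {p.name for p in layout.placements}
    for e in layout.edges:
        if e.source not in names or e.target not in names:
            bad_edges.append((e.source, e.target, "endpoint node missing"))
            continue
        if not _on_border(e.start_xy, layout.placement(e.source)):
            bad_edges.append((e.source, e.target, "start not on source border"))
        if not _on_border(e.end_xy, layout.placement(e.target)):
            bad_edges.append((e.source, e.target, "end not on target border"))
    report["edges"] = {
        "passed": not bad_edges,
        "detail": f"misrealized edges: {bad_edges}" if bad_edges else "all edges span chamber borders",
    }

    if layout.electrodes is None:
        report["electrodes"] = {"passed": True, "detail": "no electrode assignment present"}
    else:
        problems = []
        if layout.n_electrodes is not None and len(layout.electrodes) != layout.n_electrodes:
            problems.append(
                f"total {len(layout.electrodes)} != declared {layout.n_electrodes}"
            )
        for el in layout.electrodes:
            try:
                p = layout.placement(el["node"])
            except KeyError:
                problems.append(f"electrode {el['id']} on unknown node {el['node']!r}")
                continue
            if not (p.x <= el["x"] <= p.x + p.length and p.y <= el["y"] <= p.y + p.width):
                problems.append(f"electrode {el['id']} outside chamber {el['node']!r}")
        report["electrodes"] = {
            "passed": not problems,
            "detail": "; ".join(problems) if problems else "electrode assignment consistent",
        }

    report["all_passed"] = {
        "passed": all(v["passed"] for k, v in report.items() if k != "all_passed"),
        "detail": "aggregate of all checks",
    }
    return report


def layout_to_svg(layout: ChipLayout) -> str:
    """Render the layout (chambers, reservoirs, edges, electrodes) as SVG."""
    scale = 4000.0  # px per m (4 px/mm)
    plate = layout.plate
    w, h = plate.width * scale, plate.height * scale
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
        f'viewBox="0 0 {w:.2f} {h:.2f}">',
        f'<rect x="0" y="0" width="{w:.2f}" height="{h:.2f}" fill="white" '
        'stroke="black" stroke-width="1"/>',
    ]
    for well in plate.wells():
        parts.append(
            f'<circle cx="{well[0] * scale:.2f}" cy="{well[1] * scale:.2f}" r="2" '
            'fill="none" stroke="#cccccc" stroke-width="0.5"/>'
        )
    for e in layout.edges:
        (x1, y1), (x2, y2) = e.start_xy, e.end_xy
        parts.append(
            f'<line x1="{x1 * scale:.2f}" y1="{y1 * scale:.2f}" x2="{x2 * scale:.2f}" '
            f'y2="{y2 * scale:.2f}" stroke="#d62728" stroke-width="1.2"/>'
        )
    for p in layout.placements:
        parts.append(
            f'<rect x="{p.x * scale:.2f}" y="{p.y * scale:.2f}" '
            f'width="{p.length * scale:.2f}" height="{p.width * scale:.2f}" '
            'fill="#aec7e8" fill-opacity="0.6" stroke="#1f77b4" stroke-width="1"/>'
        )
        cx, cy = p.center
        parts.append(
            f'<text x="{cx * scale:.2f}" y="{cy * scale:.2f}" font-size="8" '
            f'text-anchor="middle">{p.name}</text>'
        )
        for xy, color in ((p.inlet_reservoir_xy, "#2ca02c"), (p.outlet_reservoir_xy, "#ff7f0e")):
            parts.append(
                f'<circle cx="{xy[0] * scale:.2f}" cy="{xy[1] * scale:.2f}" r="8" '
                f'fill="none" stroke="{color}" stroke-width="1.5"/>'
            )
    if layout.electrodes:
        for el in layout.electrodes:
            parts.append(
                f'<circle cx="{el["x"] * scale:.2f}" cy="{el["y"] * scale:.2f}" r="1" '
                'fill="#333333"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts)
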