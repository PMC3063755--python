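"""Neuron morphologies: trees of cylindrical sections, SWC I/O, toy builders.

A :class:`Neuron` is a tree of :class:`Section` objects.  Each section is a
contiguous polyline of 3-D points (um) with one diameter per interval and a
mechanism tag ('hh', 'passive', 'myelin', 'node', ...) that the engine maps
to membrane parameters.  All the simple geometries used in the stimulation
experiments (straight axon, bent / bifurcating / diameter-stepped dendrite
cells, soma with n dendrites, soma with a myelinated axon) have builders
here; arbitrary morphologies come in through SWC.

Somata given as a single point (or by diameter only) are represented as a
cylinder with length equal to its diameter, which has the same membrane area
as the sphere of that diameter.

All coordinates are micrometres.  Geometries built here are planar (z = 0);
the induced-field evaluation uses only (x, y).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np

__all__ = [
    "Segment",
    "Section",
    "Neuron",
    "SWCError",
    "load_swc",
    "save_swc",
    "rall_daughter_diameter",
    "straight_axon",
    "bent_dendrite_cell",
    "bifurcation_cell",
    "diameter_step_cell",
    "soma_n_dendrites",
    "soma_myelinated_axon",
    "build_toy",
    "place",
]


class Segment(NamedTuple):
    """One cylindrical piece of a section: endpoints (um) and diameter (um)."""

    p_start: np.ndarray
    p_end: np.ndarray
    diameter: float
    section: "Section"

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_end - self.p_start))

    @property
    def direction(self) -> np.ndarray:
        d = self.p_end - self.p_start
        return d / np.linalg.norm(d)


@dataclass(eq=False)
class Section:
    """A contiguous unbranched run of cylinders with a mechanism tag.

    ``points`` is (n >= 2, 3) in um; ``diams`` has one entry per interval.
    ``parent_pos`` is the arclength fraction along the parent at which this
    section attaches (0 = parent start, 1 = parent end).
    """

    name: str
    points: np.ndarray
    diams: np.ndarray
    mechanism: str = "passive"
    parent: "Section | None" = None
    parent_pos: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.diams = np.atleast_1d(np.asarray(self.diams, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError(f"section {self.name}: points must be (n>=2, 3)")
        if self.diams.shape[0] != self.points.shape[0] - 1:
            raise ValueError(
                f"section {self.name}: need one diameter per interval "
                f"({self.points.shape[0] - 1}), got {self.diams.shape[0]}"
            )
        if np.any(self.diams <= 0):
            raise ValueError(f"section {self.name}: diameters must be > 0")
        seg_len = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg_len <= 0):
            raise ValueError(f"section {self.name}: zero-length interval")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def segments(self) -> list[Segment]:
        return [
            Segment(self.points[i], self.points[i + 1], float(self.diams[i]), self)
            for i in range(len(self.diams))
        ]

    def membrane_area(self) -> float:
        """Lateral cylinder area, um^2."""
        seg_len = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return float(np.sum(np.pi * self.diams * seg_len))


@dataclass
class Neuron:
    """A connected tree of sections; ``sections[0]`` is the root."""

    sections: list[Section] = dc_field(default_factory=list)
    planar: bool = True

    def __post_init__(self) -> None:
        self.validate()

    @property
    def root(self) -> Section:
        return self.sections[0]

    def validate(self) -> None:
        if not self.sections:
            raise ValueError("neuron has no sections")
        secset = set(id(s) for s in self.sections)
        n_root = 0
        for s in self.sections:
            if s.parent is None:
                n_root += 1
            elif id(s.parent) not in secset:
                raise ValueError(f"section {s.name}: parent not in neuron")
        if n_root != 1:
            raise ValueError(f"neuron must have exactly one root, found {n_root}")
        # cycle check via parent chains
        for s in self.sections:
            seen = set()
            node = s
            while node is not None:
                if id(node) in seen:
                    raise ValueError("cycle detected in section tree")
                seen.add(id(node))
                node = node.parent
        if self.planar and any(np.any(s.points[:, 2] != 0) for s in self.sections):
            raise ValueError("planar neuron has nonzero z coordinates")

    def segments(self) -> list[Segment]:
        out: list[Segment] = []
        for s in self.sections:
            out.extend(s.segments)
        return out

    def total_length(self) -> float:
        return float(sum(s.length for s in self.sections))

    def membrane_area(self) -> float:
        return float(sum(s.membrane_area() for s in self.sections))

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(f"no section named {name!r}")

    def copy(self) -> "Neuron":
        mapping: dict[int, Section] = {}
        new_secs = []
        for s in self.sections:
            ns = Section(
                s.name,
                s.points.copy(),
                s.diams.copy(),
                s.mechanism,
                None,
                s.parent_pos,
            )
            mapping[id(s)] = ns
            new_secs.append(ns)
        for s, ns in zip(self.sections, new_secs):
            if s.parent is not None:
                ns.parent = mapping[id(s.parent)]
        return Neuron(new_secs, planar=self.planar)


# ---------------------------------------------------------------------------
# SWC I/O


class SWCError(ValueError):
    pass


_SWC_TYPE_TAG = {1: "soma", 2: "axon", 3: "dend", 4: "apic"}


def load_swc(source) -> Neuron:
    """Read a 7-column SWC file (or stream, or text) into a Neuron.

    Radii become diameters (x2).  The tree is split into unbranched sections
    at branch points; the SWC type code sets the mechanism tag ('soma',
    'axon', 'dend', 'apic'; other codes get 'dend').  A single-point soma is
    expanded into a sphere-area-equivalent cylinder (length = diameter) along
    +x from the point.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("#"):
            with open(text) as fh:
                text = fh.read()

    ids: dict[int, dict] = {}
    order: list[int] = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            typ = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from exc
        if r <= 0:
            raise SWCError(f"line {lineno}: non-positive radius {r}")
        if parent != -1 and parent not in ids:
            raise SWCError(f"line {lineno}: unknown parent id {parent}")
        if nid in ids:
            raise SWCError(f"line {lineno}: duplicate id {nid}")
        ids[nid] = dict(id=nid, typ=typ, p=np.array([x, y, z]), d=2 * r, parent=parent)
        order.append(nid)
    if not order:
        raise SWCError("empty SWC input")

    children: dict[int, list[int]] = {}
    roots = []
    for nid in order:
        pid = ids[nid]["parent"]
        if pid == -1:
            roots.append(nid)
        else:
            children.setdefault(pid, []).append(nid)
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root point, found {len(roots)}")

    sections: list[Section] = []
    planar = all(ids[n]["p"][2] == 0 for n in order)

    root = ids[roots[0]]
    sec_of_point: dict[int, Section] = {}
    counter = [0]

    def new_name(tag: str) -> str:
        counter[0] += 1
        return f"{tag}_{counter[0]}"

    root_children = children.get(root["id"], [])
    if root["typ"] == 1 and (
        not root_children or all(ids[c]["typ"] != 1 for c in root_children)
    ):
        # single-point soma: sphere-equivalent cylinder along +x
        d = root["d"]
        p = root["p"]
        pts = np.array([p - [d / 2, 0, 0], p + [d / 2, 0, 0]])
        soma = Section(new_name("soma"), pts, [d], "soma")
        sections.append(soma)
        sec_of_point[root["id"]] = soma
        stack = [(c, soma) for c in root_children]
    else:
        stack = [(c, None) for c in root_children]
        sec_of_point[root["id"]] = None  # type: ignore[assignment]

    # walk unbranched runs
    while stack:
        start_id, parent_sec = stack.pop()
        run = [ids[start_id]["parent"], start_id]
        while True:
            kids = children.get(run[-1], [])
            # unbranched runs also split where the SWC type changes
            if len(kids) == 1 and ids[kids[0]]["typ"] == ids[start_id]["typ"]:
                run.append(kids[0])
            else:
                break
        pts = np.array([ids[n]["p"] for n in run])
        dias = np.array([ids[n]["d"] for n in run[1:]])
        tag = _SWC_TYPE_TAG.get(ids[run[1]]["typ"], "dend")
        sec = Section(new_name(tag), pts, dias, tag, parent_sec, 1.0)
        if parent_sec is None and sections:
            sec.parent = sections[0]
        sections.append(sec)
        for n in run[1:]:
            sec_of_point[n] = sec
        for kid in children.get(run[-1], []):
            stack.append((kid, sec))

    # orphaned first section becomes root
    if sections and sections[0].parent is not None and all(
        s.parent is not None for s in sections
    ):
        sections[0].parent = None
    return Neuron(sections, planar=planar)


def save_swc(neuron: Neuron, path_or_stream) -> None:
    """Write a Neuron as 7-column SWC (one point per segment endpoint)."""
    lines = ["# SWC written by magcable"]
    nid = 0
    tag_code = {v: k for k, v in _SWC_TYPE_TAG.items()}
    last_id_of_sec: dict[int, int] = {}
    for sec in neuron.sections:
        typ = tag_code.get(sec.mechanism, 3)
        prev_id = last_id_of_sec.get(id(sec.parent), -1) if sec.parent else -1
        for i, p in enumerate(sec.points):
            if i == 0 and sec.parent is not None:
                # SWC shares the attachment point with the parent: skip the
                # duplicate first point, reference the parent's last id
                continue
            d = sec.diams[min(max(i - 1, 0), len(sec.diams) - 1)]
            nid += 1
            lines.append(
                f"{nid} {typ} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {d / 2:.6f} {prev_id}"
            )
            prev_id = nid
        last_id_of_sec[id(sec)] = nid
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Rall law and toy builders


def rall_daughter_diameter(parent_d: float, n_daughters: int = 2) -> float:
    """Equal-daughter diameter from Rall's 3/2-power law.

    Solves n * d^(3/2) = parent_d^(3/2), i.e. d = parent_d / n^(2/3), the
    impedance-matching branching rule.
    """
    if parent_d <= 0:
        raise ValueError("parent diameter must be > 0")
    if n_daughters < 1:
        raise ValueError("need at least one daughter")
    return parent_d / n_daughters ** (2.0 / 3.0)


def _soma_section(diameter: float, center=(0.0, 0.0, 0.0)) -> Section:
    """Soma as a cylinder of length = diameter along x, centred at ``center``."""
    if diameter <= 0:
        raise ValueError("soma diameter must be > 0")
    c = np.asarray(center, dtype=float)
    pts = np.array([c - [diameter / 2, 0, 0], c + [diameter / 2, 0, 0]])
    return Section("soma", pts, [diameter], "soma")


def straight_axon(diameter: float, length: float, mechanism: str = "axon") -> Neuron:
    """A straight axon along x, centred on the origin.  Units um."""
    if diameter <= 0 or length <= 0:
        raise ValueError("diameter and length must be > 0")
    pts = np.array([[-length / 2, 0, 0], [length / 2, 0, 0]], dtype=float)
    return Neuron([Section("axon", pts, [diameter], mechanism)])


def _dir(theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    return np.array([np.cos(th), np.sin(th), 0.0])


def bent_dendrite_cell(
    soma_d: float,
    dend_d: float,
    theta_deg: float,
    lengths: tuple[float, float] = (300.0, 300.0),
) -> Neuron:
    """Soma plus a passive dendrite with a single bend.

    The dendrite leaves the soma along +x for ``lengths[0]`` um, then turns
    by ``theta_deg`` (the angle between the second leg and the continuation
    of the first) for ``lengths[1]`` um.  theta = 0 reproduces the unbent
    cell exactly.
    """
    if not (0.0 <= theta_deg <= 180.0):
        raise ValueError("bend angle must be within [0, 180] degrees")
    if dend_d <= 0 or min(lengths) <= 0:
        raise ValueError("dendrite diameter and lengths must be > 0")
    soma = _soma_section(soma_d)
    p0 = soma.points[-1]
    p1 = p0 + lengths[0] * _dir(0.0)
    p2 = p1 + lengths[1] * _dir(theta_deg)
    dend = Section("dend", np.array([p0, p1, p2]), [dend_d, dend_d], "dend", soma, 1.0)
    return Neuron([soma, dend])


def bifurcation_cell(
    soma_d: float,
    dend_d: float,
    theta_deg: float,
    rall: bool = True,
    lengths: tuple[float, float] = (300.0, 300.0),
    daughter_d: float | None = None,
) -> Neuron:
    """Soma, a primary dendrite, and a symmetric bifurcation of angle theta.

    ``theta_deg`` is the angle between the two daughters; with ``rall`` the
    daughter diameter follows the 3/2-power law, otherwise ``daughter_d``
    (default: equal to the parent).
    """
    if not (0.0 <= theta_deg <= 180.0):
        raise ValueError("bifurcation angle must be within [0, 180] degrees")
    soma = _soma_section(soma_d)
    p0 = soma.points[-1]
    p1 = p0 + lengths[0] * _dir(0.0)
    trunk = Section("dend", np.array([p0, p1]), [dend_d], "dend", soma, 1.0)
    if rall:
        dd = rall_daughter_diameter(dend_d, 2)
    else:
        dd = daughter_d if daughter_d is not None else dend_d
    half = theta_deg / 2.0
    d1 = Section(
        "daughter_a",
        np.array([p1, p1 + lengths[1] * _dir(half)]),
        [dd],
        "dend",
        trunk,
        1.0,
    )
    d2 = Section(
        "daughter_b",
        np.array([p1, p1 + lengths[1] * _dir(-half)]),
        [dd],
        "dend",
        trunk,
        1.0,
    )
    return Neuron([soma, trunk, d1, d2])


def diameter_step_cell(
    soma_d: float,
    d1: float,
    ratio: float = 1.0,
    d2: float | None = None,
    lengths: tuple[float, float] = (300.0, 300.0),
) -> Neuron:
    """Soma plus a straight dendrite whose diameter steps from d1 to d2 = d1*ratio."""
    if d2 is None:
        d2 = d1 * ratio
    if d1 <= 0 or d2 <= 0:
        raise ValueError("diameters must be > 0")
    soma = _soma_section(soma_d)
    p0 = soma.points[-1]
    p1 = p0 + lengths[0] * _dir(0.0)
    p2 = p1 + lengths[1] * _dir(0.0)
    dend = Section("dend", np.array([p0, p1, p2]), [d1, d2], "dend", soma, 1.0)
    return Neuron([soma, dend])


def soma_n_dendrites(
    soma_d: float, dend_d: float, n: int, dend_len: float = 600.0
) -> Neuron:
    """A soma with ``n`` passive dendrites at equal angular spacing in the plane.

    All dendrites attach electrically at the soma midpoint and radiate from
    the soma centre.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if dend_d <= 0 or dend_len <= 0:
        raise ValueError("dendrite diameter and length must be > 0")
    soma = _soma_section(soma_d)
    sections = [soma]
    center = 0.5 * (soma.points[0] + soma.points[-1])
    for k in range(n):
        ang = 360.0 * k / n if n else 0.0
        p0 = center
        p1 = center + dend_len * _dir(ang)
        sections.append(
            Section(f"dend_{k}", np.array([p0, p1]), [dend_d], "dend", soma, 0.5)
        )
    return Neuron(sections)


def soma_myelinated_axon(
    soma_d: float = 20.0,
    internode_d: float = 1.0,
    node_d: float = 0.75,
    internode_len: float = 100.0,
    node_len: float = 1.0,
    n_internodes: int = 198,
) -> Neuron:
    """Soma with a long straight myelinated axon along +x.

    Alternating myelinated internodes and nodes of Ranvier; excitable (HH)
    membrane at the soma and nodes, myelin elsewhere.  Defaults follow the
    20 um soma / 1 um x 100 um internode / 0.75 um x 1 um node geometry, with
    enough internodes for about 2 cm of axon.
    """
    if min(soma_d, internode_d, node_d, internode_len, node_len) <= 0:
        raise ValueError("all diameters and lengths must be > 0")
    if n_internodes < 1:
        raise ValueError("need at least one internode")
    soma = _soma_section(soma_d)
    sections = [soma]
    parent = soma
    x = soma.points[-1].copy()
    for k in range(n_internodes):
        p1 = x + np.array([internode_len, 0, 0])
        inter = Section(
            f"internode_{k}", np.array([x, p1]), [internode_d], "myelin", parent, 1.0
        )
        sections.append(inter)
        parent, x = inter, p1
        if k < n_internodes - 1:
            p2 = x + np.array([node_len, 0, 0])
            node = Section(
                f"node_{k}", np.array([x, p2]), [node_d], "node", parent, 1.0
            )
            sections.append(node)
            parent, x = node, p2
    return Neuron(sections)


_BUILDERS = {
    "straight_axon": straight_axon,
    "bent_dendrite_cell": bent_dendrite_cell,
    "bifurcation_cell": bifurcation_cell,
    "diameter_step_cell": diameter_step_cell,
    "soma_n_dendrites": soma_n_dendrites,
    "soma_myelinated_axon": soma_myelinated_axon,
}


def build_toy(spec: dict) -> Neuron:
    """Build a toy geometry from a descriptor ``{'kind': ..., params...}``."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in _BUILDERS:
        raise ValueError(f"unknown toy geometry {kind!r}; options: {sorted(_BUILDERS)}")
    return _BUILDERS[kind](**spec)


def place(neuron: Neuron, offset_cm=(0.0, 0.0), rotation_deg: float = 0.0) -> Neuron:
    """Rigidly transform a planar neuron in its plane.

    Rotates by ``rotation_deg`` about the z-axis through the root section's
    first point, then translates by ``offset_cm`` (centimetres, converted to
    um internally).  Connectivity and diameters are untouched.
    """
    if not neuron.planar:
        raise ValueError("place() requires a planar neuron")
    out = neuron.copy()
    pivot = out.root.points[0].copy()
    th = np.radians(rotation_deg)
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    shift = np.array([offset_cm[0] * 1e4, offset_cm[1] * 1e4, 0.0])
    for sec in out.sections:
        sec.points = (sec.points - pivot) @ rot.T + pivot + shift
    return out
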