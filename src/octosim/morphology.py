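"""Synthetic octopus-cell morphology: soma plus thick unidirectional dendrites.

Octopus cells of the posteroventral cochlear nucleus extend a small number of
large-calibre, sparsely branched dendrites across the tonotopically ordered
array of auditory-nerve fibers.  The model morphology built here is a
deliberately minimal stand-in for a reconstructed cell: one isopotential soma
and a configurable number of unbranched, linearly tapering dendrites whose
total membrane areas are solved exactly from target values.  The default
area targets (soma 1526 um^2, dendrites 7775 um^2) are the unique pair for
which the measured innervation densities reproduce the measured synapse
totals, so anatomy arithmetic downstream is self-consistent.

Sections are frusta (linear taper); surface areas use the frustum lateral
area, with the soma counted as a closed surface (lateral plus both end
caps).  Morphologies round-trip through standard 7-column SWC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "TreeLocation",
    "MorphologyParams",
    "AreaReport",
    "GeometryError",
    "SWCFormatError",
    "build_octopus_morphology",
    "surface_areas",
    "path_distance",
    "locate_at_normalized_distance",
    "longest_dendrite_path",
    "dendrite_paths",
    "read_swc",
    "write_swc",
]

#: Default area targets (um^2).  Solving
#:   13.3*As/100 + 10.7*Ad/100 = 1035   (excitatory synapse budget)
#:    1.8*As/100 +  4.2*Ad/100 =  354   (glycinergic synapse budget)
#: gives As ~ 1526 um^2 and Ad ~ 7775 um^2.
DEFAULT_SOMA_AREA = 1526.0
DEFAULT_DENDRITE_AREA = 7775.0


class GeometryError(ValueError):
    """Requested geometry is infeasible (e.g. taper implies negative size)."""


class SWCFormatError(ValueError):
    """Malformed SWC record; message carries the offending line number."""


@dataclass(frozen=True)
class Section:
    """A frustum-shaped piece of membrane.

    ``diam_proximal``/``diam_distal`` are the diameters at the parent-facing
    and tip-facing ends (um); diameter varies linearly in between.  ``nseg``
    is the number of equal-length electrical segments the cable solver will
    use for this section.
    """

    id: int
    parent_id: int | None
    kind: str  # "soma" | "dendrite"
    length: float  # um
    diam_proximal: float  # um
    diam_distal: float  # um
    nseg: int = 1

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError(f"section {self.id}: length must be > 0")
        if self.diam_proximal <= 0 or self.diam_distal <= 0:
            raise GeometryError(f"section {self.id}: diameters must be > 0")
        if self.nseg < 1:
            raise GeometryError(f"section {self.id}: nseg must be >= 1")
        if self.kind not in ("soma", "dendrite"):
            raise ValueError(f"section {self.id}: unknown kind {self.kind!r}")

    def diam_at(self, frac: float) -> float:
        """Diameter (um) at normalized position ``frac`` in [0, 1]."""
        return self.diam_proximal + (self.diam_distal - self.diam_proximal) * frac

    def lateral_area(self, frac0: float = 0.0, frac1: float = 1.0) -> float:
        """Frustum lateral surface area (um^2) between two fractions."""
        d0, d1 = self.diam_at(frac0), self.diam_at(frac1)
        dx = self.length * (frac1 - frac0)
        slant = math.hypot(dx, (d0 - d1) / 2.0)
        return math.pi * (d0 + d1) / 2.0 * slant

    def membrane_area(self) -> float:
        """Total membrane area (um^2); soma sections count end caps."""
        area = self.lateral_area()
        if self.kind == "soma":
            area += math.pi * (self.diam_proximal / 2.0) ** 2
            area += math.pi * (self.diam_distal / 2.0) ** 2
        return area


@dataclass(frozen=True)
class TreeLocation:
    """A point on the tree: a section id and a fraction along it."""

    section_id: int
    frac: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac <= 1.0:
            raise ValueError(f"frac must lie in [0, 1], got {self.frac}")


@dataclass(frozen=True)
class AreaReport:
    soma_area: float  # um^2
    dendrite_area: float  # um^2

    @property
    def total(self) -> float:
        return self.soma_area + self.dendrite_area


@dataclass
class Morphology:
    """A validated tree of sections with exactly one soma root."""

    sections: dict[int, Section]
    primary_dendrite_count: int = 0
    #: All primary dendrites exit through one hemisphere (the hallmark
    #: unidirectional arbor); metadata only, no electrical consequence.
    exit_hemisphere: str = "+x"

    def __post_init__(self) -> None:
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1 or roots[0].kind != "soma":
            raise ValueError("exactly one root section of kind 'soma' required")
        somas = [s for s in self.sections.values() if s.kind == "soma"]
        if len(somas) != 1:
            raise ValueError("exactly one soma section required")
        # Parent links must form a tree.
        for s in self.sections.values():
            if s.parent_id is None:
                continue
            if s.parent_id not in self.sections:
                raise ValueError(f"section {s.id}: unknown parent {s.parent_id}")
            seen = {s.id}
            pid: int | None = s.parent_id
            while pid is not None:
                if pid in seen:
                    raise ValueError(f"cycle detected through section {s.id}")
                seen.add(pid)
                pid = self.sections[pid].parent_id

    @property
    def soma(self) -> Section:
        return next(s for s in self.sections.values() if s.kind == "soma")

    def children(self, section_id: int) -> list[Section]:
        return [s for s in self.sections.values() if s.parent_id == section_id]

    def section(self, section_id: int) -> Section:
        return self.sections[section_id]


@dataclass(frozen=True)
class MorphologyParams:
    """Targets and shape parameters for the synthetic cell.

    Dendrite lengths are solved from the area target given the fixed taper,
    so the area invariant holds exactly by construction.
    """

    soma_area: float = DEFAULT_SOMA_AREA  # um^2, closed surface
    dendrite_area: float = DEFAULT_DENDRITE_AREA  # um^2, lateral, all dendrites
    primary_dendrite_count: int = 4
    diam_proximal: float = 5.0  # um
    diam_distal: float = 1.5  # um
    max_segment_length: float = 10.0  # um; matches the 10-um density bins


def build_octopus_morphology(params: MorphologyParams | None = None) -> Morphology:
    """Construct the reference morphology deterministically from ``params``.

    The soma is a cylinder of length equal to its diameter whose *closed*
    surface equals the soma area target; each primary dendrite is a single
    tapered frustum whose length is solved so its lateral area equals an
    equal share of the dendritic area target.
    """
    p = params or MorphologyParams()
    if p.soma_area <= 0:
        raise GeometryError("soma area target must be positive")
    if p.dendrite_area < 0:
        raise GeometryError("dendrite area target must be nonnegative")
    if p.dendrite_area > 0 and p.primary_dendrite_count < 1:
        raise GeometryError("need at least one primary dendrite")

    # Closed cylinder with L = D: area = pi*D*L + 2*pi*(D/2)^2 = 1.5*pi*D^2.
    soma_diam = math.sqrt(p.soma_area / (1.5 * math.pi))
    sections: dict[int, Section] = {
        0: Section(0, None, "soma", length=soma_diam,
                   diam_proximal=soma_diam, diam_distal=soma_diam, nseg=1)
    }

    n_dend = p.primary_dendrite_count if p.dendrite_area > 0 else 0
    for k in range(n_dend):
        target = p.dendrite_area / n_dend
        r0, r1 = p.diam_proximal / 2.0, p.diam_distal / 2.0
        # lateral = pi*(r0+r1)*slant with slant = sqrt(L^2 + (r0-r1)^2)
        slant = target / (math.pi * (r0 + r1))
        under = slant * slant - (r0 - r1) ** 2
        if under <= 0:
            raise GeometryError(
                f"dendrite {k + 1}: taper {p.diam_proximal}->{p.diam_distal} um "
                f"cannot realize area {target:.1f} um^2 (slant too short)"
            )
        length = math.sqrt(under)
        nseg = max(1, math.ceil(length / _segment_length_limit(p)))
        sections[k + 1] = Section(
            k + 1, 0, "dendrite", length=length,
            diam_proximal=p.diam_proximal, diam_distal=p.diam_distal, nseg=nseg,
        )

    return Morphology(sections=sections, primary_dendrite_count=n_dend)


def _segment_length_limit(p: MorphologyParams) -> float:
    """Segment cap: the finer of the configured cap and 0.1 lambda at 100 Hz.

    lambda_100 = 0.5 * sqrt(diam / (pi * f * Ra * Cm)) with the standard
    passive values (Ra 150 ohm*cm, Cm 0.9 uF/cm^2); evaluated at the thin
    (distal) diameter so the rule is conservative along the taper.
    """
    ra, cm, f = 150.0, 0.9e-6, 100.0
    d_cm = p.diam_distal * 1e-4
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * f * ra * cm))
    return min(p.max_segment_length, 0.1 * lam_cm * 1e4)


def surface_areas(m: Morphology) -> AreaReport:
    """Total soma and dendritic membrane areas (um^2)."""
    soma = sum(s.membrane_area() for s in m.sections.values() if s.kind == "soma")
    dend = sum(s.membrane_area() for s in m.sections.values() if s.kind == "dendrite")
    return AreaReport(soma_area=soma, dendrite_area=dend)


def path_distance(m: Morphology, loc: TreeLocation) -> float:
    """Path distance (um) from the soma surface to ``loc`` along section axes.

    The soma is isopotential, so any location on it is at distance 0.
    """
    sec = m.section(loc.section_id)
    if sec.kind == "soma":
        return 0.0
    dist = sec.length * loc.frac
    pid = sec.parent_id
    while pid is not None:
        parent = m.section(pid)
        if parent.kind == "soma":
            break
        dist += parent.length
        pid = parent.parent_id
    return dist


def dendrite_paths(m: Morphology) -> list[list[int]]:
    """Root-to-tip section-id paths, one per dendritic tip."""
    paths: list[list[int]] = []

    def walk(sec: Section, trail: list[int]) -> None:
        trail = trail + [sec.id]
        kids = m.children(sec.id)
        if not kids:
            paths.append(trail)
        for child in kids:
            walk(child, trail)

    for child in m.children(m.soma.id):
        walk(child, [])
    return paths


def longest_dendrite_path(m: Morphology) -> list[int]:
    """Section ids of the root-to-tip path with the greatest total length."""
    paths = dendrite_paths(m)
    if not paths:
        raise ValueError("morphology has no dendrites")
    return max(paths, key=lambda p: sum(m.section(i).length for i in p))


def locate_at_normalized_distance(
    m: Morphology,
    dendrite_path: Sequence[int],
    d: float,
    reference: TreeLocation,
) -> TreeLocation:
    """Point at normalized separation ``d`` from ``reference`` along a path.

    ``d`` runs from 0 at the reference to 1 at the end of the path (origin
    or tip) that is farthest from the reference — the convention of the
    excitation/inhibition distance sweeps, where d=1 is maximal anatomical
    separation between the two synapses.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"normalized distance must lie in [0, 1], got {d}")
    for i, sid in enumerate(dendrite_path):
        sec = m.section(sid)
        if i == 0:
            if sec.parent_id is None or m.section(sec.parent_id).kind != "soma":
                raise ValueError("path must start at a primary dendrite")
        elif sec.parent_id != dendrite_path[i - 1]:
            raise ValueError("path sections are not connected root-to-tip")

    # Arc-length coordinate of each section start along the path.
    starts: dict[int, float] = {}
    s = 0.0
    for sid in dendrite_path:
        starts[sid] = s
        s += m.section(sid).length
    total = s
    if reference.section_id not in starts:
        raise ValueError("reference does not lie on the given path")
    s_ref = starts[reference.section_id] + m.section(reference.section_id).length * reference.frac

    to_tip = total - s_ref
    to_origin = s_ref
    direction = 1.0 if to_tip >= to_origin else -1.0
    target = s_ref + direction * d * max(to_tip, to_origin)
    target = min(max(target, 0.0), total)

    for sid in dendrite_path:
        sec = m.section(sid)
        if target <= starts[sid] + sec.length + 1e-9:
            frac = (target - starts[sid]) / sec.length
            return TreeLocation(sid, min(max(frac, 0.0), 1.0))
    return TreeLocation(dendrite_path[-1], 1.0)


# --------------------------------------------------------------------------
# SWC input/output
#
# Convention: the soma is written with the three-point convention (center
# sample plus two samples at +/- r on the y axis, radius r), representing a
# cylinder of length 2r and diameter 2r whose closed surface is the model's
# soma area.  Each dendritic section contributes one sample at its distal
# end; a section whose parent is the soma is preceded by a start sample
# (parent = soma center) carrying the proximal position and radius.  On
# reading, a sample whose parent is a type-1 sample opens a new branch and
# is interpreted as that branch's start point, not as a segment.
# --------------------------------------------------------------------------

_SWC_SOMA, _SWC_DENDRITE = 1, 3

# Deterministic fan of dendrite directions inside the +x hemisphere.
def _dendrite_direction(k: int, n: int) -> np.ndarray:
    if n == 1:
        return np.array([1.0, 0.0, 0.0])
    theta = (k - (n - 1) / 2.0) * (math.pi / 4.0) / max(n - 1, 1) * 2.0
    return np.array([math.cos(theta), math.sin(theta), 0.0])


def write_swc(m: Morphology, path: str) -> None:
    """Write the morphology as standard 7-column SWC text."""
    soma = m.soma
    r_s = soma.diam_proximal / 2.0
    lines = ["# octosim SWC export", "# id type x y z radius parent"]
    lines.append(f"1 {_SWC_SOMA} 0.0 0.0 0.0 {r_s:.6f} -1")
    lines.append(f"2 {_SWC_SOMA} 0.0 {r_s:.6f} 0.0 {r_s:.6f} 1")
    lines.append(f"3 {_SWC_SOMA} 0.0 {-r_s:.6f} 0.0 {r_s:.6f} 1")
    next_id = 4

    # section id -> (sample id of its distal end, distal xyz)
    tip: dict[int, tuple[int, np.ndarray]] = {}

    def emit(sec: Section, k_primary: int) -> None:
        nonlocal next_id
        if sec.parent_id == soma.id:
            direction = _dendrite_direction(k_primary, m.primary_dendrite_count)
            start_xyz = direction * r_s
            start_parent = 1
            lines.append(
                f"{next_id} {_SWC_DENDRITE} "
                f"{start_xyz[0]:.6f} {start_xyz[1]:.6f} {start_xyz[2]:.6f} "
                f"{sec.diam_proximal / 2.0:.6f} {start_parent}"
            )
            start_id = next_id
            next_id += 1
        else:
            start_id, start_xyz = tip[sec.parent_id]
            parent = m.section(sec.parent_id)
            direction = _dendrite_direction(k_primary, m.primary_dendrite_count)
        end_xyz = start_xyz + direction * sec.length
        lines.append(
            f"{next_id} {_SWC_DENDRITE} "
            f"{end_xyz[0]:.6f} {end_xyz[1]:.6f} {end_xyz[2]:.6f} "
            f"{sec.diam_distal / 2.0:.6f} {start_id}"
        )
        tip[sec.id] = (next_id, end_xyz)
        next_id += 1
        for child in m.children(sec.id):
            emit(child, k_primary)

    for k, primary in enumerate(m.children(soma.id)):
        emit(primary, k)

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path: str, max_segment_length: float = 10.0) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`."""
    samples: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(f"line {lineno}: expected 7 columns")
            try:
                sid = int(fields[0])
                stype = int(fields[1])
                xyz = np.array([float(v) for v in fields[2:5]])
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCFormatError(f"line {lineno}: {exc}") from exc
            if sid in samples:
                raise SWCFormatError(f"line {lineno}: duplicate id {sid}")
            if parent != -1 and parent not in samples:
                raise SWCFormatError(
                    f"line {lineno}: parent {parent} not yet defined "
                    "(missing or forward reference / cycle)"
                )
            samples[sid] = (stype, xyz, radius, parent)
            order.append(sid)

    soma_ids = [sid for sid in order if samples[sid][0] == _SWC_SOMA]
    if not soma_ids:
        raise SWCFormatError("no soma (type 1) samples found")
    root = soma_ids[0]
    _, root_xyz, r_s, root_parent = samples[root]
    if root_parent != -1:
        raise SWCFormatError("first soma sample must have parent -1")
    soma_diam = 2.0 * r_s  # three-point convention: cylinder L = D = 2r

    sections: dict[int, Section] = {
        0: Section(0, None, "soma", length=soma_diam,
                   diam_proximal=soma_diam, diam_distal=soma_diam, nseg=1)
    }
    sec_of_sample: dict[int, int] = {sid: 0 for sid in soma_ids}
    next_sec = 1
    primaries = 0
    for sid in order:
        stype, xyz, radius, parent = samples[sid]
        if stype == _SWC_SOMA:
            continue
        p_type = samples[parent][0]
        if p_type == _SWC_SOMA:
            # Branch start sample: carries proximal geometry only.
            primaries += 1
            continue
        _, p_xyz, p_radius, _ = samples[parent]
        length = float(np.linalg.norm(xyz - p_xyz))
        parent_sec = sec_of_sample.get(parent, 0)
        nseg = max(1, math.ceil(length / max_segment_length))
        sections[next_sec] = Section(
            next_sec,
            parent_sec,
            "dendrite",
            length=length,
            diam_proximal=2.0 * p_radius,
            diam_distal=2.0 * radius,
            nseg=nseg,
        )
        sec_of_sample[sid] = next_sec
        next_sec += 1

    return Morphology(sections=sections, primary_dendrite_count=primaries)
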