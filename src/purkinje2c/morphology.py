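"""Dendritic-arbour reduction to a single equivalent cylinder.

The collapse conserves axial resistance by pooling every dendritic branch into
one cylinder of radius R = sqrt(sum r_i^2) and radius-weighted mean length
l = sum(l_i r_i) / sum(r_i). Because surface area is not conserved, membrane
densities on the cylinder are rescaled by the dendritic correction factor
C_d = (arbour membrane area) / (cylinder lateral area). The cylinder can then
be re-lengthed at constant volume (adjusting the radius), which restores the
electrotonic soma-dendrite separation the collapse destroys; the linked
quantities (radius, areas, C_d) update automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Branch",
    "Soma",
    "MorphTree",
    "EquivCylinder",
    "ReductionResult",
    "read_swc",
    "write_swc",
    "collapse_tree",
    "relength_cylinder",
    "compute_cd",
    "apply_cd",
    "reduce_morphology",
]

#: SWC structure identifiers
SWC_SOMA = 1
SWC_DENDRITE_TYPES = (3, 4)  # basal and apical dendrite


@dataclass(frozen=True)
class Branch:
    """One tapered-cylinder dendritic branch (radius and length in um)."""

    id: int
    parent_id: int
    radius_um: float
    length_um: float

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError(f"branch {self.id}: radius must be > 0")
        if self.length_um <= 0:
            raise ValueError(f"branch {self.id}: length must be > 0")


@dataclass(frozen=True)
class Soma:
    length_um: float = 22.0
    diameter_um: float = 22.0

    @property
    def lateral_area_um2(self) -> float:
        """Lateral cylinder area pi*d*L (no end caps); 22 x 22 um -> 1521 um2."""
        return math.pi * self.diameter_um * self.length_um


@dataclass
class MorphTree:
    """Rooted tree of dendritic branches plus a cylindrical soma."""

    branches: Sequence[Branch]
    soma: Soma = field(default_factory=Soma)

    def __post_init__(self):
        self.branches = tuple(self.branches)
        ids = {b.id for b in self.branches}
        if len(ids) != len(self.branches):
            raise ValueError("duplicate branch ids")
        roots = [b for b in self.branches if b.parent_id not in ids]
        if self.branches and len(roots) < 1:
            raise ValueError("no root branch (cyclic parent links?)")
        # acyclicity: walk each branch to a root
        parent = {b.id: b.parent_id for b in self.branches}
        for b in self.branches:
            seen = set()
            node = b.id
            while node in parent:
                if node in seen:
                    raise ValueError(f"cycle through branch {node}")
                seen.add(node)
                node = parent[node]

    @property
    def total_dendrite_area_um2(self) -> float:
        return sum(2.0 * math.pi * b.radius_um * b.length_um for b in self.branches)


@dataclass(frozen=True)
class EquivCylinder:
    """Equivalent cylinder: radius/length in um, derived volume and area."""

    radius_um: float
    length_um: float

    def __post_init__(self):
        if self.radius_um <= 0 or self.length_um <= 0:
            raise ValueError("cylinder dimensions must be positive")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    @property
    def volume_um3(self) -> float:
        return math.pi * self.radius_um**2 * self.length_um

    @property
    def lateral_area_um2(self) -> float:
        return 2.0 * math.pi * self.radius_um * self.length_um

    def axial_resistance_ohm(self, ra_ohm_cm: float) -> float:
        """End-to-end axial resistance Ra*l/(pi R^2), in Ohm (um -> cm)."""
        return ra_ohm_cm * (self.length_um * 1e-4) / (
            math.pi * (self.radius_um * 1e-4) ** 2
        )


@dataclass(frozen=True)
class ReductionResult:
    cylinder: EquivCylinder
    cd: float
    full_dendrite_area_um2: float
    #: lateral area used in the C_d ratio (may be externally supplied when it
    #: differs from the recomputed cylinder area)
    cylinder_area_um2: float

    @property
    def recomputed_cylinder_area_um2(self) -> float:
        return self.cylinder.lateral_area_um2


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column: id type x y z radius parent)
# ---------------------------------------------------------------------------

def read_swc(path) -> MorphTree:
    """Read a standard 7-column SWC file into a MorphTree.

    Type-1 (soma) samples define the soma cylinder (length = diameter = 2r of
    the first soma sample); dendritic samples (types 3 and 4) become branches
    whose length is the Euclidean distance to the parent sample and whose
    radius is the sample radius. Other types (axon etc.) are ignored.
    """
    samples: dict[int, tuple] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
            sid, stype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
            samples[sid] = (stype, x, y, z, r, parent)

    soma_samples = [(sid, s) for sid, s in samples.items() if s[0] == SWC_SOMA]
    if soma_samples:
        r0 = soma_samples[0][1][4]
        soma = Soma(length_um=2.0 * r0, diameter_um=2.0 * r0)
    else:
        soma = Soma()

    branches = []
    for sid, (stype, x, y, z, r, parent) in sorted(samples.items()):
        if stype not in SWC_DENDRITE_TYPES:
            continue
        if parent not in samples:
            raise ValueError(f"sample {sid}: parent {parent} not in file")
        px, py, pz = samples[parent][1:4]
        length = math.dist((x, y, z), (px, py, pz))
        branches.append(Branch(id=sid, parent_id=parent, radius_um=r, length_um=length))
    return MorphTree(branches=branches, soma=soma)


def write_swc(tree: MorphTree, path) -> None:
    """Write a MorphTree as SWC, laying branches out along +x from their parent."""
    lines = ["# id type x y z radius parent"]
    soma_r = tree.soma.diameter_um / 2.0
    lines.append(f"1 {SWC_SOMA} 0 0 0 {soma_r:g} -1")
    # map branch ids to swc ids (soma occupies id 1)
    x_end: dict[int, float] = {}
    id_map: dict[int, int] = {}
    next_id = 2
    ids = {b.id for b in tree.branches}
    for b in tree.branches:
        parent_x = x_end.get(b.parent_id, 0.0) if b.parent_id in ids else 0.0
        parent_swc = id_map.get(b.parent_id, 1)
        x = parent_x + b.length_um
        lines.append(f"{next_id} 3 {x:g} 0 0 {b.radius_um:g} {parent_swc}")
        id_map[b.id] = next_id
        x_end[b.id] = x
        next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reduction operations
# ---------------------------------------------------------------------------

def collapse_tree(tree: MorphTree) -> EquivCylinder:
    """Pool all dendritic branches into one equivalent cylinder.

    R = sqrt(sum_i r_i^2) conserves the summed axial conductance of branches
    taken in parallel; l is the radius-weighted mean branch length.
    """
    if not tree.branches:
        raise ValueError("tree has no dendritic branches to collapse")
    r2 = sum(b.radius_um**2 for b in tree.branches)
    rsum = sum(b.radius_um for b in tree.branches)
    lw = sum(b.length_um * b.radius_um for b in tree.branches)
    return EquivCylinder(radius_um=math.sqrt(r2), length_um=lw / rsum)


def relength_cylinder(cyl: EquivCylinder, new_length_um: float) -> EquivCylinder:
    """Change cylinder length at constant volume: R' = sqrt(V / (pi l'))."""
    if new_length_um <= 0:
        raise ValueError("new length must be positive")
    new_r = math.sqrt(cyl.volume_um3 / (math.pi * new_length_um))
    return EquivCylinder(radius_um=new_r, length_um=new_length_um)


def compute_cd(full_area_um2: float, cylinder_area_um2: float) -> float:
    """Dendritic correction factor: arbour area over cylinder lateral area."""
    if full_area_um2 <= 0 or cylinder_area_um2 <= 0:
        raise ValueError("areas must be positive")
    return full_area_um2 / cylinder_area_um2


def apply_cd(table: Mapping | pd.DataFrame, cd: float) -> pd.DataFrame:
    """Scale a dendritic parameter table by C_d.

    ``table`` is a DataFrame (or mapping convertible to one) with columns
    ``parameter``, ``compartment`` and ``value``: every dendritic conductance
    density, membrane capacitance and Ca-shell depth is multiplied by ``cd``;
    somatic rows pass through untouched (the soma never enters the collapse).
    """
    if cd <= 0:
        raise ValueError("cd must be positive")
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    out = table.copy()
    dend = out["compartment"].str.lower().str.startswith("dend")
    out.loc[dend, "value"] = out.loc[dend, "value"] * cd
    return out


def reduce_morphology(
    tree: MorphTree,
    new_length_um: float | None = None,
    full_area_um2: float | None = None,
    cylinder_area_um2: float | None = None,
) -> ReductionResult:
    """Collapse, optionally re-length, and compute C_d in one pass.

    The arbour area defaults to the tree's summed lateral area and the
    cylinder area to the (re-lengthed) cylinder's lateral area; both can be
    supplied externally (the published model quotes measured areas that differ
    from the recomputed pi*d*l, and the ratio must then use the measured
    values). Changing the target length automatically updates radius, areas
    and C_d.
    """
    cyl = collapse_tree(tree)
    if new_length_um is not None:
        cyl = relength_cylinder(cyl, new_length_um)
    full = full_area_um2 if full_area_um2 is not None else tree.total_dendrite_area_um2
    cyl_area = (
        cylinder_area_um2 if cylinder_area_um2 is not None else cyl.lateral_area_um2
    )
    return ReductionResult(
        cylinder=cyl,
        cd=compute_cd(full, cyl_area),
        full_dendrite_area_um2=full,
        cylinder_area_um2=cyl_area,
    )
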