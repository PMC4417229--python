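"""Collapse a dendritic arbour to an equivalent cylinder and rescale it.

Builds a small synthetic tree, collapses it conserving axial resistance,
re-lengths the published collapsed cylinder at constant volume, and computes
the dendritic correction factor from the published membrane areas.
"""

from purkinje2c.morphology import EquivCylinder, compute_cd, relength_cylinder
from purkinje2c.synth import gen_synthetic_tree
from purkinje2c.morphology import collapse_tree

# a hand-checkable two-branch tree: R = sqrt(1^2 + 1^2), l = (100+200)/2
tree = gen_synthetic_tree(2, radii=[1.0, 1.0], lengths=[100.0, 200.0])
cyl = collapse_tree(tree)
print(f"collapsed synthetic tree: R = {cyl.radius_um:.5f} um, "
      f"l = {cyl.length_um:.1f} um")

# the published collapsed cylinder, re-lengthed at constant volume: the
# radius that keeps V = pi R^2 l fixed when l goes from 120.9 to 529.29 um
collapsed = EquivCylinder(radius_um=6.74 / 2.0, length_um=120.9)
relengthed = relength_cylinder(collapsed, 529.29)
print(f"re-lengthed cylinder: radius {relengthed.radius_um:.2f} um, "
      f"diameter {relengthed.diameter_um:.2f} um "
      f"(volume {relengthed.volume_um3:.0f} um^3, unchanged)")

# correction factor from the published arbour / cylinder membrane areas;
# it multiplies every dendritic conductance density, C_m and the Ca shell
# depth so the cylinder carries the arbour's total conductance load
cd = compute_cd(42310.0, 6874.0)
print(f"dendritic correction factor C_d = {cd:.2f}")
print(f"e.g. A-type K: 32 mS/cm2 x C_d = {32 * 6.16:.2f} mS/cm2")
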