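import math

import pytest
from hypothesis import given, settings, strategies as st

import pandas as pd

from purkinje2c.morphology import (
    Branch,
    EquivCylinder,
    MorphTree,
    Soma,
    apply_cd,
    collapse_tree,
    compute_cd,
    read_swc,
    reduce_morphology,
    relength_cylinder,
    write_swc,
)
from purkinje2c.synth import gen_synthetic_tree


def tree_of(spec):
    branches = [
        Branch(id=i + 2, parent_id=i + 1, radius_um=r, length_um=l)
        for i, (r, l) in enumerate(spec)
    ]
    return MorphTree(branches=branches)


class TestCollapse:
    def test_single_branch_is_identity(self):
        cyl = collapse_tree(tree_of([(2.0, 100.0)]))
        assert cyl.radius_um == pytest.approx(2.0)
        assert cyl.length_um == pytest.approx(100.0)

    def test_two_branch_hand_example(self):
        # R = sqrt(1+1), l = (100*1 + 200*1)/2
        cyl = collapse_tree(tree_of([(1.0, 100.0), (1.0, 200.0)]))
        assert cyl.radius_um == pytest.approx(math.sqrt(2.0), rel=1e-12)
        assert cyl.length_um == pytest.approx(150.0, rel=1e-12)

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError, match="no dendritic branches"):
            collapse_tree(MorphTree(branches=[]))

    def test_parallel_branches_conserve_axial_conductance(self):
        # equal-length parallel branches: 1/R_eq == sum 1/R_i
        spec = [(1.0, 120.0), (1.5, 120.0), (0.7, 120.0)]
        cyl = collapse_tree(tree_of(spec))
        ra = 35.4
        g_branches = sum(
            1.0 / EquivCylinder(r, l).axial_resistance_ohm(ra) for r, l in spec
        )
        assert 1.0 / cyl.axial_resistance_ohm(ra) == pytest.approx(
            g_branches, rel=1e-12
        )

    def test_invalid_branches_rejected(self):
        with pytest.raises(ValueError):
            Branch(id=1, parent_id=0, radius_um=-1.0, length_um=10.0)
        with pytest.raises(ValueError):
            Branch(id=1, parent_id=0, radius_um=1.0, length_um=0.0)


class TestRelength:
    def test_published_dimensions(self):
        # collapsed cylinder 120.9 um long, 6.74 um diameter, re-lengthed to
        # 529.29 um at constant volume -> radius 1.61 um, diameter 3.22 um
        cyl = EquivCylinder(radius_um=6.74 / 2.0, length_um=120.9)
        new = relength_cylinder(cyl, 529.29)
        assert round(new.radius_um, 2) == 1.61
        assert round(new.diameter_um, 2) == 3.22

    def test_identity_length(self):
        cyl = EquivCylinder(2.0, 100.0)
        new = relength_cylinder(cyl, 100.0)
        assert new.radius_um == pytest.approx(2.0, rel=1e-12)

    def test_r2l_conserved_hand_case(self):
        # R^2 l: 4*100 -> 1*400
        new = relength_cylinder(EquivCylinder(2.0, 100.0), 400.0)
        assert new.radius_um == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            relength_cylinder(EquivCylinder(2.0, 100.0), 0.0)

    @given(
        r=st.floats(0.1, 20.0),
        l=st.floats(1.0, 2000.0),
        new_l=st.floats(1.0, 2000.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_volume_conserved(self, r, l, new_l):
        cyl = EquivCylinder(r, l)
        new = relength_cylinder(cyl, new_l)
        assert new.volume_um3 == pytest.approx(cyl.volume_um3, rel=1e-9)


class TestCd:
    def test_published_ratio(self):
        assert round(compute_cd(42310.0, 6874.0), 2) == 6.16

    def test_equal_areas(self):
        assert compute_cd(123.0, 123.0) == 1.0

    def test_simple_division(self):
        assert compute_cd(100.0, 25.0) == 4.0

    def test_bad_areas_rejected(self):
        with pytest.raises(ValueError):
            compute_cd(0.0, 1.0)
        with pytest.raises(ValueError):
            compute_cd(1.0, -1.0)


class TestApplyCd:
    def table(self):
        return pd.DataFrame(
            {
                "parameter": ["g_ka", "g_leak", "cm", "depth", "g_bk"],
                "compartment": ["dendrite"] * 4 + ["soma"],
                "value": [32.0, 0.000079, 0.8, 0.1, 72.86],
            }
        )

    def test_scales_dendritic_rows_only(self):
        out = apply_cd(self.table(), 6.16)
        vals = dict(zip(out["parameter"], out["value"]))
        assert vals["g_ka"] == pytest.approx(197.12)
        assert vals["g_leak"] == pytest.approx(0.000487, abs=5e-7)
        assert vals["cm"] == pytest.approx(0.8 * 6.16)
        assert vals["depth"] == pytest.approx(0.616)
        assert vals["g_bk"] == 72.86  # soma untouched

    def test_unit_cd_is_identity(self):
        out = apply_cd(self.table(), 1.0)
        assert (out["value"] == self.table()["value"]).all()

    def test_round_trip(self):
        out = apply_cd(apply_cd(self.table(), 6.16), 1.0 / 6.16)
        for a, b in zip(out["value"], self.table()["value"]):
            assert a == pytest.approx(b, rel=1e-12)


class TestSwc:
    def test_round_trip_and_reduction(self, tmp_path):
        tree = gen_synthetic_tree(4, seed=7)
        path = tmp_path / "tree.swc"
        write_swc(tree, path)
        back = read_swc(path)
        assert len(back.branches) == 4
        c1, c2 = collapse_tree(tree), collapse_tree(back)
        assert c1.radius_um == pytest.approx(c2.radius_um, rel=1e-6)
        assert c1.length_um == pytest.approx(c2.length_um, rel=1e-6)

    def test_deterministic_generation(self, tmp_path):
        a = tmp_path / "a.swc"
        b = tmp_path / "b.swc"
        write_swc(gen_synthetic_tree(5, seed=3), a)
        write_swc(gen_synthetic_tree(5, seed=3), b)
        assert a.read_bytes() == b.read_bytes()

    def test_known_two_branch_tree(self):
        tree = gen_synthetic_tree(2, radii=[1.0, 1.0], lengths=[100.0, 200.0])
        cyl = collapse_tree(tree)
        assert cyl.radius_um == pytest.approx(math.sqrt(2.0))
        assert cyl.length_um == pytest.approx(150.0)


class TestReducePipeline:
    def test_linked_update_of_radius_and_cd(self):
        tree = gen_synthetic_tree(6, seed=1)
        short = reduce_morphology(tree)
        long = reduce_morphology(tree, new_length_um=2.0 * short.cylinder.length_um)
        # volume constant; radius shrinks by sqrt(2); lateral area therefore
        # grows by sqrt(2) and the recomputed C_d shrinks accordingly
        assert long.cylinder.volume_um3 == pytest.approx(
            short.cylinder.volume_um3, rel=1e-9
        )
        assert long.cylinder.radius_um == pytest.approx(
            short.cylinder.radius_um / math.sqrt(2.0), rel=1e-9
        )
        assert long.cd == pytest.approx(short.cd / math.sqrt(2.0), rel=1e-9)

    def test_external_areas_respected(self):
        tree = gen_synthetic_tree(3, seed=2)
        res = reduce_morphology(
            tree, full_area_um2=42310.0, cylinder_area_um2=6874.0
        )
        assert round(res.cd, 2) == 6.16
        assert res.recomputed_cylinder_area_um2 != res.cylinder_area_um2

    def test_soma_lateral_area(self):
        assert round(Soma(22.0, 22.0).lateral_area_um2) == 1521
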