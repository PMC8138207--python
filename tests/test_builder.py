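import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from graphdock.builder import (
    CC_BOND,
    FunctionalizationSpec,
    build_circular_graphene,
    build_rectangular_graphene,
    check_hueckel,
    circular_fingerprint,
    deduplicate_models,
    functionalize_graphene,
)
from graphdock.structures import AROMATIC, MolecularStructure


def carbon_indices(s):
    return [i for i, a in enumerate(s.atoms) if a.element == "C"]


class TestCircularBuilder:
    def test_minimal_diameter_gives_single_ring(self):
        g = build_circular_graphene(3.0)
        assert sum(a.element == "C" for a in g.atoms) == 6
        assert sum(a.element == "H" for a in g.atoms) == 6

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValueError):
            build_circular_graphene(2.0)

    def test_interior_carbons_have_three_carbon_neighbours(self):
        g = build_circular_graphene(18.0)
        adj = g.neighbours()
        for i in carbon_indices(g):
            c_nbrs = sum(g.atoms[j].element == "C" for j in adj[i])
            h_nbrs = sum(g.atoms[j].element == "H" for j in adj[i])
            # interior carbons: 3 C neighbours; edge carbons: 2 C + 1 H
            assert (c_nbrs, h_nbrs) in ((3, 0), (2, 1))

    def test_carbons_lie_within_radius(self):
        d = 15.0
        g = build_circular_graphene(d)
        for i in carbon_indices(g):
            assert np.linalg.norm(g.atoms[i].position[:2]) <= d / 2 + 1e-9
        # hydrogens at most one C–H bond farther out
        for i, a in enumerate(g.atoms):
            assert np.linalg.norm(a.position[:2]) <= d / 2 + 1.09

    def test_sheet_is_planar_and_aromatic(self):
        g = build_circular_graphene(12.0)
        assert np.allclose(g.coords[:, 2], 0.0)
        assert all(g.atoms[i].atom_type == "C.ar" for i in carbon_indices(g))
        rep = check_hueckel(g)
        assert rep.pi_connected


class TestRectangularBuilder:
    def test_minimal_rectangle_is_one_ring(self):
        g = build_rectangular_graphene(3.2, 3.2)
        assert sum(a.element == "C" for a in g.atoms) == 6

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_rectangular_graphene(1.0, 20.0)

    def test_square_contains_inscribed_circle_cut(self):
        d = 16.0
        circ = build_circular_graphene(d)
        rect = build_rectangular_graphene(d, d)
        assert rect.n_atoms >= circ.n_atoms

    def test_carbon_count_matches_independent_lattice_enumeration(self):
        w = h = 14.0
        g = build_rectangular_graphene(w, h)
        # independent enumeration: walk the triangular lattice of hexagon
        # centres, collect vertices inside the window, then strip atoms
        # with fewer than two in-window neighbours (the builder's pruning)
        s = math.sqrt(3.0) * CC_BOND
        pts = set()
        n = int((max(w, h)) / s) + 4
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                cx = i * s + j * s / 2
                cy = j * s * math.sqrt(3) / 2
                for k in range(6):
                    ang = math.pi / 6 + k * math.pi / 3
                    x = cx + CC_BOND * math.cos(ang)
                    y = cy + CC_BOND * math.sin(ang)
                    if abs(x) <= w / 2 and abs(y) <= h / 2:
                        pts.add((round(x, 4), round(y, 4)))
        pts = list(pts)
        changed = True
        while changed:
            changed = False
            keep = []
            for p in pts:
                deg = sum(
                    0 < math.dist(p, q) < CC_BOND * 1.1 for q in pts
                )
                if deg >= 2:
                    keep.append(p)
                else:
                    changed = True
            pts = keep
        assert sum(a.element == "C" for a in g.atoms) == len(pts)


class TestHueckel:
    def test_benzene_ring_is_aromatic(self, benzene):
        rep = check_hueckel(benzene)
        assert rep.pi_electron_count == 6
        assert rep.hueckel_ok  # 4·1 + 2
        assert rep.pi_connected

    def test_two_disjoint_rings_are_disconnected(self, benzene):
        a = benzene.copy()
        b = benzene.copy()
        n = a.n_atoms
        for at in b.atoms:
            at.position = at.position + np.array([20.0, 0, 0])
        a.atoms.extend(b.atoms)
        from graphdock.structures import Bond

        a.bonds.extend(Bond(x.i + n, x.j + n, x.order) for x in b.bonds)
        rep = check_hueckel(a)
        assert rep.pi_electron_count == 12
        assert not rep.pi_connected
        assert not rep.hueckel_ok  # 12 ≡ 0 (mod 4)

    def test_4n_plus_2_is_count_mod_4(self, coronene_patch):
        rep = check_hueckel(coronene_patch)
        assert rep.hueckel_ok == (rep.pi_electron_count % 4 == 2)


class TestFingerprint:
    def test_deterministic(self, go_patch):
        assert circular_fingerprint(go_patch).ToBitString() == circular_fingerprint(
            go_patch
        ).ToBitString()

    def test_invariant_under_renumbering_and_rotation(self, go_patch):
        perm = list(reversed(range(go_patch.n_atoms)))
        inv = {old: new for new, old in enumerate(perm)}
        rot = Rotation.from_euler("xyz", [0.3, -0.8, 1.1])
        from graphdock.structures import Bond

        atoms = [go_patch.atoms[i] for i in perm]
        moved = MolecularStructure(
            [
                type(a)(a.element, a.atom_type, rot.apply(a.position) + 5.0, a.partial_charge, a.formal_charge)
                for a in atoms
            ],
            [Bond(inv[b.i], inv[b.j], b.order) for b in go_patch.bonds],
            name="copy",
        )
        assert (
            circular_fingerprint(go_patch).ToBitString()
            == circular_fingerprint(moved).ToBitString()
        )

    def test_symmetry_inequivalent_hydroxyl_sites_differ(self):
        # a rectangular patch has both central and off-centre basal carbons;
        # grafting OH at graph-inequivalent sites must change the fingerprint
        base = build_circular_graphene(12.0)
        specs = [
            FunctionalizationSpec(n_hydroxyl=1, manner="systematic", max_models=40, seed=0)
        ]
        models = functionalize_graphene(base, specs[0])
        fps = {circular_fingerprint(m).ToBitString() for m in models}
        assert len(fps) == len(models) > 1


@pytest.fixture(scope="module")
def sheet():
    return build_circular_graphene(16.0)


class TestFunctionalize:

    def test_group_counts_match_spec_exactly(self, sheet):
        spec = FunctionalizationSpec(
            n_hydroxyl=2, n_epoxy=1, n_carboxyl=2, max_models=5, seed=4
        )
        for m in functionalize_graphene(sheet, spec):
            # count grafted groups by substructure: OH oxygens bond 1 C,
            # epoxy oxygens bridge 2 C, carboxyls contribute a C.2 carbon
            adj = m.neighbours()
            oxygens = [i for i, a in enumerate(m.atoms) if a.element == "O"]
            oh = sum(
                1
                for i in oxygens
                if sum(m.atoms[j].element == "C" for j in adj[i]) == 1
                and any(m.atoms[j].element == "H" for j in adj[i])
            )
            epoxy = sum(
                1
                for i in oxygens
                if sum(m.atoms[j].element == "C" for j in adj[i]) == 2
            )
            cooh = sum(1 for a in m.atoms if a.atom_type == "C.2")
            assert (oh - cooh, epoxy, cooh) == (2, 1, 2)  # each COOH adds one O–H oxygen

    def test_pi_system_stays_connected(self, sheet):
        spec = FunctionalizationSpec(n_hydroxyl=3, n_epoxy=3, n_carboxyl=3, max_models=8, seed=9)
        for m in functionalize_graphene(sheet, spec):
            rep = check_hueckel(m)
            assert rep.pi_connected
            assert rep.pi_electron_count == check_hueckel(sheet).pi_electron_count - 3 - 2 * 3

    def test_same_seed_reproduces_identical_models(self, sheet):
        spec = FunctionalizationSpec(n_hydroxyl=1, n_epoxy=1, n_carboxyl=1, max_models=4, seed=11)
        a = functionalize_graphene(sheet, spec)
        b = functionalize_graphene(sheet, spec)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.coords, mb.coords)
            assert [x.atom_type for x in ma.atoms] == [x.atom_type for x in mb.atoms]

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            FunctionalizationSpec(n_hydroxyl=0, n_epoxy=0, n_carboxyl=0, max_models=1)

    def test_dual_surface_places_oxygens_on_both_sides(self, sheet):
        spec = FunctionalizationSpec(
            n_hydroxyl=4, surface_mode="dual", manner="systematic", max_models=1, seed=0
        )
        m = functionalize_graphene(sheet, spec)[0]
        zs = [a.position[2] for a in m.atoms if a.element == "O"]
        assert any(z > 0 for z in zs) and any(z < 0 for z in zs)


class TestDedup:
    def test_rotated_renumbered_copy_collapses(self, go_patch):
        rot = Rotation.from_euler("z", 1.0)
        copy = go_patch.copy()
        for a in copy.atoms:
            a.position = rot.apply(a.position) + np.array([3.0, -2.0, 0.5])
        from graphdock.structures import Bond

        perm = list(reversed(range(copy.n_atoms)))
        inv = {old: new for new, old in enumerate(perm)}
        renumbered = MolecularStructure(
            [copy.atoms[i] for i in perm],
            [Bond(inv[b.i], inv[b.j], b.order) for b in copy.bonds],
        )
        out = deduplicate_models([go_patch, renumbered])
        assert len(out) == 1
        assert out[0] is go_patch  # first occurrence kept

    def test_distinct_list_unchanged_and_idempotent(self, benzene, go_patch, coronene_patch):
        models = [benzene, go_patch, coronene_patch]
        once = deduplicate_models(models)
        assert once == models
        assert deduplicate_models(once) == once

    def test_k_copies_collapse_to_one(self, benzene):
        assert len(deduplicate_models([benzene.copy() for _ in range(5)])) == 1
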