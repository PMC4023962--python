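"""Composite-tree surgery: scaling, grafting, genus collapsing, richness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divergrass.phylo_core import TimeTree, TipData, TreeError
from divergrass.tree_assembly import (
    GraftInstruction,
    RichnessRule,
    collapse_to_representatives,
    graft,
    largest_remainder_split,
    scale_to_root_age,
    validate_assignment,
)
from divergrass.synthetic_data import (
    DEFAULT_BISSE_PARAMS,
    SimulationConfig,
    simulate_bisse_tree,
)


class TestScale:
    def test_doubling(self, three_tip_tree):
        out = scale_to_root_age(three_tip_tree, 4.0)
        assert out.root_age == pytest.approx(4.0)
        info_ab = out.find_tip("A").edge.length
        assert info_ab == pytest.approx(2.0)

    def test_identity(self, three_tip_tree):
        out = scale_to_root_age(three_tip_tree, three_tip_tree.root_age)
        assert out.as_newick() == three_tip_tree.as_newick()

    def test_composition(self, sim_tree_50):
        tree, _ = sim_tree_50
        ab = scale_to_root_age(scale_to_root_age(tree, 17.0), 41.0)
        ac = scale_to_root_age(tree, 41.0)
        for lab in tree.tip_labels[:10]:
            assert ab.find_tip(lab).parent_node.age == pytest.approx(
                ac.find_tip(lab).parent_node.age, rel=1e-10
            )

    def test_preserves_age_ratios(self, sim_tree_50):
        tree, _ = sim_tree_50
        out = scale_to_root_age(tree, 123.0)
        ratio = 123.0 / tree.root_age
        for lab in tree.tip_labels[:10]:
            a = tree.find_tip(lab).parent_node.age
            b = out.find_tip(lab).parent_node.age
            assert b == pytest.approx(a * ratio, rel=1e-10)

    def test_invalid_target(self, three_tip_tree):
        with pytest.raises(ValueError):
            scale_to_root_age(three_tip_tree, 0.0)


class TestGraft:
    backbone_nwk = "((P1:2,P2:2):3,Out:5);"

    def test_hand_fixture(self):
        backbone = TimeTree.from_newick(self.backbone_nwk)
        sub = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        out = graft(backbone, GraftInstruction(("P1", "P2"), sub, 2.0))
        assert out.n_tips == 5  # 3 - 2 + 4
        assert out.root_age == pytest.approx(5.0)
        crown = out.find_tip("A").parent_node.parent_node.age
        assert crown == pytest.approx(2.0)
        # backbone node ages outside the replaced clade untouched
        assert out.find_tip("Out").parent_node.age == pytest.approx(5.0)

    def test_identity_graft(self):
        backbone = TimeTree.from_newick(self.backbone_nwk)
        sub = TimeTree.from_newick("(P1:2,P2:2);")
        out = graft(backbone, GraftInstruction(("P1", "P2"), sub, 2.0))
        assert sorted(out.tip_labels) == ["Out", "P1", "P2"]
        assert out.root_age == pytest.approx(5.0)
        assert out.find_tip("P1").parent_node.age == pytest.approx(2.0)

    def test_sequential_grafts_conserve_tip_count(self):
        # chain of placeholder pairs; each graft adds (subtree tips - 2)
        backbone = TimeTree.from_newick(
            "(((G1a:1,G1b:1):4,(G2a:2,G2b:2):3):5,Out:10);"
        )
        n = backbone.n_tips
        for i, pair in enumerate([("G1a", "G1b"), ("G2a", "G2b")]):
            k = 3 + i
            labels = ",".join(f"X{i}_{j}:1" for j in range(k))
            sub = TimeTree.from_newick(f"({labels});")
            sub = TimeTree.from_newick(
                "(" + ",".join(f"X{i}_{j}:1" for j in range(2)) + ","
                + ",".join(f"X{i}_{j}:1" for j in range(2, k)) + ");"
            ).resolve_polytomies()
            backbone = graft(backbone, GraftInstruction(pair, sub, 0.5))
            n = n - 2 + k
            assert backbone.n_tips == n
        assert backbone.root_age == pytest.approx(10.0)

    def test_non_monophyletic_pair_rejected(self):
        backbone = TimeTree.from_newick("((P1:2,X:2):3,P2:5);")
        sub = TimeTree.from_newick("(A:1,B:1);")
        with pytest.raises(TreeError, match="monophyletic"):
            graft(backbone, GraftInstruction(("P1", "P2"), sub, 1.0))

    def test_crown_older_than_stem_rejected(self):
        backbone = TimeTree.from_newick(self.backbone_nwk)
        sub = TimeTree.from_newick("(A:1,B:1);")
        with pytest.raises(TreeError, match="stem"):
            graft(backbone, GraftInstruction(("P1", "P2"), sub, 5.5))

    def test_grafting_preserves_ultrametricity(self, sim_tree_50):
        backbone = TimeTree.from_newick(self.backbone_nwk)
        tree, _ = sim_tree_50
        out = graft(backbone, GraftInstruction(("P1", "P2"), tree, 3.0))
        # TimeTree constructor re-validates ultrametricity
        assert out.n_tips == 1 + tree.n_tips
        assert all(lf.age == 0.0 for lf in out.leaf_nodes())


class TestLargestRemainder:
    def test_poa_example(self):
        assert largest_remainder_split(550, 3) == [184, 183, 183]

    @given(total=st.integers(1, 100_000), k=st.integers(1, 50))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_sums_and_evenness(self, total, k):
        parts = largest_remainder_split(total, k)
        assert sum(parts) == total
        assert max(parts) - min(parts) <= 1
        assert parts == sorted(parts, reverse=True)


class TestCollapse:
    def _tree_and_tips(self):
        tree = TimeTree.from_newick(
            "(((Poa_a:1,Poa_b:1):1,(Poa_c:1.5,Poa_d:1.5):0.5):3,"
            "(Festuca_x:2,Festuca_y:2):3);"
        )
        tips = TipData.from_dict({l: 0 for l in tree.tip_labels})
        return tree, tips

    def test_split_threshold_divides_large_genus(self):
        tree, tips = self._tree_and_tips()
        rule = RichnessRule(genus_sizes={"Poa": 550, "Festuca": 10})
        out, newtips = collapse_to_representatives(tree, tips, rule)
        tab = newtips.table.set_index("tip_label")
        poa = sorted(
            int(r) for l, r in tab["richness"].items() if l.startswith("Poa")
        )
        assert poa == [183, 183, 184]
        assert int(tab.loc["Festuca_x", "richness"]) == 10
        assert newtips.total_richness == 560
        assert out.n_tips == 4

    def test_single_sampled_tip_carries_genus_richness(self):
        tree = TimeTree.from_newick("((Aristida_x:2,Stipa_y:2):2,Panicum_z:4);")
        tips = TipData.from_dict({l: 0 for l in tree.tip_labels})
        rule = RichnessRule(
            genus_sizes={"Aristida": 10, "Stipa": 3, "Panicum": 8}
        )
        out, newtips = collapse_to_representatives(tree, tips, rule)
        tab = newtips.table.set_index("tip_label")
        assert int(tab.loc["Aristida_x", "richness"]) == 10
        assert newtips.total_richness == 21

    def test_mixed_state_genus_splits_into_state_blocks(self):
        tree = TimeTree.from_newick(
            "(((Gen_a:1,Gen_b:1):1,Gen_c:2):2,Out_x:4);"
        )
        tips = TipData.from_dict({"Gen_a": 0, "Gen_b": 0, "Gen_c": 1, "Out_x": 0})
        rule = RichnessRule(
            genus_sizes={"Gen": 30, "Out": 1}, state_counts={"Gen": (20, 10)}
        )
        out, newtips = collapse_to_representatives(tree, tips, rule)
        tab = newtips.table.set_index("tip_label")
        assert int(tab.loc["Gen_a", "state"]) == 0
        assert int(tab.loc["Gen_a", "richness"]) == 20
        assert int(tab.loc["Gen_c", "state"]) == 1
        assert int(tab.loc["Gen_c", "richness"]) == 10
        assert newtips.total_richness == 31

    def test_spread_genus_distributes_evenly_across_blocks(self):
        # polyphyletic genus: tips interleaved with another genus
        tree = TimeTree.from_newick(
            "(((Pan_a:1,Pan_b:1):2,(Other_x:2,Pan_c:2):1):2,Out_y:5);"
        )
        tips = TipData.from_dict({l: 0 for l in tree.tip_labels})
        rule = RichnessRule(
            genus_sizes={"Pan": 90, "Other": 5, "Out": 1},
            spread_genera=("Pan",),
        )
        out, newtips = collapse_to_representatives(tree, tips, rule)
        tab = newtips.table.set_index("tip_label")
        # 90 spread over 3 tips = 30 each; the (a,b) block keeps 60
        assert int(tab.loc["Pan_a", "richness"]) == 60
        assert int(tab.loc["Pan_c", "richness"]) == 30
        assert newtips.total_richness == 96

    def test_missing_genus_raises(self):
        tree, tips = self._tree_and_tips()
        rule = RichnessRule(genus_sizes={"Poa": 550})
        with pytest.raises(KeyError, match="Festuca"):
            collapse_to_representatives(tree, tips, rule)

    def test_richness_conserved_on_simulated_trees(self):
        for s in range(3):
            tree, tips = simulate_bisse_tree(
                SimulationConfig(seed=400 + s, params=DEFAULT_BISSE_PARAMS,
                                 target_tips=40)
            )
            # fake genera: group labels by numeric prefix bucket
            relab = {
                l: f"G{int(l[1:]) % 7}_{l}" for l in tree.tip_labels
            }
            for lf in tree.leaf_nodes():
                lf.taxon.label = relab[TimeTree._label(lf)]
            tree.refresh()
            tips2 = TipData(
                tips.table.assign(
                    tip_label=[relab[l] for l in tips.table.tip_label]
                ),
                f=tips.f,
            )
            sizes = {f"G{i}": 11 for i in range(7)}
            out, newtips = collapse_to_representatives(
                tree, tips2, RichnessRule(genus_sizes=sizes)
            )
            assert newtips.total_richness == sum(
                sizes[g] for g in
                {l.split("_", 1)[0] for l in tree.tip_labels}
            )


class TestValidateAssignment:
    def test_coverage_report(self):
        df = pd.DataFrame(
            {
                "tip_label": [f"t{i}" for i in range(10)],
                "state": pd.array([0, 1] * 5, dtype="Int64"),
                "richness": [5] * 10,
            }
        )
        tips = TipData(df, sampling_mode="unresolved")
        rep = validate_assignment(tips, known_total=100)
        assert rep.total_assigned == 50
        assert rep.coverage == pytest.approx(0.5)
        assert rep.sampling_fraction == pytest.approx(10 / 50)

    def test_all_richness_one_means_f_one(self):
        tips = TipData.from_dict({"a": 0, "b": 1})
        rep = validate_assignment(tips)
        assert rep.total_assigned == 2
        assert rep.sampling_fraction == pytest.approx(1.0)
        assert rep.coverage is None

    def test_sum_matches_brute_force(self, sim_tree_100):
        _, tips = sim_tree_100
        rng = np.random.default_rng(1)
        t = tips.table.copy()
        t["richness"] = rng.integers(1, 20, len(t))
        td = TipData(t, sampling_mode="unresolved")
        rep = validate_assignment(td)
        assert rep.total_assigned == sum(int(x) for x in t["richness"])
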