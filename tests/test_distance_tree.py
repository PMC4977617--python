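import numpy as np
import pytest

import phenodiv as pv
from phenodiv.distance_tree import DistanceMatrix, Tree

from conftest import make_records


def random_additive_tree(n_leaves, seed):
    """Random topology with random positive branch lengths; returns (Tree, labels)."""
    rng = np.random.default_rng(seed)
    tree = Tree()
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    for i, lab in enumerate(labels):
        tree.leaf_labels[i] = lab
        tree.adj.setdefault(i, [])
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        tree.add_edge(nxt, a, float(rng.uniform(0.1, 1.0)))
        tree.add_edge(nxt, b, float(rng.uniform(0.1, 1.0)))
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    tree.root = active[0]
    return tree, labels


class TestGenotypeDistance:
    def test_identical_genotypes_zero(self, toy_catalog):
        row = {"COL": "Red", "SHP": "Round", "SIZ": "Small"}
        dm = pv.genotype_distance(pv.encode_binary(make_records(toy_catalog, [row, row])))
        assert dm.d[0, 1] == 0.0

    def test_fourteen_of_twentyfour(self, catalog):
        """Maximally divergent same-named accessions: 14 mismatches out of 24."""
        keys = catalog.trait_keys
        a = {k: catalog[k].variables[0].label for k in keys}
        b = dict(a)
        for k in keys:
            if catalog[k].n_states > 1 and sum(a[x] != b[x] for x in keys) < 14:
                b[k] = catalog[k].variables[1].label
        tm = make_records(catalog, [a, b])
        dm = pv.genotype_distance(pv.encode_binary(tm))
        assert dm.d[0, 1] == pytest.approx(14 / 24)

    def test_matches_pairwise_recount_oracle(self, catalog):
        tm = pv.simulate_panel(pv.odisha_like_spec(n=15, seed=21, with_groups=False))
        dm = pv.genotype_distance(pv.encode_binary(tm))
        for i in range(15):
            for j in range(i + 1, 15):
                diff = pv.pairwise_trait_diff(tm, tm.ids[i], tm.ids[j])
                expected = diff["count"] / (24 - len(diff["skipped"]))
                assert dm.d[i, j] == pytest.approx(expected)

    def test_neilog_transform(self, toy_catalog):
        rows = [
            {"COL": "Red", "SHP": "Round", "SIZ": "Small"},
            {"COL": "Blue", "SHP": "Round", "SIZ": "Small"},
            {"COL": "Blue", "SHP": "Oval", "SIZ": "Large"},
        ]
        bm = pv.encode_binary(make_records(toy_catalog, rows))
        m = pv.genotype_distance(bm, metric="mismatch")
        d = pv.genotype_distance(bm, metric="neilog")
        assert d.d[0, 1] == pytest.approx(-np.log(1 - m.d[0, 1]))
        assert np.isinf(d.d[0, 2])  # complete mismatch


class TestGroupNeiDistance:
    def test_identical_frequencies_zero(self, toy_catalog):
        rows = [
            {"COL": "Red", "SHP": "Round", "SIZ": "Small"},
            {"COL": "Blue", "SHP": "Oval", "SIZ": "Large"},
        ]
        tm = make_records(toy_catalog, rows + rows, groups=["a", "a", "b", "b"])
        fts = {g: pv.frequencies(tm, subset=tm.group_members(g)) for g in ("a", "b")}
        dm = pv.group_nei_distance(fts)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_groups_infinite(self, toy_catalog):
        a = {"COL": "Red", "SHP": "Round", "SIZ": "Small"}
        b = {"COL": "Blue", "SHP": "Oval", "SIZ": "Large"}
        tm = make_records(toy_catalog, [a, a, b, b], groups=["x", "x", "y", "y"])
        fts = {g: pv.frequencies(tm, subset=tm.group_members(g)) for g in ("x", "y")}
        with pytest.warns(UserWarning, match="infinite"):
            dm = pv.group_nei_distance(fts)
        assert np.isinf(dm.d[0, 1])

    def test_hand_computed_two_trait_example(self, toy_catalog):
        # group x: COL fixed Red, SHP split 50/50; group y: COL fixed Blue, SHP split
        # J per trait then averaged over the three toy traits (SIZ also fixed/equal)
        x1 = {"COL": "Red", "SHP": "Round", "SIZ": "Small"}
        x2 = {"COL": "Red", "SHP": "Oval", "SIZ": "Small"}
        y1 = {"COL": "Blue", "SHP": "Round", "SIZ": "Small"}
        y2 = {"COL": "Blue", "SHP": "Oval", "SIZ": "Small"}
        tm = make_records(toy_catalog, [x1, x2, y1, y2], groups=["x", "x", "y", "y"])
        fts = {g: pv.frequencies(tm, subset=tm.group_members(g)) for g in ("x", "y")}
        dm = pv.group_nei_distance(fts)
        # Jx = Jy = mean(1, 0.5, 1) = 5/6 ; Jxy = mean(0, 0.5, 1) = 0.5
        expected = -np.log(0.5 / (5 / 6))
        assert dm.d[0, 1] == pytest.approx(expected, abs=1e-12)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        labels = ["a", "b", "c"]
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = pv.neighbor_joining(DistanceMatrix(labels, d))
        pl = tree.path_lengths()
        assert np.allclose(pl.d, d, atol=1e-12)
        # v_a = (d_ab + d_ac - d_bc)/2 = 0.1
        center = tree.root
        lengths = {tree.leaf_labels[v]: ln for v, ln in tree.adj[center]}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        ref, labels = random_additive_tree(4, seed=5)
        dm = ref.path_lengths()
        tree = pv.neighbor_joining(dm)
        got = tree.path_lengths()
        assert got.labels == dm.labels
        assert np.allclose(got.d, dm.d, atol=1e-9)

    @pytest.mark.parametrize("n_leaves,seed", [(6, 0), (6, 1), (8, 2), (8, 3)])
    def test_additivity_oracle(self, n_leaves, seed):
        ref, _ = random_additive_tree(n_leaves, seed)
        dm = ref.path_lengths()
        got = pv.neighbor_joining(dm).path_lengths()
        assert np.allclose(got.d, dm.d, atol=1e-9)

    def test_missing_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing|infinite"):
            pv.neighbor_joining(DistanceMatrix(["a", "b", "c"], d))

    def test_matches_skbio_topology_on_random_matrix(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(11)
        n = 7
        labels = [f"t{i}" for i in range(n)]
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        mine = pv.neighbor_joining(DistanceMatrix(labels, d))
        theirs = sk_nj(SkDM(d, ids=labels))

        def splits_mine(tree):
            out = set()
            for u, nbrs in tree.adj.items():
                for v, _ in nbrs:
                    if u < v and u not in tree.leaf_labels and v not in tree.leaf_labels:
                        side, other = pv.cluster_report(tree, edge=(u, v))
                        out.add(frozenset(side if labels[0] in other else other))
            return out

        def splits_skbio(tree):
            out = set()
            tips = set(labels)
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    out.add(side if labels[0] not in side else frozenset(tips - side))
            return out

        assert splits_mine(mine) == splits_skbio(theirs)


class TestNewickAndClusters:
    def test_three_taxon_newick_parseable(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = pv.neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        s = tree.to_newick()
        assert s.endswith(";") and s.count("(") == s.count(")")

    def test_newick_round_trip_preserves_lengths(self, tmp_path):
        ref, _ = random_additive_tree(7, seed=9)
        tree = pv.neighbor_joining(ref.path_lengths())
        path = tmp_path / "t.nwk"
        pv.write_newick(tree, path)
        back = pv.read_newick(path)
        a = tree.path_lengths()
        b = back.path_lengths()
        assert a.labels == b.labels
        assert np.allclose(a.d, b.d, atol=1e-9)

    def test_label_quoting(self):
        tree = Tree()
        tree.leaf_labels = {0: "odd name (x)", 1: "b", 2: "c"}
        for i in (0, 1, 2):
            tree.adj.setdefault(i, [])
        tree.add_edge(3, 0, 0.1)
        tree.add_edge(3, 1, 0.2)
        tree.add_edge(3, 2, 0.3)
        tree.root = 3
        s = tree.to_newick()
        assert "'odd name (x)'" in s
        back = pv.read_newick(s)
        assert "odd name (x)" in back.leaves

    def test_cluster_report_recovers_two_clumps(self, catalog):
        rng = np.random.default_rng(3)
        rows, groups = [], []
        for clump, first_state in (("A", 0), ("B", 1)):
            for _ in range(6):
                states = {}
                for t in catalog.traits:
                    if t.n_states == 1:
                        states[t.key] = t.variables[0].label
                    else:
                        # clumps centred on different states with small noise
                        base = first_state if rng.random() > 0.1 else 1 - first_state
                        states[t.key] = t.variables[base].label
                rows.append(states)
                groups.append(clump)
        tm = make_records(catalog, rows)
        tree = pv.neighbor_joining(pv.genotype_distance(pv.encode_binary(tm)))
        side_a, side_b = pv.cluster_report(tree)
        clump_of = {f"G{i + 1}": g for i, g in enumerate(groups)}
        purity = max(
            sum(clump_of[x] == "A" for x in side_a) + sum(clump_of[x] == "B" for x in side_b),
            sum(clump_of[x] == "B" for x in side_a) + sum(clump_of[x] == "A" for x in side_b),
        ) / 12
        assert purity >= 11 / 12


def test_distances_invariant_under_genotype_permutation(odisha_panel):
    rng = np.random.default_rng(4)
    order = rng.permutation(odisha_panel.n)
    shuffled = pv.TraitMatrix(odisha_panel.catalog, [odisha_panel.records[i] for i in order])
    a = pv.genotype_distance(pv.encode_binary(odisha_panel))
    b = pv.genotype_distance(pv.encode_binary(shuffled))
    inv = np.argsort(order)
    assert np.allclose(a.d, b.d[np.ix_(inv, inv)])
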