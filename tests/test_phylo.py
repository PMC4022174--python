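"""Distances, neighbour joining, bootstrap, and Newick I/O.

Independent oracles: a scipy.linalg.expm grid-search likelihood for JTT
distances, random additive matrices (where NJ is provably exact) for tree
reconstruction, and scikit-bio's / dendropy's implementations for
cross-library topology and round-trip checks.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import simulate_jtt_pair
from mipclass.phylo import (
    DistanceMatrix,
    Msa,
    bootstrap_supports,
    default_model,
    is_monophyletic,
    jtt_distance,
    jtt_distance_matrix,
    nj_tree,
    parse_newick,
    trim_msa,
)


def random_additive_tree(n_taxa: int, rng):
    """A random binary tree and its exact leaf-to-leaf path-length matrix."""
    ids = [f"T{i}" for i in range(n_taxa)]
    # start from a star over the first three taxa, attach the rest by
    # subdividing a random edge; represent as node -> {neighbor: length}
    nodes = {i: {} for i in range(n_taxa)}
    next_id = n_taxa

    def link(u, v, w):
        nodes[u][v] = w
        nodes[v][u] = w

    center = next_id
    nodes[center] = {}
    next_id += 1
    for i in range(3):
        link(center, i, rng.uniform(0.1, 1.0))
    edges = [(center, 0), (center, 1), (center, 2)]
    for leaf in range(3, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        w = nodes[u].pop(v)
        nodes[v].pop(u)
        mid = next_id
        nodes[mid] = {}
        next_id += 1
        cut = rng.uniform(0.2, 0.8) * w
        link(u, mid, cut)
        link(mid, v, w - cut)
        link(mid, leaf, rng.uniform(0.1, 1.0))
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (mid, leaf)])
    # all-pairs distances by BFS from each leaf
    m = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n_taxa):
            m[i, j] = dist[j]
    return DistanceMatrix(tuple(ids), m)


def tree_path_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a PhyloTree."""
    out = {}

    def below(node):
        if node.is_leaf:
            return {node.name: node.length}
        merged = {}
        groups = []
        for c in node.children:
            d = below(c)
            groups.append(d)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a, da in groups[gi].items():
                    for b, db in groups[gj].items():
                        out[tuple(sorted((a, b)))] = da + db
        for g in groups:
            for a, da in g.items():
                merged[a] = da + node.length
        return merged

    below(tree.root)
    return out


class TestTrim:
    def _msa(self, rows):
        return Msa(tuple(f"s{i}" for i in range(len(rows))), tuple(rows))

    def test_clean_alignment_is_fixed_point(self):
        m = self._msa(["ACDE", "ACDE", "ACDF"])
        assert trim_msa(m) is m

    def test_gappy_terminal_block_removed_exactly(self):
        lead = ["-" * 10 + "ACDE", "-" * 10 + "ACDE", "A" * 10 + "ACDE",
                "-" * 10 + "ACDE", "-" * 10 + "ACDE", "-" * 10 + "ACDE",
                "-" * 10 + "ACDE", "-" * 10 + "ACDE", "-" * 10 + "ACDE",
                "-" * 10 + "ACDE"]
        m = self._msa(lead)  # first 10 columns are 90% gaps
        t = trim_msa(m, terminal_gap_fraction=0.5)
        assert t.n_cols == 4
        assert t.rows[0] == "ACDE"

    def test_internal_gappy_columns_untouched(self):
        m = self._msa(["AC--DE", "AC--DE", "AC--DE"])
        assert trim_msa(m).n_cols == 6

    def test_idempotent(self):
        m = self._msa(["---ACDE--", "--GACDE--", "---ACDEF-"])
        once = trim_msa(m)
        assert trim_msa(once).rows == once.rows

    def test_trimming_everything_is_an_error_naming_threshold(self):
        m = self._msa(["----", "A---", "----"])
        with pytest.raises(ValueError, match="0.5"):
            trim_msa(m, terminal_gap_fraction=0.5)


class TestJttDistance:
    def test_identical_rows_give_zero(self):
        row = "ACDEFGHIKLMNPQRSTVWY" * 5
        assert jtt_distance(row, row) == 0.0

    def test_symmetric(self):
        a, b = simulate_jtt_pair(0.3, 500, seed=4)
        assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a), abs=1e-6)

    def test_matches_expm_grid_search_oracle(self):
        """ML estimate at true d=0.1 on 10k sites agrees with an independent
        grid-search likelihood built on scipy.linalg.expm."""
        model = default_model()
        a, b = simulate_jtt_pair(0.1, 10_000, seed=6)
        est = jtt_distance(a, b)
        idx = {c: i for i, c in enumerate("ARNDCQEGHILKMFPSTWYV")}
        counts = np.zeros((20, 20))
        for x, y in zip(a, b):
            counts[idx[x], idx[y]] += 1
        grid = np.arange(0.005, 0.5, 0.0005)
        lls = [
            float(np.sum(counts * np.log(np.maximum(expm(model.q * d), 1e-300))))
            for d in grid
        ]
        grid_opt = grid[int(np.argmax(lls))]
        assert est == pytest.approx(grid_opt, abs=1e-3)
        # and the estimate sits in a sane interval around the truth
        assert 0.08 < est < 0.12

    def test_pairwise_deletion_ignores_gapped_columns(self):
        a = "AAAA" + "-" * 4 + "WWWW"
        b = "AAAA" + "CCCC" + "WWWW"
        assert jtt_distance(a, b) == 0.0

    def test_complete_deletion_drops_any_gapped_column(self):
        # under complete deletion only the 4 gap-free columns count, and they
        # are identical across rows -> all distances zero
        msa = Msa(("a", "b", "c"), ("AC-WEF", "ACDWE-", "ACDWEF"))
        dm = jtt_distance_matrix(msa, gap_mode="complete")
        assert np.allclose(dm.matrix, 0.0)
        with pytest.raises(ValueError, match="complete deletion"):
            jtt_distance_matrix(Msa(("a", "b"), ("A-", "-A")), gap_mode="complete")
        with pytest.raises(ValueError, match="gap_mode"):
            jtt_distance_matrix(msa, gap_mode="banana")

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(ValueError, match="no shared"):
            jtt_distance("AA--", "--WW")

    def test_saturation_capped_and_flagged(self):
        # a pair simulated far beyond the search bound must hit the cap
        a, b = simulate_jtt_pair(6.0, 400, seed=12)
        c, _ = simulate_jtt_pair(0.05, 400, seed=13)
        msa = Msa(("a", "b", "c"), (a, b, c))
        dm = jtt_distance_matrix(msa, d_max=1.5)
        assert dm.matrix.max() == pytest.approx(1.5)
        assert ("a", "b") in dm.saturated_pairs


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        ids = ("A", "B", "C", "D")
        # tree ((A:1,B:2):1,(C:3,D:4)) -> path distances
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(ids, m))
        ok, _ = is_monophyletic(tree, {"A", "B"})
        assert ok
        paths = tree_path_distances(tree)
        for i, a in enumerate(ids):
            for j in range(i + 1, 4):
                assert paths[(a, ids[j])] == pytest.approx(m[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ("A", "B", "C")
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, m))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            dm = random_additive_tree(n, rng)
            tree = nj_tree(dm)
            paths = tree_path_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((dm.ids[i], dm.ids[j])))
                    assert paths[key] == pytest.approx(dm.matrix[i, j], abs=1e-9)

    def test_topology_agrees_with_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        for _ in range(5):
            n = int(rng.integers(5, 10))
            dm = random_additive_tree(n, rng)
            # perturb slightly so the matrix is non-additive but tree-like
            noise = rng.uniform(-0.01, 0.01, size=dm.matrix.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            m = dm.matrix + noise
            m = (m + m.T) / 2  # exact symmetry for both libraries
            ours = nj_tree(DistanceMatrix(dm.ids, m))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(m, ids=list(dm.ids)))
            ours_bips = set(ours.bipartitions())
            leaves = ours.leaf_names
            theirs_parsed = parse_newick(str(theirs).strip())
            theirs_bips = set()
            for bp in theirs_parsed.bipartitions():
                theirs_bips.add(min(bp, leaves - bp, key=sorted))
            ours_norm = {min(bp, leaves - bp, key=sorted) for bp in ours_bips}
            assert ours_norm == theirs_bips

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))
        with pytest.raises(ValueError, match="finite"):
            DistanceMatrix(("a", "b", "c"), np.full((3, 3), np.nan))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1, 0]])))


class TestDistanceMonotonicity:
    def test_estimates_track_true_divergence(self):
        truths = [0.05, 0.2, 0.4, 0.6, 0.8]
        ests = []
        for k, d in enumerate(truths):
            a, b = simulate_jtt_pair(d, 4000, seed=100 + k)
            ests.append(jtt_distance(a, b))
        assert ests == sorted(ests)


class TestBootstrap:
    def _family_msa(self, n_families=4, per=3, seed=1):
        from mipclass.synthetic import generate_family, make_template_family

        templates = make_template_family(seed=1000, n_templates=n_families)
        ids, rows = [], []
        for f, tpl in enumerate(templates):
            seqs, _ = generate_family(
                tpl, n=per, divergence=0.05, indel_rate=0.0, seed=seed + f
            )
            for s in seqs:
                ids.append(f"F{f}_{s.seq_id[-2:]}")
                rows.append(s.residues)
        return Msa(tuple(ids), tuple(rows))

    def test_separated_families_get_full_support(self):
        msa = self._family_msa()
        tree = bootstrap_supports(msa, n_reps=50, seed=3)
        for f in range(4):
            labels = {l for l in tree.leaf_names if l.startswith(f"F{f}_")}
            ok, support = is_monophyletic(tree, labels)
            assert ok and support == 100.0

    def test_deterministic_given_seed(self):
        msa = self._family_msa(n_families=2, per=3)
        t1 = bootstrap_supports(msa, n_reps=20, seed=9)
        t2 = bootstrap_supports(msa, n_reps=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_column_duplication_leaves_decisive_supports_stable(self):
        """Resampling is column-exchangeable, so doubling every column keeps
        decisive supports in place. (Weak, near-tie edges are excluded: a
        doubled alignment halves the variance of resampled column weights,
        which legitimately concentrates borderline supports.)"""
        msa = self._family_msa(n_families=3, per=3)
        doubled = Msa(msa.ids, tuple(r + r for r in msa.rows))
        t1 = bootstrap_supports(msa, n_reps=100, seed=5)
        t2 = bootstrap_supports(doubled, n_reps=100, seed=5)
        b1 = {bp: n.support for bp, n in t1.bipartitions().items()}
        b2 = {bp: n.support for bp, n in t2.bipartitions().items()}
        decisive = {bp for bp, v in b1.items() if v >= 90.0 or v <= 10.0}
        assert decisive, "expected at least the family clades to be decisive"
        for bp in decisive & set(b2):
            p = min(max(b1[bp] / 100.0, 0.01), 0.99)
            se = 100.0 * np.sqrt(p * (1 - p) / 100)
            assert abs(b1[bp] - b2[bp]) <= 3 * se + 1e-9

    def test_supports_lie_in_percent_range(self):
        msa = self._family_msa(n_families=2, per=3)
        tree = bootstrap_supports(msa, n_reps=30, seed=2)
        for _, node in tree.bipartitions().items():
            assert 0.0 <= node.support <= 100.0

    def test_needs_four_taxa(self):
        msa = Msa(("a", "b", "c"), ("AA", "AW", "WW"))
        with pytest.raises(ValueError, match="at least 4"):
            bootstrap_supports(msa, n_reps=10, seed=1)


class TestMonophyly:
    def _caterpillar(self):
        return parse_newick("((((A:1,B:1)90:1,C:1)80:1,D:1)70:1,E:1);")

    def test_true_clade_with_support(self):
        ok, support = is_monophyletic(self._caterpillar(), {"A", "B"})
        assert ok and support == 90.0

    def test_non_clade(self):
        ok, support = is_monophyletic(self._caterpillar(), {"A", "C"})
        assert not ok and support is None

    def test_complement_side_counts_as_monophyletic(self):
        ok, _ = is_monophyletic(self._caterpillar(), {"D", "E"})
        assert ok  # {D,E} is the complement of the {A,B,C} side

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="ZZZ"):
            is_monophyletic(self._caterpillar(), {"A", "ZZZ"})


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self):
        msa_ids = ("A", "B", "C", "D", "E")
        rng = np.random.default_rng(8)
        dm = random_additive_tree(5, rng)
        tree = nj_tree(dm)
        for bp, node in tree.bipartitions().items():
            node.support = 77.0
        text = tree.to_newick()
        back = parse_newick(text)
        assert back.leaf_names == tree.leaf_names
        p1, p2 = tree_path_distances(tree), tree_path_distances(back)
        for k in p1:
            assert p2[k] == pytest.approx(p1[k], abs=1e-9)
        for bp, node in back.bipartitions().items():
            assert node.support == 77.0

    def test_dendropy_parses_our_newick(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(9)
        tree = nj_tree(random_additive_tree(6, rng))
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(tree.leaf_names)


def test_stockholm_and_fasta_readers(tmp_path):
    rows = {"s1": "ACD-E", "s2": "ACDFE", "s3": "AC-FE"}
    fasta = tmp_path / "a.fasta"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
    sto = tmp_path / "a.sto"
    sto.write_text(
        "# STOCKHOLM 1.0\n" + "".join(f"{k}  {v}\n" for k, v in rows.items()) + "//\n"
    )
    m1 = Msa.from_file(fasta, "fasta")
    m2 = Msa.from_file(sto, "stockholm")
    assert m1.rows == m2.rows == tuple(rows.values())
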