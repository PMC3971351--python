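import itertools

import numpy as np
import pandas as pd
import pytest

from pathprints.phylo import (
    CharacterMatrix,
    Phylogeny,
    StateCostMatrix,
    Tree,
    bootstrap_support,
    nj_start_tree,
    parsimony_search,
    read_newick,
    robinson_foulds,
    sankoff_score,
    write_newick,
)


def cmatrix(rows: dict[str, list[int]]) -> CharacterMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"PW{i}" for i in range(df.shape[1])]
    return CharacterMatrix(df)


def exhaustive_sankoff(tree: Tree, cm: CharacterMatrix, costs: StateCostMatrix) -> float:
    """Oracle: enumerate every internal-state assignment and sum edge costs."""
    internals = [n for n in sorted(tree.adj) if n not in tree.labels]
    edges = [(u, v) for u in sorted(tree.adj) for v in sorted(tree.adj[u]) if u < v]
    total = 0.0
    for char in cm.data.columns:
        leaf_state = {t: int(cm.data.loc[t, char]) for t in cm.taxa}
        best = np.inf
        for assign in itertools.product([-1, 0, 1], repeat=len(internals)):
            state = dict(zip(internals, assign))
            for n, taxon in tree.labels.items():
                state[n] = leaf_state[taxon]
            cost = sum(costs.cost(state[u], state[v]) for u, v in edges)
            best = min(best, cost)
        total += best
    return total


def random_tree(taxa: list[str], rng) -> Tree:
    """Random unrooted binary topology by sequential leaf attachment."""
    newick = f"({taxa[0]},{taxa[1]},{taxa[2]});"
    t = Tree.from_newick(newick)
    for taxon in taxa[3:]:
        edges = [(u, v) for u in sorted(t.adj) for v in sorted(t.adj[u]) if u < v]
        u, v = edges[rng.integers(len(edges))]
        t._unlink(u, v)
        mid = t._new_node()
        leaf = t._new_node(taxon)
        t._link(u, mid)
        t._link(mid, v)
        t._link(mid, leaf)
    return t


class TestStateCostMatrix:
    def test_difference_costs(self):
        c = StateCostMatrix.difference()
        assert c.cost(-1, 1) == 2
        assert c.cost(0, 1) == c.cost(-1, 0) == 1
        assert c.cost(1, 1) == 0

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1, 2], [2, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            StateCostMatrix(m)

    def test_triangle_violation_rejected(self):
        m = np.array([[0, 5, 1], [5, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="triangle"):
            StateCostMatrix(m)


class TestSankoffScore:
    def test_uniform_character_costs_nothing(self):
        cm = cmatrix({"A": [1], "B": [1], "C": [1]})
        tree = Tree.from_newick("(A,B,C);")
        assert sankoff_score(tree, cm) == 0.0

    def test_single_opposite_leaf_costs_two(self):
        # -1 vs +1 disagreement costs |-1 - 1| = 2 under the difference cost
        cm = cmatrix({"A": [-1], "B": [1], "C": [1]})
        tree = Tree.from_newick("(A,B,C);")
        assert sankoff_score(tree, cm) == 2.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        costs = StateCostMatrix.difference()
        for trial in range(20):
            n_taxa = int(rng.integers(4, 6))
            taxa = [f"T{i}" for i in range(n_taxa)]
            tree = random_tree(taxa, rng)
            cm = cmatrix({t: rng.choice([-1, 0, 1], 8).tolist() for t in taxa})
            assert sankoff_score(tree, cm, costs) == exhaustive_sankoff(tree, cm, costs)

    def test_invariant_under_newick_rotation(self):
        cm = cmatrix({t: [1, -1, 0, 1, 0] for t in "ABCDE"})
        cm.data.loc["A"] = [-1, 1, 0, -1, 1]
        cm.data.loc["C"] = [0, 0, 1, 1, -1]
        t1 = Tree.from_newick("((A,B),(C,D),E);")
        t2 = Tree.from_newick("(E,(D,C),(B,A));")
        assert sankoff_score(t1, cm) == sankoff_score(t2, cm)

    def test_linear_in_cost_matrix(self):
        rng = np.random.default_rng(5)
        taxa = [f"T{i}" for i in range(5)]
        tree = random_tree(taxa, rng)
        cm = cmatrix({t: rng.choice([-1, 0, 1], 6).tolist() for t in taxa})
        full = StateCostMatrix.difference()
        half = StateCostMatrix(full.costs / 2)
        assert sankoff_score(tree, cm, full) == 2 * sankoff_score(tree, cm, half)

    def test_leaf_mismatch_rejected(self):
        cm = cmatrix({"A": [1], "B": [1], "C": [1]})
        with pytest.raises(ValueError, match="taxa"):
            sankoff_score(Tree.from_newick("(A,B,X);"), cm)


class TestParsimonySearch:
    def test_four_taxa_matches_exhaustive_topology_search(self):
        rng = np.random.default_rng(8)
        topologies = [
            "((A,B),(C,D));",
            "((A,C),(B,D));",
            "((A,D),(B,C));",
        ]
        for trial in range(10):
            cm = cmatrix({t: rng.choice([-1, 0, 1], 10).tolist() for t in "ABCD"})
            best_exhaustive = min(
                sankoff_score(Tree.from_newick(nwk), cm) for nwk in topologies
            )
            assert parsimony_search(cm).score == best_exhaustive

    def test_search_never_worse_than_start(self):
        rng = np.random.default_rng(9)
        cm = cmatrix({f"T{i}": rng.choice([-1, 0, 1], 12).tolist() for i in range(6)})
        start = nj_start_tree(cm)
        res = parsimony_search(cm, start=start)
        assert res.score <= sankoff_score(start, cm)

    def test_recovers_planted_six_taxon_lineage(self):
        from pathprints.synthetic import make_lineage

        truth = Tree.from_newick("((A,B),(C,D),(E,F));")
        base = pd.Series(np.zeros(120, dtype=int), index=[f"PW{i}" for i in range(120)])
        cm = make_lineage(truth, base, flips_per_edge=10, seed=3)
        res = parsimony_search(cm)
        assert robinson_foulds(res.tree, truth) == 0

    def test_constant_character_does_not_change_topology(self):
        rng = np.random.default_rng(14)
        cm = cmatrix({f"T{i}": rng.choice([-1, 0, 1], 15).tolist() for i in range(6)})
        res = parsimony_search(cm)
        padded = cm.data.copy()
        padded["CONST"] = 1
        res_padded = parsimony_search(CharacterMatrix(padded))
        assert res.tree.splits() == res_padded.tree.splits()

    def test_too_few_taxa_rejected(self):
        cm = cmatrix({"A": [1], "B": [0], "C": [-1]})
        with pytest.raises(ValueError, match="4 taxa"):
            parsimony_search(cm)


class TestBootstrap:
    def test_conflict_free_data_fully_supported(self):
        # every internal split of ((A,B),(C,D),(E,F)) backed by 10 clean
        # characters and nothing conflicting: every replicate recovers it
        truth = Tree.from_newick("((A,B),(C,D),(E,F));")
        taxa = ["A", "B", "C", "D", "E", "F"]
        rows = {t: [] for t in taxa}
        for group in (["A", "B"], ["C", "D"], ["E", "F"]):
            for _ in range(10):
                for t in taxa:
                    rows[t].append(1 if t in group else -1)
        cm = cmatrix(rows)
        res = bootstrap_support(cm, n_reps=30, seed=1)
        assert robinson_foulds(res.tree, truth) == 0
        assert res.supports and all(v == 1.0 for v in res.supports.values())

    def test_supports_bounded_and_reproducible(self):
        rng = np.random.default_rng(3)
        cm = cmatrix({f"T{i}": rng.choice([-1, 0, 1], 10).tolist() for i in range(5)})
        a = bootstrap_support(cm, n_reps=20, seed=4)
        b = bootstrap_support(cm, n_reps=20, seed=4)
        assert a.supports == b.supports
        assert all(0.0 <= v <= 1.0 for v in a.supports.values())

    def test_evenly_conflicting_characters_halve_support(self):
        # 20 characters support (AB|CD), 20 support (AC|BD)
        rows = {"A": [], "B": [], "C": [], "D": []}
        for _ in range(20):  # AB vs CD
            rows["A"].append(1); rows["B"].append(1); rows["C"].append(-1); rows["D"].append(-1)
        for _ in range(20):  # AC vs BD
            rows["A"].append(1); rows["C"].append(1); rows["B"].append(-1); rows["D"].append(-1)
        cm = cmatrix(rows)
        res = bootstrap_support(cm, n_reps=200, seed=6)
        (support,) = res.supports.values()
        assert 0.25 <= support <= 0.75


class TestNewickIO:
    def test_round_trip_preserves_topology(self, tmp_path):
        t = Tree.from_newick("((A,B),(C,D),(E,F));")
        write_newick(t, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert robinson_foulds(t, back) == 0

    def test_supports_written_as_internal_labels(self, tmp_path):
        t = Tree.from_newick("((A,B),(C,D));")
        supports = {s: 0.87 for s in t.splits()}
        write_newick(Phylogeny(tree=t, score=0.0, supports=supports), tmp_path / "t.nwk")
        assert "0.87" in (tmp_path / "t.nwk").read_text()

    def test_rf_distance_between_distinct_topologies(self):
        a = Tree.from_newick("((A,B),(C,D));")
        b = Tree.from_newick("((A,C),(B,D));")
        assert robinson_foulds(a, b) == 2
        assert robinson_foulds(a, a) == 0
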