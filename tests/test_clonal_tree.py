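"""Perfect-phylogeny reconstruction: compatibility, topology, serialization.

The independent oracle for tree existence is exhaustive: enumerate every
rooted tree shape on up to five clone nodes and every assignment of regions
to nodes, and ask whether each mutation's observed region-set equals some
node's subtree region-set. This brute force never consults the laminarity
shortcut used by the implementation.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from multiregion.clonal_tree import (
    IncompatibleMatrixError,
    TopologyCategory,
    build_clone_tree,
    check_compatibility,
    classify_topology,
    parse_newick,
    render_tree,
    replay_presence,
)

from conftest import make_profile


def brute_force_tree_exists(region_sets: list[set[str]], regions: list[str]) -> bool:
    """Exhaustively search rooted clone trees realizing all region-sets.

    Any realizing tree can be contracted (merging a node whose subtree
    region-set is not a target into its parent) to at most one node per
    distinct target plus a root, so searching up to that many nodes is
    exhaustive.
    """
    targets = {frozenset(s) for s in region_sets}
    k = len(regions)
    for n_nodes in range(1, len(targets) + 2):
        # parent[i] < i enumerates every labeled rooted tree on n_nodes
        for parents in product(*[range(i) for i in range(1, n_nodes)]):
            for assignment in product(range(n_nodes), repeat=k):
                subtree = [set() for _ in range(n_nodes)]
                for r, node in zip(regions, assignment):
                    subtree[node].add(r)
                # children carry larger ids than parents, so one reverse
                # sweep accumulates every subtree region-set
                for child in range(n_nodes - 1, 0, -1):
                    subtree[parents[child - 1]] |= subtree[child]
                achievable = {frozenset(s) for s in subtree}
                if targets <= achievable:
                    return True
    return False


def pairwise_conflicts(region_sets: list[set[str]]) -> int:
    n = 0
    for i in range(len(region_sets)):
        for j in range(i + 1, len(region_sets)):
            a, b = region_sets[i], region_sets[j]
            if a & b and not (a <= b or b <= a):
                n += 1
    return n


class TestCompatibility:
    def test_disjoint_sets_are_compatible(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3", "R4"],
            {"A:1": ("SETD2", {"R1", "R2"}), "B:1": ("BAP1", {"R3", "R4"})},
        )
        assert check_compatibility(profile) == []

    def test_overlap_without_nesting_conflicts(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3"],
            {"A:1": ("SETD2", {"R1", "R2"}), "B:1": ("BAP1", {"R2", "R3"})},
        )
        conflicts = check_compatibility(profile)
        assert len(conflicts) == 1
        # the exhaustive search over all rooted trees on 3 regions agrees
        assert not brute_force_tree_exists([{"R1", "R2"}, {"R2", "R3"}], ["R1", "R2", "R3"])

    def test_full_row_never_conflicts(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3"],
            {"A:1": ("VHL", {"R1", "R2", "R3"}), "B:1": ("BAP1", {"R2", "R3"}),
             "C:1": ("KDM5C", {"R1"})},
        )
        assert check_compatibility(profile) == []

    def test_exhaustive_oracle_agreement_on_random_matrices(self):
        """Existence per the brute-force tree search matches the pairwise rule."""
        rng = np.random.default_rng(11)
        regions = ["R1", "R2", "R3", "R4"]
        n_checked_sat = n_checked_unsat = 0
        for _ in range(40):
            m = int(rng.integers(1, 5))
            sets = []
            for _ in range(m):
                size = int(rng.integers(1, 5))
                sets.append(set(rng.choice(regions, size=size, replace=False)))
            exists = brute_force_tree_exists(sets, regions)
            compatible = pairwise_conflicts(sets) == 0
            assert exists == compatible
            rows = {f"K:{i}": ("VHL", s) for i, s in enumerate(sets)}
            profile = make_profile("P1", regions, rows)
            assert (check_compatibility(profile) == []) == exists
            n_checked_sat += exists
            n_checked_unsat += not exists
        assert n_checked_sat >= 10 and n_checked_unsat >= 10


class TestBuildCloneTree:
    def test_single_shared_mutation_trunk(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3", "R4"],
            {"VHL:1": ("VHL", {"R1", "R2", "R3", "R4"})},
        )
        tree = build_clone_tree(profile)
        assert [m.gene for m in tree.root.mutations] == ["VHL"]
        assert tree.root.regions == ["R1", "R2", "R3", "R4"]
        assert tree.root.children == []

    def test_trunk_and_branch(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3", "R4"],
            {
                "VHL:1": ("VHL", {"R1", "R2", "R3", "R4"}),
                "PBRM1:1": ("PBRM1", {"R1", "R2", "R3", "R4"}),
                "SETD2:1": ("SETD2", {"R1", "R2"}),
            },
        )
        tree = build_clone_tree(profile)
        assert [m.gene for m in tree.root.mutations] == ["VHL", "PBRM1"]
        assert tree.root.regions == ["R3", "R4"]
        (branch,) = tree.root.children
        assert [m.gene for m in branch.mutations] == ["SETD2"]
        assert branch.regions == ["R1", "R2"]

    def test_empty_matrix_gives_root_only_tree(self):
        profile = make_profile("P1", ["R1", "R2", "R3"], {})
        tree = build_clone_tree(profile)
        assert tree.root.mutations == [] and tree.root.children == []
        assert tree.root.regions == ["R1", "R2", "R3"]

    def test_equal_region_sets_collapse_onto_one_edge(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3"],
            {"A:1": ("SETD2", {"R1", "R2"}), "B:1": ("BAP1", {"R1", "R2"})},
        )
        tree = build_clone_tree(profile)
        (branch,) = tree.root.children
        assert sorted(m.gene for m in branch.mutations) == ["BAP1", "SETD2"]

    def test_incompatible_matrix_refused_with_conflicts(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3"],
            {"A:1": ("SETD2", {"R1", "R2"}), "B:1": ("BAP1", {"R2", "R3"})},
        )
        with pytest.raises(IncompatibleMatrixError) as exc:
            build_clone_tree(profile)
        assert len(exc.value.conflicts) == 1

    def test_round_trip_on_random_laminar_matrices(self):
        """Replaying edge mutations reproduces every laminar input matrix."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            profile = random_laminar_profile(rng)
            tree = build_clone_tree(profile)
            muts, regs, matrix = replay_presence(tree)
            assert regs == profile.regions
            by_key = {m.variant_key: row for m, row in zip(muts, matrix)}
            for m, row in zip(profile.mutations, profile.presence):
                assert by_key[m.variant_key].tolist() == row.tolist()
            assert len(by_key) == len(profile.mutations)


def random_laminar_profile(rng: np.random.Generator):
    """Test-local laminar matrix generator (recursive block splitting)."""
    k = int(rng.integers(1, 6))
    regions = [f"R{i + 1}" for i in range(k)]
    blocks: list[list[str]] = []

    def split(seq: list[str]) -> None:
        if len(seq) < 2:
            return
        cut = int(rng.integers(1, len(seq)))
        for part in (seq[:cut], seq[cut:]):
            blocks.append(part)
            split(part)

    shuffled = list(rng.permutation(regions))
    split(shuffled)
    pool = [set(regions)] + [set(b) for b in blocks]
    m = int(rng.integers(0, 7))
    rows = {}
    for i in range(m):
        rows[f"K:{i}"] = ("VHL", pool[int(rng.integers(len(pool)))])
    return make_profile("P1", regions, rows)


class TestTopology:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ({"VHL:1": ("VHL", {"R1", "R2", "R3"})}, TopologyCategory.SINGLE_SHARED_ONLY),
            (
                {"VHL:1": ("VHL", {"R1", "R2", "R3"}),
                 "PBRM1:1": ("PBRM1", {"R1", "R2", "R3"})},
                TopologyCategory.MULTIPLE_SHARED_ONLY,
            ),
            (
                {"VHL:1": ("VHL", {"R1", "R2", "R3"}),
                 "SETD2:1": ("SETD2", {"R1"})},
                TopologyCategory.SHARED_AND_NONSHARED,
            ),
            ({"KDM5C:1": ("KDM5C", {"R2"})}, TopologyCategory.NONSHARED_ONLY),
            ({}, TopologyCategory.NO_MUTATIONS),
        ],
    )
    def test_five_categories(self, rows, expected):
        profile = make_profile("P1", ["R1", "R2", "R3"], rows)
        assert classify_topology(profile) == expected

    def test_cohort_category_counts(self, paper_counts_cohort):
        counts: dict[TopologyCategory, int] = {}
        for profile in paper_counts_cohort.profiles:
            cat = classify_topology(profile)
            counts[cat] = counts.get(cat, 0) + 1
        assert counts == {
            TopologyCategory.SINGLE_SHARED_ONLY: 3,
            TopologyCategory.MULTIPLE_SHARED_ONLY: 4,
            TopologyCategory.SHARED_AND_NONSHARED: 3,
            TopologyCategory.NONSHARED_ONLY: 1,
            TopologyCategory.NO_MUTATIONS: 3,
        }
        assert sum(counts.values()) == len(paper_counts_cohort.profiles)


class TestSerialization:
    def test_root_only_newick(self):
        profile = make_profile("P1", ["R1", "R2", "R3"], {})
        nwk = render_tree(build_clone_tree(profile), "newick")
        assert nwk.startswith("(R1,R2,R3)") and nwk.endswith(";")

    def test_newick_round_trip_is_lossless(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            profile = random_laminar_profile(rng)
            tree = build_clone_tree(profile)
            text = render_tree(tree, "newick")
            assert render_tree(parse_newick(text), "newick") == text

    def test_dot_trunk_out_degree(self):
        profile = make_profile(
            "P1", ["R1", "R2", "R3", "R4"],
            {"VHL:1": ("VHL", {"R1", "R2", "R3", "R4"})},
        )
        dot = render_tree(build_clone_tree(profile), "dot")
        assert dot.count("clone0 ->") == 4
        assert 'label="VHL"' in dot

    def test_unknown_format_rejected(self):
        profile = make_profile("P1", ["R1"], {})
        with pytest.raises(ValueError, match="format"):
            render_tree(build_clone_tree(profile), "nexus")
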