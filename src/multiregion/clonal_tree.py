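"""Clonal phylogeny reconstruction from binary presence matrices.

The model is a perfect phylogeny on binary characters: every mutation is
gained exactly once and never lost, and the ancestral state is all
wild-type. Under that model a single rooted clone tree fitting all cores
exists if and only if the region-sets of the mutations are pairwise nested
or disjoint (a laminar family). Shared (all-core) mutations form the trunk;
each maximal region-set under containment opens a branch; every biopsy core
attaches as a leaf to the clone whose accumulated mutation set equals the
core's observed mutations.

Trunk mutations are mutually unordered (simultaneous all-region mutations
cannot be ordered by presence data) and are carried as a set on the trunk
edge, printed in a canonical gene order for deterministic output. Nonshared
mutations with identical region-sets are indistinguishable by these data
and collapse onto one edge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import dendropy

from .heterogeneity import Mutation, TumorProfile

__all__ = [
    "TopologyCategory",
    "CloneNode",
    "CloneTree",
    "IncompatibleMatrixError",
    "check_compatibility",
    "build_clone_tree",
    "classify_topology",
    "render_tree",
    "parse_newick",
    "replay_presence",
]

#: canonical print order for the five-gene ccRCC panel; unknown genes follow
#: alphabetically
GENE_ORDER = ("VHL", "PBRM1", "SETD2", "BAP1", "KDM5C")


class TopologyCategory(str, Enum):
    """Five-way branching-pattern classification of a tumor."""

    SINGLE_SHARED_ONLY = "single_shared_only"
    MULTIPLE_SHARED_ONLY = "multiple_shared_only"
    SHARED_AND_NONSHARED = "shared_and_nonshared"
    NONSHARED_ONLY = "nonshared_only"
    NO_MUTATIONS = "no_mutations"


class IncompatibleMatrixError(ValueError):
    """Raised when no perfect phylogeny fits the presence matrix."""

    def __init__(self, conflicts: list[tuple[Mutation, Mutation]]):
        self.conflicts = conflicts
        pairs = ", ".join(f"({a.variant_key}, {b.variant_key})" for a, b in conflicts)
        super().__init__(f"no single tree fits these mutations; conflicts: {pairs}")


def _gene_rank(gene: str) -> tuple[int, str]:
    try:
        return (GENE_ORDER.index(gene), gene)
    except ValueError:
        return (len(GENE_ORDER), gene)


def sort_mutations(mutations: Iterable[Mutation]) -> list[Mutation]:
    return sorted(mutations, key=lambda m: (_gene_rank(m.gene), m.variant_key))


@dataclass
class CloneNode:
    """A clone: the mutations acquired on its incoming edge, its subclone
    children, and the biopsy regions attached directly to it."""

    mutations: list[Mutation] = field(default_factory=list)
    children: list["CloneNode"] = field(default_factory=list)
    regions: list[str] = field(default_factory=list)

    def subtree_regions(self) -> list[str]:
        out = list(self.regions)
        for child in self.children:
            out.extend(child.subtree_regions())
        return out

    def walk(self) -> Iterable["CloneNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class CloneTree:
    patient_id: str
    regions: list[str]  # declaration order, preserved for replay
    root: CloneNode

    def n_clones(self) -> int:
        return sum(1 for _ in self.root.walk())


def check_compatibility(profile: TumorProfile) -> list[tuple[Mutation, Mutation]]:
    """Return every pair of mutations whose region-sets overlap without nesting.

    An empty list means a perfect phylogeny exists for this tumor.
    """
    sets = [profile.region_set(i) for i in range(len(profile.mutations))]
    conflicts = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a & b and not (a <= b or b <= a):
                conflicts.append((profile.mutations[i], profile.mutations[j]))
    return conflicts


def build_clone_tree(profile: TumorProfile) -> CloneTree:
    """Order mutations by region-set containment into a rooted clone tree.

    Raises :class:`IncompatibleMatrixError` (carrying the conflict list) when
    the matrix admits no perfect phylogeny; there is no silent repair.
    """
    conflicts = check_compatibility(profile)
    if conflicts:
        raise IncompatibleMatrixError(conflicts)

    full = frozenset(profile.regions)
    # group mutations by region-set; the full set is the trunk (possibly empty)
    by_set: dict[frozenset[str], list[Mutation]] = {full: []}
    for i, mut in enumerate(profile.mutations):
        by_set.setdefault(profile.region_set(i), []).append(mut)

    nodes = {s: CloneNode(mutations=sort_mutations(muts)) for s, muts in by_set.items()}
    order = {r: k for k, r in enumerate(profile.regions)}

    def _set_key(s: frozenset[str]) -> tuple[int, ...]:
        return tuple(sorted(order[r] for r in s))

    # parent of a set is its smallest proper superset among the node sets;
    # laminarity guarantees the smallest superset is unique
    for s in sorted((s for s in nodes if s != full), key=lambda s: (-len(s), _set_key(s))):
        supersets = [t for t in nodes if s < t]
        parent = min(supersets, key=len)
        nodes[parent].children.append(nodes[s])

    # each region attaches to the deepest (smallest) set containing it
    for r in profile.regions:
        containing = [s for s in nodes if r in s]
        nodes[min(containing, key=len)].regions.append(r)

    # canonical child order: by earliest-declared region of the subtree
    for node in nodes.values():
        node.regions.sort(key=order.__getitem__)
        node.children.sort(key=lambda c: min(order[r] for r in c.subtree_regions()))

    tree = CloneTree(patient_id=profile.patient_id, regions=list(profile.regions), root=nodes[full])
    assert sorted(tree.root.subtree_regions()) == sorted(profile.regions)
    return tree


def classify_topology(profile: TumorProfile) -> TopologyCategory:
    """Assign one of the five branching-pattern categories to a tumor."""
    if not profile.labels and profile.mutations:
        raise ValueError("labels not computed; run classify_shared first")
    n = len(profile.mutations)
    n_shared = sum(1 for lab in profile.labels if lab == "shared")
    if n == 0:
        return TopologyCategory.NO_MUTATIONS
    if n_shared == 0:
        return TopologyCategory.NONSHARED_ONLY
    if n_shared == n:
        return (
            TopologyCategory.SINGLE_SHARED_ONLY
            if n == 1
            else TopologyCategory.MULTIPLE_SHARED_ONLY
        )
    return TopologyCategory.SHARED_AND_NONSHARED


# ---------------------------------------------------------------------------
# serialization


def _mut_token(m: Mutation) -> str:
    return f"{m.gene}@{m.variant_key}"


def _parse_mut_token(token: str, patient_id: str) -> Mutation:
    gene, _, key = token.partition("@")
    return Mutation(gene=gene, variant_key=key, patient_id=patient_id)


def _newick_node(node: CloneNode, is_root: bool, tree: CloneTree) -> str:
    parts = [_newick_node(c, False, tree) for c in node.children]
    parts.extend(node.regions)
    label = f"({','.join(parts)})" if parts else ""
    fields = []
    if is_root:
        fields.append(f"patient={tree.patient_id}")
        fields.append("regions=" + "|".join(tree.regions))
    fields.append("muts=" + "|".join(_mut_token(m) for m in node.mutations))
    return f"{label}[&{'&'.join(fields)}]"


def render_tree(tree: CloneTree, format: str = "newick") -> str:
    """Serialize a clone tree as annotated Newick or Graphviz DOT.

    Newick leaves are region ids; each clone node carries a comment with its
    edge mutations (``[&muts=GENE@chrom:pos:ref:alt|...]``); the root comment
    additionally records the patient and the region declaration order, making
    parse -> render lossless. DOT emits one node per clone plus one box per
    region.
    """
    if format == "newick":
        return _newick_node(tree.root, True, tree) + ";"
    if format == "dot":
        return _render_dot(tree)
    raise ValueError(f"unknown format {format!r}; choose 'newick' or 'dot'")


def _render_dot(tree: CloneTree) -> str:
    out = io.StringIO()
    out.write(f'digraph "{tree.patient_id}" {{\n')
    out.write("  node [shape=ellipse];\n")
    ids: dict[int, str] = {}
    for k, node in enumerate(tree.root.walk()):
        ids[id(node)] = f"clone{k}"
        genes = ", ".join(m.gene for m in node.mutations) or "(no mutations)"
        out.write(f'  clone{k} [label="{genes}"];\n')
    for node in tree.root.walk():
        for child in node.children:
            out.write(f"  {ids[id(node)]} -> {ids[id(child)]};\n")
        for r in node.regions:
            out.write(f'  {ids[id(node)]} -> "{r}";\n')
    for r in tree.regions:
        out.write(f'  "{r}" [shape=box];\n')
    out.write("}\n")
    return out.getvalue()


def parse_newick(text: str) -> CloneTree:
    """Parse the annotated Newick dialect written by :func:`render_tree`."""
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
    )
    root_fields = _comment_fields(dtree.seed_node.comments)
    patient_id = root_fields.get("patient", "")
    regions = [r for r in root_fields.get("regions", "").split("|") if r]

    def _convert(dnode) -> CloneNode:
        fields = _comment_fields(dnode.comments)
        muts = [
            _parse_mut_token(tok, patient_id)
            for tok in fields.get("muts", "").split("|")
            if tok
        ]
        node = CloneNode(mutations=muts)
        for child in dnode.child_nodes():
            if child.is_leaf() and not child.comments:
                node.regions.append(child.taxon.label)
            else:
                node.children.append(_convert(child))
        return node

    return CloneTree(patient_id=patient_id, regions=regions, root=_convert(dtree.seed_node))


def _comment_fields(comments: Sequence[str]) -> dict[str, str]:
    fields: dict[str, str] = {}
    for comment in comments:
        for part in comment.lstrip("&").split("&"):
            key, _, value = part.partition("=")
            if key:
                fields[key] = value
    return fields


def replay_presence(tree: CloneTree):
    """Replay edge mutations root-to-leaf, rebuilding the presence matrix.

    Returns ``(mutations, regions, matrix)`` with mutations in canonical
    order and regions in declaration order; for any tree built from a
    compatible profile this reproduces the input matrix exactly.
    """
    import numpy as np

    acc: dict[str, set[str]] = {}  # variant_key -> regions
    muts: dict[str, Mutation] = {}

    def _walk(node: CloneNode, inherited: list[Mutation]) -> None:
        carried = inherited + node.mutations
        for m in node.mutations:
            muts.setdefault(m.variant_key, m)
        for r in node.regions:
            for m in carried:
                acc.setdefault(m.variant_key, set()).add(r)
        for child in node.children:
            _walk(child, carried)

    _walk(tree.root, [])
    ordered = sort_mutations(muts.values())
    matrix = np.zeros((len(ordered), len(tree.regions)), dtype=np.int8)
    col = {r: j for j, r in enumerate(tree.regions)}
    for i, m in enumerate(ordered):
        for r in acc.get(m.variant_key, ()):
            matrix[i, col[r]] = 1
    return ordered, list(tree.regions), matrix
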