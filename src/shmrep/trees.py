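"""Germline-rooted clonal lineage trees with inferred intermediates.

Each unique member sequence of a clone is represented by its set of
substitutions against the germline V segment.  The tree is grown greedily:
sequences are attached in order of increasing mutation count to the existing
node (observed or inferred) whose mutation set is the largest subset of
theirs, and an inferred intermediate is created whenever two branches share
a proper, non-empty common mutation subset not yet represented.  Edge
weights are nucleotide differences between parent and child; reversions are
never inferred, so weights along any root-to-node path sum exactly to the
node's distance from germline.  The heuristic is exact on perfect-phylogeny
input and is checked against exhaustive small-instance search in the tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from shmrep.reference import GermlineReference

MutSet = frozenset  # of (position, to_base) pairs


@dataclass
class TreeNode:
    label: str
    mutations: MutSet
    multiplicity: int = 0  # 0 for inferred / germline-root-only nodes
    inferred: bool = False
    parent: "TreeNode | None" = None
    children: list = field(default_factory=list)

    @property
    def edge_weight(self) -> int:
        if self.parent is None:
            return 0
        return len(self.mutations - self.parent.mutations)


@dataclass
class LineageTree:
    clone_id: str
    root: TreeNode
    nodes: list[TreeNode]

    def node_by_label(self, label: str) -> TreeNode:
        for node in self.nodes:
            if node.label == label:
                return node
        raise KeyError(label)

    def edges(self) -> list[tuple[str, str, int]]:
        out = []
        for node in self.nodes:
            if node.parent is not None:
                out.append((node.parent.label, node.label, node.edge_weight))
        return out


def _mutation_set(sequence: str, germline: str) -> MutSet:
    if len(sequence) != len(germline):
        raise ValueError(
            f"sequence length {len(sequence)} != germline length {len(germline)}"
        )
    return frozenset(
        (i, sequence[i]) for i in range(len(germline)) if sequence[i] != germline[i]
    )


def build_lineage_tree(
    members: list[tuple[str, str]] | list[str],
    ref: GermlineReference,
    clone_id: str = "clone",
) -> LineageTree:
    """Build a germline-rooted minimum-weight lineage tree for one clone.

    ``members`` is a list of aligned V sequences (or (label, sequence)
    pairs); duplicates collapse into one node with multiplicity.  Sequences
    are compared over their common aligned length with the germline.
    """
    germ = ref.sequence
    if members and isinstance(members[0], str):
        members = [(f"seq{i}", s) for i, s in enumerate(members)]

    # deduplicate, preserving first label and counting multiplicity
    counts: Counter[str] = Counter()
    first_label: dict[str, str] = {}
    for label, seq in members:
        seq = seq.upper()[: len(germ)]
        counts[seq] += 1
        first_label.setdefault(seq, label)

    root = TreeNode(label="germline", mutations=frozenset(), multiplicity=0)
    nodes: list[TreeNode] = [root]
    n_inferred = 0

    # germline itself observed -> it contributes multiplicity to the root
    unique = []
    for seq, count in counts.items():
        mset = _mutation_set(seq, germ)
        if not mset:
            root.multiplicity += count
        else:
            unique.append((mset, first_label[seq], count))
    # attach in order of increasing mutation count; lexicographic tie-break
    unique.sort(key=lambda item: (len(item[0]), sorted(item[0])))

    def _attach(mset: MutSet, label: str, count: int, inferred: bool) -> TreeNode:
        """Insert a mutation set into the tree, recursing on shared subsets.

        The parent is the existing node sharing the largest mutation subset
        among nodes that do not already contain ``mset`` (ties prefer true
        ancestors, then larger multiplicity, then label).  When the sharing
        is partial, the shared set itself is attached first (recursively) as
        an inferred intermediate.  After insertion, any node whose mutation
        set strictly contains the new one is re-parented under it if that
        shortens its edge — this is what pulls diverged branches together
        under a common inferred precursor.
        """
        nonlocal n_inferred
        for n in nodes:
            if n.mutations == mset:
                n.multiplicity += count
                if n.inferred and not inferred:
                    n.inferred = False
                    n.label = label
                return n
        candidates = [n for n in nodes if not n.mutations >= mset]
        best = max(
            candidates,
            key=lambda n: (
                len(n.mutations & mset),
                n.mutations <= mset,
                n.multiplicity,
                n.label,
            ),
        )
        shared = best.mutations & mset
        if shared == best.mutations:
            parent = best
        else:
            n_inferred += 1
            parent = _attach(shared, f"inferred_{n_inferred - 1}", 0, True)
        node = TreeNode(
            label=label, mutations=mset, multiplicity=count, inferred=inferred, parent=parent
        )
        parent.children.append(node)
        nodes.append(node)
        # re-parent sweep: supersets of the new node move under it when that
        # shortens their edge (never creates a reversion or a cycle, since a
        # descendant of any superset cannot be the new node)
        for other in nodes:
            if (
                other.parent is not None
                and other is not node
                and node.mutations < other.mutations
                and len(node.mutations) > len(other.parent.mutations)
            ):
                other.parent.children.remove(other)
                other.parent = node
                node.children.append(other)
        return node

    for mset, label, count in unique:
        _attach(mset, label, count, inferred=False)

    return LineageTree(clone_id=clone_id, root=root, nodes=nodes)


def total_tree_weight(tree: LineageTree) -> int:
    """Sum of edge weights = total inferred mutation events in the clone."""
    return sum(node.edge_weight for node in tree.nodes if node.parent is not None)


def write_newick(tree: LineageTree) -> str:
    """Newick text with branch lengths = edge weights; round-trippable."""

    def render(node: TreeNode) -> str:
        label = node.label
        if node.children:
            inner = ",".join(
                f"{render(child)}:{child.edge_weight}" for child in node.children
            )
            return f"({inner}){label}"
        return label

    return render(tree.root) + ";"


def edge_table(tree: LineageTree):
    """Edge-list rows (parent, child, weight, multiplicity, inferred)."""
    import pandas as pd

    rows = [
        {
            "clone_id": tree.clone_id,
            "parent": node.parent.label,
            "child": node.label,
            "weight": node.edge_weight,
            "multiplicity": node.multiplicity,
            "inferred": node.inferred,
        }
        for node in tree.nodes
        if node.parent is not None
    ]
    return pd.DataFrame(
        rows, columns=["clone_id", "parent", "child", "weight", "multiplicity", "inferred"]
    )
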