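"""Rooted phylogenetic trees: Newick I/O, rooting, clades, triples, consensus.

This module is the shared currency of the pipeline.  Trees are rooted,
leaf-labelled, optionally carry non-negative branch lengths (coalescent
units when the tree is a species tree) and per-internal-node support
percentages.  Polytomies are allowed; operations that require binary
trees check and raise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class TreeError(ValueError):
    pass


@dataclass(eq=False)
class Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    parent: "Node | None" = field(default=None, repr=False)
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class RootedTree:
    """A rooted, leaf-labelled tree with unique leaf labels."""

    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.label for leaf in self.leaves()]
        if any(lab is None for lab in labels):
            raise TreeError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def label_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    # -- clades ------------------------------------------------------------

    def clades(self, include_trivial: bool = False) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes below the root.

        Non-trivial clades (the default) have 2 <= size < n_leaves.
        """
        sets = self._node_leafsets()
        n = self.n_leaves
        out = []
        for node, s in sets.items():
            if node is self.root:
                continue
            if include_trivial or (2 <= len(s) < n):
                out.append(s)
        return out

    def _node_leafsets(self) -> dict[int | Node, frozenset[str]]:
        sets: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.label])
            else:
                sets[node] = frozenset().union(*(sets[c] for c in node.children))
        return sets

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        unknown = want - self.label_set()
        if unknown:
            raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
        sets = self._node_leafsets()
        best = self.root
        for node in self.postorder():
            if want <= sets[node] and len(sets[node]) < len(sets[best]):
                best = node
        return best

    def copy(self) -> "RootedTree":
        def rec(node: Node) -> Node:
            clone = Node(label=node.label, length=node.length, support=node.support)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return RootedTree(rec(self.root))

    def __repr__(self) -> str:
        return f"RootedTree({write_newick(self)!r})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEWICK_SPECIAL = set("(),:;[]'")


def parse_newick(text: str, support_labels: bool = True) -> RootedTree:
    """Parse one Newick tree.

    Internal-node labels are interpreted as support percentages when
    ``support_labels`` is true and the label parses as a number; set it to
    False to keep them as plain labels.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def err(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            end = s.find("'", pos + 1)
            if end < 0:
                raise err("unterminated quoted label")
            lab = s[pos + 1 : end]
            pos = end + 1
            return lab
        start = pos
        while pos < len(s) and s[pos] not in _NEWICK_SPECIAL and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def parse_length() -> float | None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise err("invalid branch length") from None
        return None

    def parse_subtree() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_subtree())
                if pos >= len(s):
                    raise err("unexpected end of string inside '('")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise err(f"expected ',' or ')', found {s[pos]!r}")
            lab = parse_label()
            if lab:
                if support_labels:
                    try:
                        node.support = float(lab)
                    except ValueError:
                        node.label = lab
                else:
                    node.label = lab
        else:
            lab = parse_label()
            if not lab:
                raise err("expected a leaf label")
            node.label = lab
        node.length = parse_length()
        return node

    root = parse_subtree()
    if pos >= len(s) or s[pos] != ";":
        raise err("expected ';' terminating the tree")
    pos += 1
    if s[pos:].strip():
        raise err("trailing characters after ';'")
    return RootedTree(root)


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: RootedTree, supports: bool = True) -> str:
    def rec(node: Node) -> str:
        if node.is_leaf:
            out = node.label
        else:
            out = "(" + ",".join(rec(c) for c in node.children) + ")"
            if supports and node.support is not None:
                out += _fmt_len(node.support)
            elif node.label:
                out += node.label
        if node.length is not None:
            out += ":" + _fmt_len(node.length)
        return out

    return rec(tree.root) + ";"


def read_newick_file(path) -> list[RootedTree]:
    """Read one tree per non-empty line (';'-terminated)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(trees: Sequence[RootedTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Canonical form (deterministic ordering, used for tie-breaking and caching)
# ---------------------------------------------------------------------------

def canonical_newick(tree: RootedTree) -> str:
    """Topology-only Newick with children sorted by smallest leaf label."""

    def rec(node: Node) -> tuple[str, str]:
        if node.is_leaf:
            return node.label, node.label
        parts = sorted(rec(c) for c in node.children)
        key = parts[0][0]
        return key, "(" + ",".join(p[1] for p in parts) + ")"

    return rec(tree.root)[1] + ";"


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: RootedTree, outgroup: Iterable[str]) -> RootedTree:
    """Re-root so that the root separates ``outgroup`` from all other leaves.

    The outgroup must form one side of some branch of the unrooted topology;
    the split branch's length is divided equally between the two root children.
    """
    og = frozenset(outgroup)
    labels = tree.label_set()
    unknown = og - labels
    if unknown:
        raise TreeError(f"outgroup labels not in tree: {sorted(unknown)}")
    if not og or og == labels:
        raise TreeError("outgroup must be a proper non-empty subset of the leaves")
    ingroup = labels - og

    work = tree.copy()
    sets = work._node_leafsets()

    # Already rooted correctly?
    if len(work.root.children) == 2:
        kids = work.root.children
        if sets[kids[0]] == og or sets[kids[1]] == og:
            return work

    # Find the edge (child side) whose clade is the outgroup or the ingroup.
    target = None
    for node in work.postorder():
        if node.parent is not None and sets[node] in (og, ingroup):
            target = node
            break
    if target is None:
        best = min(
            (sets[n] for n in work.postorder() if n.parent is not None),
            key=lambda s: len(s.symmetric_difference(og)),
        )
        raise TreeError(
            "outgroup is not separable by a single branch; closest split is "
            f"{sorted(best)}"
        )

    # Re-root on the edge above `target`: reverse parent links up to old root.
    old_parent = target.parent
    old_parent.children.remove(target)
    half = target.length / 2.0 if target.length is not None else None

    new_root = Node()
    new_root.add_child(target)
    target.length = half

    # Walk up, flipping edges: each former parent becomes a child.
    node, carry_len, carry_sup = old_parent, half, target.support
    prev = new_root
    while node is not None:
        parent = node.parent
        if parent is not None:
            parent.children.remove(node)
        node.parent = None
        flipped_len, flipped_sup = node.length, node.support
        node.length, node.support = carry_len, carry_sup
        prev.add_child(node)
        prev, node, carry_len, carry_sup = node, parent, flipped_len, flipped_sup

    # Suppress the old root if it became a unary node.
    def suppress_unary(n: Node) -> None:
        for child in list(n.children):
            suppress_unary(child)
        if len(n.children) == 1 and n.parent is not None:
            child = n.children[0]
            if child.length is not None or n.length is not None:
                child.length = (child.length or 0.0) + (n.length or 0.0)
            n.parent.children[n.parent.children.index(n)] = child
            child.parent = n.parent

    suppress_unary(new_root)
    out = RootedTree(new_root)
    # Orient: outgroup child listed last for readability.
    outsets = out._node_leafsets()
    out.root.children.sort(key=lambda c: (outsets[c] <= og, sorted(outsets[c])[0]))
    return out


def is_monophyletic(tree: RootedTree, labels: Iterable[str]) -> bool:
    """True iff some node's leaf set equals exactly ``labels``."""
    want = frozenset(labels)
    unknown = want - tree.label_set()
    if unknown:
        raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
    sets = tree._node_leafsets()
    return want in sets.values()


def prune_to(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Restrict the tree to ``keep``, suppressing unary nodes (lengths summed)."""
    keep = frozenset(keep)
    unknown = keep - tree.label_set()
    if unknown:
        raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
    if len(keep) < 1:
        raise TreeError("cannot prune to an empty leaf set")

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(label=node.label, length=node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        new = Node(label=node.label, length=node.length, support=node.support)
        for k in kids:
            new.add_child(k)
        return new

    root = rec(tree.root)
    root.length = None
    return RootedTree(root)


# ---------------------------------------------------------------------------
# Rooted triples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RootedTriple:
    """Rooted 3-leaf topology: ``cherry`` pair joins before meeting ``outlier``."""

    taxa: tuple[str, str, str]  # sorted
    cherry: frozenset[str]

    def __post_init__(self):
        if len(set(self.taxa)) != 3:
            raise TreeError("a rooted triple needs three distinct labels")
        if not self.cherry < set(self.taxa) or len(self.cherry) != 2:
            raise TreeError("cherry must be a 2-subset of the taxa")

    @property
    def outlier(self) -> str:
        (o,) = set(self.taxa) - self.cherry
        return o


def extract_rooted_triples(tree: RootedTree) -> list[RootedTriple]:
    """All C(n,3) rooted triples induced by the tree (unresolved ones skipped)."""
    leaves = sorted(tree.leaf_labels())
    if len(leaves) < 3:
        raise TreeError("need at least 3 leaves to extract triples")
    depth = _pairwise_mrca_depth(tree)
    out = []
    for a, b, c in itertools.combinations(leaves, 3):
        dab, dac, dbc = depth[(a, b)], depth[(a, c)], depth[(b, c)]
        if dab > dac and dab > dbc:
            cherry = frozenset((a, b))
        elif dac > dab and dac > dbc:
            cherry = frozenset((a, c))
        elif dbc > dab and dbc > dac:
            cherry = frozenset((b, c))
        else:  # polytomy: unresolved triple
            continue
        out.append(RootedTriple((a, b, c), cherry))
    return out


def _pairwise_mrca_depth(tree: RootedTree) -> dict[tuple[str, str], int]:
    """Topological depth (edges from root) of the MRCA of every leaf pair."""
    leaf_lists: dict[Node, list[str]] = {}
    d = {id(tree.root): 0}
    for node in tree.preorder():
        for c in node.children:
            d[id(c)] = d[id(node)] + 1
    out: dict[tuple[str, str], int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leaf_lists[node] = [node.label]
        else:
            kids = [leaf_lists[c] for c in node.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for x in kids[i]:
                        for y in kids[j]:
                            key = (x, y) if x < y else (y, x)
                            out[key] = d[id(node)]
            merged = []
            for k in kids:
                merged.extend(k)
            leaf_lists[node] = merged
    return out


# ---------------------------------------------------------------------------
# Consensus and comparison
# ---------------------------------------------------------------------------

def _check_same_leaves(trees: Sequence[RootedTree]) -> frozenset[str]:
    ref = trees[0].label_set()
    for t in trees[1:]:
        if t.label_set() != ref:
            diff = sorted(ref.symmetric_difference(t.label_set()))
            raise TreeError(f"trees have different leaf sets; difference: {diff}")
    return ref


def clade_frequencies(trees: Sequence[RootedTree]) -> dict[frozenset[str], int]:
    """Count, over the input trees, how many contain each non-trivial clade."""
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in set(t.clades()):
            counts[clade] = counts.get(clade, 0) + 1
    return counts


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def majority_rule_consensus(
    trees: Sequence[RootedTree], mode: str = "extended"
) -> RootedTree:
    """Majority-rule consensus of rooted trees sharing one leaf set.

    ``strict``: keep exactly the clades occurring in >50% of the trees.
    ``extended``: additionally add compatible minority clades greedily in
    descending frequency (ties at exactly 50% are eligible), the Phylip
    ``consense`` default.  Each retained clade carries its frequency as a
    support percentage.
    """
    if not trees:
        raise TreeError("consensus of an empty tree list")
    if mode not in ("strict", "extended"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    labels = _check_same_leaves(trees)
    n = len(trees)
    counts = clade_frequencies(trees)

    ordered = sorted(
        counts.items(), key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0]))
    )
    accepted: list[tuple[frozenset[str], int]] = []
    for clade, cnt in ordered:
        if cnt * 2 > n:
            accepted.append((clade, cnt))
        elif mode == "extended":
            if all(_compatible(clade, other) for other, _ in accepted):
                accepted.append((clade, cnt))

    # Build the tree: parent of each clade = smallest accepted strict superset.
    accepted.sort(key=lambda kv: -len(kv[0]))
    root = Node(support=100.0)
    node_of: dict[frozenset[str], Node] = {labels: root}
    for clade, cnt in sorted(accepted, key=lambda kv: -len(kv[0])):
        parents = [s for s in node_of if clade < s]
        parent = node_of[min(parents, key=len)]
        node = Node(support=100.0 * cnt / n)
        parent.add_child(node)
        node_of[clade] = node
    for leaf in sorted(labels):
        hosts = [s for s in node_of if leaf in s]
        parent = node_of[min(hosts, key=len)]
        parent.add_child(Node(label=leaf))
    tree = RootedTree(root)
    _sort_children(tree)
    return tree


def _sort_children(tree: RootedTree) -> None:
    sets = tree._node_leafsets()
    for node in tree.postorder():
        node.children.sort(key=lambda c: sorted(sets[c])[0])


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Rooted Robinson–Foulds distance: |symmetric difference of clade sets|."""
    _check_same_leaves([t1, t2])
    return len(set(t1.clades()).symmetric_difference(set(t2.clades())))


def unrooted_rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """RF distance on the unrooted topologies (bipartition symmetric difference)."""
    labels = _check_same_leaves([t1, t2])

    def biparts(t: RootedTree) -> set[frozenset[frozenset[str]]]:
        out = set()
        for clade in t.clades(include_trivial=True):
            if 2 <= len(clade) <= len(labels) - 2:
                out.add(frozenset((clade, labels - clade)))
        return out

    return len(biparts(t1).symmetric_difference(biparts(t2)))
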