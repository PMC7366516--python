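"""Unrooted phylogenetic trees, bipartitions, consensus and RF distance.

``Phylotree`` is a light adjacency-based representation tuned for the search
engine: taxa are indexed 0..n-1 in a fixed canonical order (the ``taxa``
tuple), internal nodes carry larger integer ids, and every internal edge is
identified by a bitmask over taxon indices — the side of the split *not*
containing taxon 0.  Newick parsing and writing are delegated to dendropy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

logger = logging.getLogger(__name__)


@dataclass
class Phylotree:
    """An unrooted multifurcating tree over named leaves.

    ``root_mask`` (optional) marks a root edge by the taxon bitmask of one of
    its sides — set by outgroup rooting and preserved from rooted Newick.
    ``supports`` maps internal-split bitmasks to percent support values.
    """

    taxa: tuple[str, ...]
    adj: dict[int, list[int]]
    root_mask: Optional[int] = None
    supports: dict[int, float] = field(default_factory=dict)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path,
                    taxa: Sequence[str] | None = None) -> "Phylotree":
        """Parse a Newick string (or path to one).  Internal node labels, if
        numeric, are interpreted as clade supports."""
        text = str(source)
        if isinstance(source, Path) or ("(" not in text and Path(text).is_file()):
            text = Path(source).read_text(encoding="utf-8")
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
        return cls.from_dendropy(dtree, taxa=taxa)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree,
                      taxa: Sequence[str] | None = None) -> "Phylotree":
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if taxa is None:
            taxa = tuple(sorted(labels))
        else:
            taxa = tuple(taxa)
        if sorted(labels) != sorted(taxa):
            raise ValueError("leaf labels do not match the supplied taxon set")
        index = {name: i for i, name in enumerate(taxa)}
        adj: dict[int, list[int]] = {}
        ids: dict[int, int] = {}
        next_internal = len(taxa)
        support_nodes: list[tuple[int, float]] = []

        def node_id(nd) -> int:
            nonlocal next_internal
            key = id(nd)
            if key not in ids:
                if nd.is_leaf():
                    ids[key] = index[nd.taxon.label]
                else:
                    ids[key] = next_internal
                    next_internal += 1
            return ids[key]

        for nd in dtree.preorder_node_iter():
            u = node_id(nd)
            adj.setdefault(u, [])
            if not nd.is_leaf() and nd.label is not None:
                try:
                    support_nodes.append((u, float(nd.label)))
                except ValueError:
                    pass
            for ch in nd.child_nodes():
                v = node_id(ch)
                adj.setdefault(v, [])
                adj[u].append(v)
                adj[v].append(u)

        root = node_id(dtree.seed_node)
        root_mask = None
        while root >= len(taxa) and len(adj[root]) == 1:
            # artifact of an outer "(...)" wrapper: drop the degree-1 root
            child = adj[root][0]
            adj[child].remove(root)
            del adj[root]
            root = child
        if root >= len(taxa) and len(adj[root]) == 2:  # rooted newick: suppress the degree-2 root
            a, b = adj[root]
            adj[a].remove(root)
            adj[b].remove(root)
            adj[a].append(b)
            adj[b].append(a)
            del adj[root]
            tree = cls(taxa, adj)
            root_mask = tree._leafmask_side(b, a)
            tree.root_mask = tree._canon_mask(root_mask)
        else:
            tree = cls(taxa, adj)
        for u, val in support_nodes:
            if u in tree.adj:
                mask = tree.split_below(u)
                if mask is not None:
                    tree.supports[mask] = val
        return tree

    def to_dendropy(self, namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        ns = namespace or dendropy.TaxonNamespace(list(self.taxa))
        dtree = dendropy.Tree(taxon_namespace=ns)
        n = len(self.taxa)
        if self.root_mask is not None:
            u, v = self._edge_for_mask(self.root_mask)
        else:
            u = next(i for i in self.adj if i >= n) if any(
                i >= n for i in self.adj) else next(iter(self.adj))
            v = None

        def build(node, parent, dparent):
            if node < n:
                dn = dendropy.Node(taxon=ns.get_taxon(self.taxa[node]))
            else:
                dn = dendropy.Node()
                mask = self._mask_below(node, parent)
                key = self._canon_mask(mask)
                if key in self.supports:
                    dn.label = format_support(self.supports[key])
            dparent.add_child(dn)
            for nb in self.adj[node]:
                if nb != parent:
                    build(nb, node, dn)
            return dn

        if v is None:
            seed = dtree.seed_node
            for nb in self.adj[u]:
                build(nb, u, seed)
        else:
            seed = dtree.seed_node
            build(u, v, seed)
            build(v, u, seed)
        dtree.is_rooted = self.root_mask is not None
        return dtree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(schema="newick",
                                         suppress_rooting=True,
                                         unquoted_underscores=True)
        return s.strip()

    # -- structure ----------------------------------------------------------
    @property
    def nleaves(self) -> int:
        return len(self.taxa)

    def copy(self) -> "Phylotree":
        return Phylotree(self.taxa, {u: list(vs) for u, vs in self.adj.items()},
                         self.root_mask, dict(self.supports))

    def edges(self) -> list[tuple[int, int]]:
        return sorted((u, v) for u, vs in self.adj.items() for v in vs if u < v)

    def _postorder(self, root: int, avoid: int) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents, for the subtree at
        ``root`` reached from ``avoid``."""
        order, stack = [], [(root, avoid)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        order.reverse()
        return order

    def _leafmask_side(self, node: int, parent: int) -> int:
        mask = 0
        for nd, _ in self._postorder(node, parent):
            if nd < self.nleaves:
                mask |= 1 << nd
        return mask

    def _mask_below(self, node: int, parent: int) -> int:
        return self._leafmask_side(node, parent)

    def _canon_mask(self, mask: int) -> int:
        full = (1 << self.nleaves) - 1
        return mask if not (mask & 1) else full ^ mask

    def split_below(self, internal: int) -> int | None:
        """Canonical split mask of the edge above ``internal`` in a leaf-0
        rooted view; None for the node adjacent to the root view."""
        n = self.nleaves
        # parent = neighbour on the path toward leaf 0
        for nb in self.adj[internal]:
            mask = self._leafmask_side(internal, nb)
            if not (mask & 1):
                if 2 <= mask.bit_count() <= n - 2:
                    return mask
                return None
        return None

    def splits(self) -> frozenset[int]:
        """Canonical bitmasks (side excluding taxon 0) of all internal edges."""
        n = self.nleaves
        out = set()
        masks: dict[int, int] = {}
        order = self._postorder(next(iter(self.adj[0])), 0)
        for node, parent in order:
            if node < n:
                masks[node] = 1 << node
            else:
                m = 0
                for nb in self.adj[node]:
                    if nb != parent:
                        m |= masks[nb]
                masks[node] = m
            if node >= n and parent is not None:
                if 2 <= masks[node].bit_count() <= n - 2:
                    out.add(masks[node])
        return frozenset(out)

    def topology_key(self) -> frozenset[int]:
        return self.splits()

    def _edge_for_mask(self, mask: int) -> tuple[int, int]:
        """Find the edge whose split equals ``mask`` (canonical or not)."""
        mask = self._canon_mask(mask)
        n = self.nleaves
        for u, v in self.edges():
            m = self._canon_mask(self._leafmask_side(v, u))
            if m == mask:
                return (u, v)
        raise ValueError("no edge realises the requested split")

    # -- comparisons --------------------------------------------------------
    def __eq__(self, other) -> bool:  # topology identity
        return (isinstance(other, Phylotree) and self.taxa == other.taxa
                and self.splits() == other.splits())

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits()))


def format_support(value: float) -> str:
    return str(int(round(value)))


def robinson_foulds(a: Phylotree, b: Phylotree) -> int:
    """Symmetric difference of the internal bipartition sets."""
    if a.taxa != b.taxa:
        raise ValueError("trees are over different leaf sets")
    return len(a.splits() ^ b.splits())


def _compatible(m1: int, m2: int, full: int) -> bool:
    return (m1 & m2 == 0 or m1 & m2 == m1 or m1 & m2 == m2
            or (m1 | m2) == full)


def tree_from_splits(splits: Iterable[int], taxa: Sequence[str],
                     supports: Mapping[int, float] | None = None) -> Phylotree:
    """Build the (possibly multifurcating) tree realising a compatible set of
    canonical splits (sides excluding taxon 0)."""
    taxa = tuple(taxa)
    n = len(taxa)
    full = (1 << n) - 1
    splits = sorted(set(splits), key=lambda m: m.bit_count())
    for i, m1 in enumerate(splits):
        for m2 in splits[i + 1:]:
            if not _compatible(m1, m2, full):
                raise ValueError("incompatible split set")
    # treat each split as a clade in the tree rooted at leaf 0
    next_id = n
    node_of: dict[int, int] = {}
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    root = next_id
    next_id += 1
    adj[root] = []

    def connect(u, v):
        adj[u].append(v)
        adj[v].append(u)

    # parent of a clade = smallest strictly-containing clade, else root
    clades = sorted(splits, key=lambda m: m.bit_count())
    for m in clades:
        node_of[m] = next_id
        adj[next_id] = []
        next_id += 1
    for m in clades:
        parent = root
        best = None
        for other in clades:
            if other != m and (m & other) == m:
                if best is None or other.bit_count() < best.bit_count():
                    best = other
        parent = node_of[best] if best is not None else root
        connect(node_of[m], parent)
    for leaf in range(1, n):
        best = None
        for m in clades:
            if m >> leaf & 1:
                if best is None or m.bit_count() < best.bit_count():
                    best = m
        connect(leaf, node_of[best] if best is not None else root)
    connect(0, root)
    tree = Phylotree(taxa, adj)
    if supports:
        tree.supports = {m: supports[m] for m in splits if m in supports}
    return tree


def strict_consensus(trees: Sequence[Phylotree]) -> Phylotree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValueError("consensus of an empty tree set")
    taxa = trees[0].taxa
    if any(t.taxa != taxa for t in trees):
        raise ValueError("trees are over different leaf sets")
    common = frozenset.intersection(*[t.splits() for t in trees])
    return tree_from_splits(common, taxa)


def majority_rule(trees: Sequence[Phylotree], threshold: float = 0.5
                  ) -> Phylotree:
    """Tree containing the splits present in more than ``threshold`` of the
    input trees (threshold >= 0.5 guarantees compatibility)."""
    if not trees:
        raise ValueError("consensus of an empty tree set")
    if threshold < 0.5:
        raise ValueError("majority-rule threshold must be >= 0.5")
    taxa = trees[0].taxa
    if any(t.taxa != taxa for t in trees):
        raise ValueError("trees are over different leaf sets")
    counts: dict[int, int] = {}
    for t in trees:
        for m in t.splits():
            counts[m] = counts.get(m, 0) + 1
    keep = [m for m, c in counts.items() if c / len(trees) > threshold]
    supports = {m: 100.0 * counts[m] / len(trees) for m in keep}
    return tree_from_splits(keep, taxa, supports)


def root_on_outgroup(tree: Phylotree, outgroup: Iterable[str]) -> Phylotree:
    """Root on the edge separating the outgroup from the ingroup.

    When the outgroup is not a clade of the unrooted topology, the root is
    placed on the edge that best separates outgroup from ingroup and a
    warning is issued.
    """
    outgroup = set(outgroup)
    unknown = outgroup - set(tree.taxa)
    if unknown:
        raise ValueError(f"outgroup taxa not in tree: {sorted(unknown)}")
    if not outgroup or outgroup == set(tree.taxa):
        raise ValueError("outgroup must be a proper non-empty subset of leaves")
    n = tree.nleaves
    omask = 0
    for name in outgroup:
        omask |= 1 << tree.taxa.index(name)
    full = (1 << n) - 1
    best_edge, best_score, exact = None, -1, False
    for u, v in tree.edges():
        side = tree._leafmask_side(v, u)
        score = max((side & omask).bit_count() + ((full ^ side) & ~omask & full).bit_count(),
                    ((full ^ side) & omask).bit_count() + (side & ~omask & full).bit_count())
        if side == omask or side == full ^ omask:
            best_edge, exact = (u, v), True
            break
        if score > best_score:
            best_edge, best_score = (u, v), score
    if not exact:
        warnings.warn("outgroup is not monophyletic on this topology; rooting "
                      "on the edge that best separates it", stacklevel=2)
    u, v = best_edge
    rooted = tree.copy()
    rooted.root_mask = tree._canon_mask(tree._leafmask_side(v, u))
    return rooted


def read_trees(path: str | Path, taxa: Sequence[str] | None = None
               ) -> list[Phylotree]:
    """Read one Newick tree per line (blank lines ignored)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            out.append(Phylotree.from_newick(line.strip(), taxa=taxa))
    return out


def write_trees(trees: Iterable[Phylotree], path: str | Path) -> None:
    Path(path).write_text(
        "".join(t.to_newick() + "\n" for t in trees), encoding="utf-8")
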