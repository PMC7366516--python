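"""Maximum parsimony on binary matrices: Fitch lengths, exhaustive and
TBR-heuristic search, nonparametric bootstrap, and ensemble statistics.

The engine scores trees with Fitch's algorithm for unordered characters.  All
characters of a matrix are packed two bits per character into Python integers,
so one tree evaluation costs a handful of bitwise operations per internal
node regardless of character count.  Missing states (``?``) enter as the full
state set {0, 1} (union semantics), so they never force a change.

Multifurcating trees (consensus topologies) are scored with Hartigan's
generalisation, which coincides with Fitch on binary trees.

Search follows classic PAUP-style practice: random-addition-sequence stepwise
addition followed by tree-bisection-reconnection (TBR) hill climbing, keeping
a pool of all equally parsimonious trees found; the exhaustive search
enumerates all (2n-5)!! unrooted binary topologies and is the oracle for the
heuristic on small problems.  All tie-breaking is driven by the seeded RNG or
by a canonical edge ordering — never by ambient hash order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .coding import MISSING, CharacterMatrix, classification_counts
from .trees import (
    Phylotree,
    majority_rule,
    robinson_foulds,
    strict_consensus,
    tree_from_splits,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchResult", "BootstrapResult", "fitch_length", "fitch_steps_per_char",
    "exhaustive_search", "heuristic_search", "tbr_neighbors", "bootstrap",
    "tree_statistics", "n_unrooted_topologies", "strict_consensus",
    "majority_rule", "robinson_foulds",
]


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labelled leaves."""
    if n < 3:
        return 1
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


# ---------------------------------------------------------------------------
# Packed-bitset Fitch machinery (internal)
# ---------------------------------------------------------------------------

def _pack_rows(states: np.ndarray) -> tuple[list[int], int, int]:
    """Pack a (ntaxa, nchar) {0,1,-1} grid into one integer per taxon.

    Character j occupies bits 2j (state 0) and 2j+1 (state 1); ``?`` sets both.
    Returns (codes, mask_lo, nchar)."""
    ntaxa, nchar = states.shape
    mask_lo = 0
    for j in range(nchar):
        mask_lo |= 1 << (2 * j)
    codes = []
    for i in range(ntaxa):
        code = 0
        row = states[i]
        for j in range(nchar):
            v = row[j]
            if v == 0:
                code |= 1 << (2 * j)
            elif v == 1:
                code |= 1 << (2 * j + 1)
            else:
                code |= 0b11 << (2 * j)
        codes.append(code)
    return codes, mask_lo, nchar


def _postorder_adj(adj: dict[int, list[int]], root: int, avoid: int
                   ) -> list[tuple[int, int]]:
    order, stack = [], [(root, avoid)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    order.reverse()
    return order


def _fitch_adj(adj: dict[int, list[int]], n: int, codes: Sequence[int],
               mask_lo: int) -> int:
    """Fitch length of an unrooted binary tree given packed leaf codes."""
    r = 0 if 0 in adj else min(k for k in adj if k < n)
    top = adj[r][0]
    sets: dict[int, int] = {}
    changes = 0
    for node, parent in _postorder_adj(adj, top, r):
        if node < n:
            sets[node] = codes[node]
            continue
        a = b = None
        for nb in adj[node]:
            if nb == parent:
                continue
            if a is None:
                a = sets[nb]
            else:
                b = sets[nb]
        inter = a & b
        nz = (inter | (inter >> 1)) & mask_lo
        empty = (~nz) & mask_lo
        changes += empty.bit_count()
        sets[node] = inter | ((a | b) & (empty | (empty << 1)))
    inter = codes[r] & sets[top]
    nz = (inter | (inter >> 1)) & mask_lo
    changes += ((~nz) & mask_lo).bit_count()
    return changes


def _splits_adj(adj: dict[int, list[int]], n: int) -> frozenset[int]:
    top = adj[0][0]
    masks: dict[int, int] = {}
    out = set()
    for node, parent in _postorder_adj(adj, top, 0):
        if node < n:
            masks[node] = 1 << node
            continue
        m = 0
        for nb in adj[node]:
            if nb != parent:
                m |= masks[nb]
        masks[node] = m
        if 2 <= m.bit_count() <= n - 2:
            out.add(m)
    return frozenset(out)


def _copy_adj(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {u: list(vs) for u, vs in adj.items()}


def _edges_adj(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return sorted((u, v) for u, vs in adj.items() for v in vs if u < v)


def _validate(tree: Phylotree, matrix: CharacterMatrix) -> None:
    if set(tree.taxa) != set(matrix.taxa):
        raise ValueError("tree leaf set does not match matrix taxa")


def _codes_for(tree_taxa: Sequence[str], matrix: CharacterMatrix):
    idx = [matrix.taxa.index(t) for t in tree_taxa]
    return _pack_rows(matrix.states[idx])


# ---------------------------------------------------------------------------
# Public scoring
# ---------------------------------------------------------------------------

def fitch_length(tree: Phylotree, matrix: CharacterMatrix) -> int:
    """Minimum number of state changes the matrix requires on ``tree``.

    Exact for binary and multifurcating trees; independent of rooting.
    """
    _validate(tree, matrix)
    n = tree.nleaves
    binary = all(len(vs) == 3 for u, vs in tree.adj.items() if u >= n)
    if binary and n >= 3:
        codes, mask_lo, _ = _codes_for(tree.taxa, matrix)
        return _fitch_adj(tree.adj, n, codes, mask_lo)
    return int(fitch_steps_per_char(tree, matrix).sum())


def fitch_steps_per_char(tree: Phylotree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimum change counts on ``tree`` (Hartigan upward pass;
    handles polytomies)."""
    _validate(tree, matrix)
    n = tree.nleaves
    nchar = matrix.ncharacters
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    leaf_sets = np.zeros((n, nchar, 2), dtype=bool)
    for li, name in enumerate(tree.taxa):
        col = matrix.states[row_of[name]]
        leaf_sets[li, :, 0] = (col == 0) | (col == MISSING)
        leaf_sets[li, :, 1] = (col == 1) | (col == MISSING)
    steps = np.zeros(nchar, dtype=np.int64)
    if n < 2 or nchar == 0:
        return steps
    top = tree.adj[0][0]
    sets: dict[int, np.ndarray] = {}
    for node, parent in tree._postorder(top, 0):
        if node < n:
            sets[node] = leaf_sets[node]
            continue
        children = [sets[nb] for nb in tree.adj[node] if nb != parent]
        counts = np.sum(children, axis=0)  # (nchar, 2)
        k = counts.max(axis=1)
        steps += len(children) - k
        sets[node] = counts == k[:, None]
    counts = sets[top].astype(np.int64) + leaf_sets[0]
    steps += 2 - counts.max(axis=1)
    return steps


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    """Most-parsimonious trees plus length and ensemble statistics."""

    mp_trees: list[Phylotree]
    length: int
    ci: float
    hi: float
    ri: Optional[float]
    per_character_min_steps: np.ndarray
    per_character_observed_steps: np.ndarray
    search_log: dict

    @property
    def n_trees(self) -> int:
        return len(self.mp_trees)

    def topology_keys(self) -> frozenset[frozenset[int]]:
        return frozenset(t.topology_key() for t in self.mp_trees)


@dataclass
class BootstrapResult:
    """Per-clade bootstrap supports and the support-annotated consensus."""

    taxa: tuple[str, ...]
    split_support: dict[int, float]  # canonical split mask -> percent
    replicates: int
    seed: Optional[int]
    consensus: Phylotree
    degenerate: bool = False

    def support(self, clade: Iterable[str]) -> float:
        """Support (percent of replicates) for the bipartition separating
        ``clade`` from the remaining taxa; 0.0 if never seen."""
        mask = 0
        for name in clade:
            mask |= 1 << self.taxa.index(name)
        full = (1 << len(self.taxa)) - 1
        if mask & 1:
            mask = full ^ mask
        return self.split_support.get(mask, 0.0)

    def clade_supports(self) -> dict[frozenset[str], float]:
        out = {}
        for mask, pct in self.split_support.items():
            names = frozenset(self.taxa[i] for i in range(len(self.taxa))
                              if mask >> i & 1)
            out[names] = pct
        return out


def _min_steps(matrix: CharacterMatrix) -> np.ndarray:
    m = np.zeros(matrix.ncharacters, dtype=np.int64)
    for j in range(matrix.ncharacters):
        col = matrix.states[:, j]
        if np.any(col == 0) and np.any(col == 1):
            m[j] = 1
    return m


def _max_steps_star(matrix: CharacterMatrix) -> np.ndarray:
    M = np.zeros(matrix.ncharacters, dtype=np.int64)
    for j in range(matrix.ncharacters):
        col = matrix.states[:, j]
        M[j] = min(int(np.sum(col == 0)), int(np.sum(col == 1)))
    return M


def tree_statistics(result: "SearchResult | Phylotree",
                    matrix: CharacterMatrix) -> dict:
    """Consistency, homoplasy and retention indices on a most-parsimonious
    tree: CI = Σmin/L, HI = 1 − CI, RI = (ΣMax − L)/(ΣMax − Σmin)."""
    tree = result.mp_trees[0] if isinstance(result, SearchResult) else result
    obs = fitch_steps_per_char(tree, matrix)
    L = int(obs.sum())
    m = _min_steps(matrix)
    M = _max_steps_star(matrix)
    if L == 0:
        logger.info("tree length is 0; CI defined as 1.0 by convention")
        ci = 1.0
    else:
        ci = float(m.sum()) / L
    hi = 1.0 - ci
    denom = int(M.sum() - m.sum())
    ri = float(M.sum() - L) / denom if denom > 0 else None
    return {"ci": ci, "hi": hi, "ri": ri, "length": L,
            "min_steps": m, "max_steps": M, "observed_steps": obs}


def _make_result(matrix: CharacterMatrix, pool: Mapping[frozenset, dict],
                 length: int, log: dict) -> SearchResult:
    taxa = tuple(matrix.taxa)
    trees = [Phylotree(taxa, _copy_adj(adj)) for adj in pool.values()]
    trees.sort(key=lambda t: sorted(t.splits()))
    stats = tree_statistics(trees[0], matrix)
    assert stats["length"] == length
    return SearchResult(
        mp_trees=trees, length=length, ci=stats["ci"], hi=stats["hi"],
        ri=stats["ri"], per_character_min_steps=stats["min_steps"],
        per_character_observed_steps=stats["observed_steps"], search_log=log)


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------

def exhaustive_search(matrix: CharacterMatrix, max_taxa: int = 10
                      ) -> SearchResult:
    """Evaluate every unrooted binary topology; returns all optimal trees.

    Deterministic; refuses more than ``max_taxa`` taxa (the topology count is
    (2n-5)!!) — use :func:`heuristic_search` for larger problems.
    """
    n = matrix.ntaxa
    if n < 3:
        raise ValueError("exhaustive search needs at least 3 taxa")
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa would require {n_unrooted_topologies(n):,} topologies; "
            "use heuristic_search for problems this large")
    codes, mask_lo, _ = _pack_rows(matrix.states)
    c = n  # first internal node id
    adj: dict[int, list[int]] = {0: [c], 1: [c], 2: [c], c: [0, 1, 2]}
    best_len = None
    pool: dict[frozenset, dict] = {}
    evaluated = 0

    def rec(k: int) -> None:
        nonlocal best_len, evaluated
        if k == n:
            length = _fitch_adj(adj, n, codes, mask_lo)
            evaluated += 1
            if best_len is None or length < best_len:
                best_len = length
                pool.clear()
            if length == best_len:
                pool[_splits_adj(adj, n)] = _copy_adj(adj)
            return
        w = n + k - 2
        for (u, v) in _edges_adj(adj):
            adj[u].remove(v)
            adj[v].remove(u)
            adj[u].append(w)
            adj[v].append(w)
            adj[w] = [u, v, k]
            adj[k] = [w]
            rec(k + 1)
            del adj[w], adj[k]
            adj[u].remove(w)
            adj[v].remove(w)
            adj[u].append(v)
            adj[v].append(u)

    if n == 3:
        best_len = _fitch_adj(adj, n, codes, mask_lo)
        evaluated = 1
        pool[_splits_adj(adj, n)] = _copy_adj(adj)
    else:
        rec(3)
    log = {"method": "exhaustive", "topologies_evaluated": evaluated,
           "n_taxa": n, "n_characters": matrix.ncharacters}
    return _make_result(matrix, pool, best_len, log)


# ---------------------------------------------------------------------------
# TBR neighbourhood
# ---------------------------------------------------------------------------

def _fragment_nodes(adj, start):
    seen, stack = {start}, [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _tbr_all(adj: dict[int, list[int]], n: int) -> list[dict[int, list[int]]]:
    """All TBR rearrangements of an unrooted binary tree (may include
    topological duplicates; callers dedupe by splits)."""
    out = []
    for (u, v) in _edges_adj(adj):
        base = _copy_adj(adj)
        base[u].remove(v)
        base[v].remove(u)
        spare = []
        for x in (u, v):
            if len(base[x]) == 2:  # suppress degree-2 cut vertex
                a, b = base[x]
                base[a].remove(x)
                base[b].remove(x)
                base[a].append(b)
                base[b].append(a)
                del base[x]
                spare.append(x)
        out.extend(_tbr_reconnections(base, spare))
    return out


def _tbr_reconnections(base, spare):
    # the bisected tree has exactly two components; leaves are never
    # suppressed, so a single-leaf fragment survives as a bare node
    comps = []
    remaining = set(base)
    while remaining:
        c = _fragment_nodes(base, next(iter(remaining)))
        comps.append(c)
        remaining -= c
    assert len(comps) == 2, "bisection must yield two fragments"
    frag1, frag2 = comps
    spare = list(spare)
    results = []

    def attach_points(frag):
        if len(frag) == 1:
            return [None]  # the bare node itself
        return [(a, b) for a in sorted(frag) for b in base[a] if a < b
                and b in frag]

    for e1 in attach_points(frag1):
        for e2 in attach_points(frag2):
            new = _copy_adj(base)
            free = list(spare)

            def subdivide(edge, frag):
                if edge is None:
                    return next(iter(frag))
                a, b = edge
                r = free.pop()
                new[a].remove(b)
                new[b].remove(a)
                new[a].append(r)
                new[b].append(r)
                new[r] = [a, b]
                return r

            p1 = subdivide(e1, frag1)
            p2 = subdivide(e2, frag2)
            new[p1].append(p2)
            new[p2].append(p1)
            results.append(new)
    return results


def tbr_neighbors(tree: Phylotree) -> list[Phylotree]:
    """All distinct topologies reachable by one TBR move (input excluded)."""
    n = tree.nleaves
    if n < 4:
        raise ValueError("TBR needs at least 4 leaves")
    own = _splits_adj(tree.adj, n)
    seen = {own}
    out = []
    for adj in _tbr_all(tree.adj, n):
        key = _splits_adj(adj, n)
        if key not in seen:
            seen.add(key)
            out.append(Phylotree(tree.taxa, adj))
    return out


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------

def _stepwise_addition(order: Sequence[int], n: int, codes, mask_lo,
                       rng: np.random.Generator) -> dict[int, list[int]]:
    c = n
    adj: dict[int, list[int]] = {order[0]: [c], order[1]: [c], order[2]: [c],
                                 c: [order[0], order[1], order[2]]}
    for k in range(3, n):
        leaf = order[k]
        w = n + k - 2
        best_len, best_edges = None, []
        for (u, v) in _edges_adj(adj):
            adj[u].remove(v)
            adj[v].remove(u)
            adj[u].append(w)
            adj[v].append(w)
            adj[w] = [u, v, leaf]
            adj[leaf] = [w]
            length = _fitch_adj(adj, n, codes, mask_lo)
            if best_len is None or length < best_len:
                best_len, best_edges = length, [(u, v)]
            elif length == best_len:
                best_edges.append((u, v))
            del adj[w], adj[leaf]
            adj[u].remove(w)
            adj[v].remove(w)
            adj[u].append(v)
            adj[v].append(u)
        u, v = best_edges[int(rng.integers(len(best_edges)))]
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].append(w)
        adj[v].append(w)
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
    return adj


def _hill_climb(adj, n, codes, mask_lo, maxtrees=None):
    best = _fitch_adj(adj, n, codes, mask_lo)
    pool = {_splits_adj(adj, n): _copy_adj(adj)}
    frontier = [adj]
    while frontier:
        current = frontier.pop()
        for nb in _tbr_all(current, n):
            length = _fitch_adj(nb, n, codes, mask_lo)
            if length < best:
                best = length
                pool = {_splits_adj(nb, n): _copy_adj(nb)}
                frontier = [nb]  # restart the plateau from the better tree
                break
            if length == best:
                key = _splits_adj(nb, n)
                if key not in pool and (maxtrees is None or len(pool) < maxtrees):
                    pool[key] = _copy_adj(nb)
                    frontier.append(nb)
    return best, pool


def heuristic_search(matrix: CharacterMatrix, n_addition_replicates: int = 10,
                     seed: int | None = None, maxtrees: int | None = None
                     ) -> SearchResult:
    """Random-addition-sequence stepwise addition + TBR branch swapping.

    Each replicate adds taxa in a random order (greedy placement, ties broken
    by the seeded RNG) and swaps to a local optimum, keeping every
    equally-parsimonious tree found; results are pooled over replicates and
    deduplicated by topology.  Fully reproducible for a fixed seed.
    """
    n = matrix.ntaxa
    if n < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    if n_addition_replicates < 1:
        raise ValueError("need at least one addition replicate")
    rng = np.random.default_rng(seed)
    codes, mask_lo, _ = _pack_rows(matrix.states)
    global_best, global_pool = None, {}
    for rep in range(n_addition_replicates):
        order = list(rng.permutation(n))
        adj = _stepwise_addition(order, n, codes, mask_lo, rng)
        best, pool = _hill_climb(adj, n, codes, mask_lo, maxtrees=maxtrees)
        if global_best is None or best < global_best:
            global_best, global_pool = best, dict(pool)
        elif best == global_best:
            for key, a in pool.items():
                if key not in global_pool and (
                        maxtrees is None or len(global_pool) < maxtrees):
                    global_pool[key] = a
    log = {"method": "heuristic", "tbr": True,
           "n_addition_replicates": n_addition_replicates, "seed": seed,
           "maxtrees": maxtrees, "n_taxa": n,
           "n_characters": matrix.ncharacters}
    return _make_result(matrix, global_pool, global_best, log)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _run_search(matrix: CharacterMatrix, config: Mapping, seed: int | None
                ) -> SearchResult:
    method = config.get("method", "heuristic")
    if method == "exhaustive":
        return exhaustive_search(matrix, max_taxa=config.get("max_taxa", 10))
    return heuristic_search(
        matrix, n_addition_replicates=config.get("n_addition_replicates", 10),
        seed=seed, maxtrees=config.get("maxtrees"))


def bootstrap(matrix: CharacterMatrix, replicates: int = 1000,
              seed: int | None = None,
              search: Mapping | None = None) -> BootstrapResult:
    """Nonparametric bootstrap over characters.

    Per replicate: resample characters with replacement to the original
    count, run the configured search (default: heuristic with 2 addition
    replicates — a fast profile adequate for resampled matrices), and record
    the splits of the replicate's strict consensus of MP trees.  Support is
    the percentage of replicates containing each split.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    search = dict(search or {"method": "heuristic", "n_addition_replicates": 2})
    rng = np.random.default_rng(seed)
    nchar = matrix.ncharacters
    degenerate = classification_counts(matrix)["informative"] == 0
    if degenerate:
        logger.warning("no parsimony-informative characters; bootstrap "
                       "supports will be uninformative")
    counts: dict[int, int] = {}
    taxa = tuple(matrix.taxa)
    for _ in range(replicates):
        cols = rng.integers(0, nchar, size=nchar)
        sub = CharacterMatrix(
            list(matrix.taxa),
            [_relabelled(matrix.characters[j], i) for i, j in enumerate(cols)],
            matrix.states[:, cols])
        rep_seed = int(rng.integers(2 ** 31))
        result = _run_search(sub, search, rep_seed)
        consensus_splits = frozenset.intersection(
            *[t.splits() for t in result.mp_trees])
        for m in consensus_splits:
            counts[m] = counts.get(m, 0) + 1
    support = {m: 100.0 * c / replicates for m, c in counts.items()}
    keep = [m for m, pct in support.items() if pct > 50.0]
    consensus = tree_from_splits(keep, taxa, supports=support)
    return BootstrapResult(taxa=taxa, split_support=support,
                           replicates=replicates, seed=seed,
                           consensus=consensus, degenerate=degenerate)


def _relabelled(char, i):
    from dataclasses import replace
    return replace(char, id=f"{char.id}__bs{i}")
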