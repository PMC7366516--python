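import importlib.resources as resources
from pathlib import Path

import numpy as np
import pytest

from karyophylo import CharacterMatrix, Phylotree, RearrangementCharacter


def data_path(name: str) -> Path:
    return Path(resources.files("karyophylo") / "data" / name)


def generic_matrix(states, taxa=None) -> CharacterMatrix:
    """Build a matrix of anonymous binary characters from a {0,1,-1} grid."""
    states = np.asarray(states, dtype=np.int8)
    taxa = list(taxa) if taxa else [f"t{i}" for i in range(states.shape[0])]
    chars = [RearrangementCharacter(id=f"c{j + 1}", kind="other-discrete")
             for j in range(states.shape[1])]
    return CharacterMatrix(taxa, chars, states)


def random_matrix(rng: np.random.Generator, ntaxa: int, nchar: int,
                  missing_frac: float = 0.0) -> CharacterMatrix:
    states = rng.integers(0, 2, size=(ntaxa, nchar)).astype(np.int8)
    if missing_frac:
        mask = rng.random((ntaxa, nchar)) < missing_frac
        # keep at least one observed state per column
        for j in range(nchar):
            if mask[:, j].all():
                mask[rng.integers(ntaxa), j] = False
        states[mask] = -1
    return generic_matrix(states)


def random_topology(rng: np.random.Generator, taxa) -> Phylotree:
    """Uniform-ish random unrooted binary topology by random stepwise addition."""
    taxa = tuple(taxa)
    n = len(taxa)
    c = n
    adj = {0: [c], 1: [c], 2: [c], c: [0, 1, 2]}
    for k in range(3, n):
        edges = sorted((u, v) for u, vs in adj.items() for v in vs if u < v)
        u, v = edges[int(rng.integers(len(edges)))]
        w = n + k - 2
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].append(w)
        adj[v].append(w)
        adj[w] = [u, v, k]
        adj[k] = [w]
    return Phylotree(taxa, adj)


def brute_force_length(tree: Phylotree, matrix) -> int:
    """Independent parsimony oracle: enumerate every assignment of states to
    internal nodes (and to leaves with missing data) and count edge changes."""
    from itertools import product

    n = tree.nleaves
    row = {t: i for i, t in enumerate(matrix.taxa)}
    edges = tree.edges()
    total = 0
    for j in range(matrix.ncharacters):
        fixed = {}
        free = []
        for li, name in enumerate(tree.taxa):
            v = int(matrix.states[row[name], j])
            if v == -1:
                free.append(li)
            else:
                fixed[li] = v
        internal = [u for u in tree.adj if u >= n]
        best = None
        for assign in product((0, 1), repeat=len(internal) + len(free)):
            state = dict(fixed)
            state.update(zip(internal, assign))
            state.update(zip(free, assign[len(internal):]))
            cost = sum(state[u] != state[v] for u, v in edges)
            best = cost if best is None else min(best, cost)
        total += best
    return total


@pytest.fixture
def quartet_matrix():
    return generic_matrix([[1], [1], [0], [0]], taxa=["A", "B", "C", "D"])
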