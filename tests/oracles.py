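"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive -- O(n^2) scans, quadratic DP, direct
enumeration -- and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def comp(s: str) -> str:
    return "".join(_COMP[b] for b in s)


# hand-entered NCBI translation table 4 (mold/protozoan/coelenterate
# mitochondrial): standard code with TGA -> Trp
CODE4 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate4(cds: str) -> str:
    aa = [CODE4[cds[i : i + 3]] for i in range(0, len(cds), 3)]
    if aa and aa[-1] == "*":
        aa.pop()
    return "".join(aa)


# ---------------------------------------------------------------------------
# maximal exact repeats by full diagonal scan


def _transform(s: str, orientation: str) -> str:
    return {
        "forward": s,
        "reverse": s[::-1],
        "complement": comp(s),
        "palindromic": revcomp(s),
    }[orientation]


def brute_force_exact_repeats(
    s: str, min_len: int, kinds=("forward", "reverse", "complement", "palindromic")
) -> set[tuple]:
    """All maximal exact pairs as {(a, b, orientation, length)} with
    0-based half-open intervals a <= b."""
    L = len(s)
    out: set[tuple] = set()
    for orientation in kinds:
        t = _transform(s, orientation)
        sa = np.frombuffer(s.encode(), dtype=np.uint8)
        ta = np.frombuffer(t.encode(), dtype=np.uint8)
        for d in range(-(L - min_len), L - min_len + 1):
            i0, j0 = (max(0, d), max(0, -d))
            n = L - abs(d)
            if n < min_len:
                continue
            eq = sa[i0 : i0 + n] == ta[j0 : j0 + n]
            k = 0
            while k < n:
                if not eq[k]:
                    k += 1
                    continue
                start = k
                while k < n and eq[k]:
                    k += 1
                run = k - start
                if run < min_len:
                    continue
                i, j = i0 + start, j0 + start
                a = (i, i + run)
                if orientation in ("forward", "complement"):
                    b = (j, j + run)
                else:
                    b = (L - j - run, L - j)
                if a == b:
                    continue
                pair = (a, b) if a <= b else (b, a)
                out.add((pair[0], pair[1], orientation, run))
    return out


# ---------------------------------------------------------------------------
# signed circular adjacency / breakpoint oracle


def _neg(g: str) -> str:
    return ("-" if g[0] == "+" else "+") + g[1:]


def oracle_adjacencies(order) -> set:
    n = len(order)
    adj = set()
    for i in range(n):
        a, b = order[i], order[(i + 1) % n]
        adj.add(min((a, b), (_neg(b), _neg(a))))
    return adj


def oracle_breakpoints(order_a, order_b) -> int:
    """Breakpoints of a relative to b (same gene set, both signed circular)."""
    return len(oracle_adjacencies(order_a) - oracle_adjacencies(order_b))


# ---------------------------------------------------------------------------
# affine-gap global alignment score (Gotoh DP)


def gotoh_score(a: str, b: str, matrix, open_pen: float, extend_pen: float) -> float:
    """Optimal global score; first gap position costs open, later extend."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_pen - (i - 1) * extend_pen
    for j in range(1, m + 1):
        Y[0][j] = -open_pen - (j - 1) * extend_pen
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + matrix[a[i - 1], b[j - 1]]
            X[i][j] = max(M[i - 1][j] - open_pen, X[i - 1][j] - extend_pen)
            Y[i][j] = max(M[i][j - 1] - open_pen, Y[i][j - 1] - extend_pen)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# additive distances on a random tree (for NJ recovery tests)


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths -> (taxa, D, splits).

    splits is the set of non-trivial bipartitions as frozensets of taxon
    labels (smaller side).
    """
    import itertools

    labels = [f"t{i}" for i in range(n_taxa)]
    # build a random topology by sequential leaf attachment
    edges: dict[int, list] = {}
    next_id = n_taxa
    nodes = [0, 1, 2]
    center = next_id
    next_id += 1
    adj: dict[int, dict[int, float]] = {center: {}}
    for leaf in nodes:
        w = float(rng.uniform(0.1, 1.0))
        adj.setdefault(leaf, {})[center] = w
        adj[center][leaf] = w
    for leaf in range(3, n_taxa):
        # pick a random edge and subdivide
        pairs = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = pairs[rng.integers(len(pairs))]
        mid = next_id
        next_id += 1
        w = adj[u].pop(v)
        adj[v].pop(u)
        cut = float(rng.uniform(0.2, 0.8)) * w
        adj.setdefault(mid, {})
        adj[u][mid] = cut
        adj[mid][u] = cut
        adj[mid][v] = w - cut
        adj[v][mid] = w - cut
        wl = float(rng.uniform(0.1, 1.0))
        adj.setdefault(leaf, {})[mid] = wl
        adj[mid][leaf] = wl

    # all-pairs path lengths by BFS/DFS
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n_taxa):
            D[i, j] = dist[j]

    # bipartitions: removing each internal edge
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u >= n_taxa and v >= n_taxa:
                side = _component(adj, u, without=v)
                leaves = frozenset(labels[x] for x in side if x < n_taxa)
                if 1 < len(leaves) < n_taxa - 1:
                    splits.add(leaves)
    # canonicalize: store the smaller side
    canon = {_canonical_split(sp, labels) for sp in splits}
    return labels, D, canon


def _canonical_split(side: frozenset, labels) -> frozenset:
    """Deterministic representative: the side containing the first label."""
    full = frozenset(labels)
    anchor = sorted(labels)[0]
    return side if anchor in side else full - side


def _component(adj, start, without):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != without and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def newick_splits(newick: str, labels) -> set:
    """Non-trivial bipartitions of an unrooted newick tree (smaller side)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    full = frozenset(labels)
    out = set()
    for edge in tree.preorder_edge_iter():
        bp = edge.bipartition
        if bp is None:
            continue
        side = frozenset(
            t.label for t in tree.taxon_namespace
            if bp.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)
        )
        if 1 < len(side) < len(full) - 1:
            out.add(_canonical_split(side, labels))
    return out
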