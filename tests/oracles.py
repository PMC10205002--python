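"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes a different computational route from the code
it checks (edge enumeration instead of a preorder sweep, exhaustive scans
instead of vectorized windows, plain non-phylogenetic formulas for the
identity-covariance reductions).
"""

import numpy as np


def bm_cov_by_edge_enumeration(tree) -> np.ndarray:
    """C[i, j] = sum of branch lengths of edges shared by both root paths."""
    dtree = tree._dtree
    paths = {}
    for leaf in dtree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = dict(edges)
    n = len(tree.tips)
    C = np.zeros((n, n))
    for i, a in enumerate(tree.tips):
        for j, b in enumerate(tree.tips):
            shared = set(paths[a]) & set(paths[b])
            C[i, j] = sum(paths[a][e] for e in shared)
    return C


def peaks_bruteforce(p, window=3, rel_height=0.10):
    """Exhaustive O(n*w) peak scan with the same policy as detect_peaks."""
    p = np.asarray(p, float)
    n = p.size
    half = window // 2
    cand = []
    for i in range(1, n - 1):
        ok = True
        for j in range(max(0, i - half), min(n, i + half + 1)):
            if j != i and not (p[i] > p[j]):
                ok = False
                break
        if ok:
            cand.append(i)
    if not cand:
        return 0, []
    tallest = max(p[i] for i in cand)
    kept = [i for i in cand if p[i] >= rel_height * tallest]
    return len(kept), kept


def plain_two_block_pls(X1, X2):
    """Ordinary (non-phylogenetic) two-block PLS first-axis correlation."""
    X1c = X1 - X1.mean(axis=0)
    X2c = X2 - X2.mean(axis=0)
    R = X1c.T @ X2c / (X1.shape[0] - 1)
    U, _, Vt = np.linalg.svd(R, full_matrices=False)
    s1, s2 = X1c @ U[:, 0], X2c @ Vt[0]
    return abs(np.corrcoef(s1, s2)[0, 1])


def classical_partial_F(y, X, j):
    """Textbook partial F for dropping column j from an OLS fit with intercept."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    Dr = np.delete(D, j + 1, axis=1)

    def rss(D_):
        b, *_ = np.linalg.lstsq(D_, y, rcond=None)
        r = y - D_ @ b
        return float(r @ r)

    rss_full, rss_red = rss(D), rss(Dr)
    df_res = n - D.shape[1]
    return (rss_red - rss_full) / (rss_full / df_res)


def star_newick(labels, t=1.0):
    inner = ",".join(f"{l}:{t}" for l in labels)
    return f"({inner});"
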