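"""Independent brute-force oracles used by the test suite.

Everything here is deliberately simple and slow — fixed-step RK4 in plain
Python floats, direct tree traversals — and shares no code with the
package's numerical core, so agreement is evidence of correctness rather
than repetition.
"""

from __future__ import annotations

import math

from divergrass.phylo_core import TimeTree


def rk4_branch(y, params, duration, h=1e-4):
    """Fixed-step RK4 integration of the BiSSE branch system.

    ``y = (E0, E1, D0, D1)``; ``params`` a BisseParams; step ``h`` in My.
    """
    l0, l1, m0, m1, q01, q10 = (
        params.lambda0, params.lambda1, params.mu0, params.mu1,
        params.q01, params.q10,
    )

    def deriv(s):
        E0, E1, D0, D1 = s
        return (
            m0 - (l0 + m0 + q01) * E0 + q01 * E1 + l0 * E0 * E0,
            m1 - (l1 + m1 + q10) * E1 + q10 * E0 + l1 * E1 * E1,
            -(l0 + m0 + q01) * D0 + q01 * D1 + 2.0 * l0 * E0 * D0,
            -(l1 + m1 + q10) * D1 + q10 * D0 + 2.0 * l1 * E1 * D1,
        )

    n = max(int(math.ceil(duration / h)), 1)
    step = duration / n
    s = tuple(float(v) for v in y)
    for _ in range(n):
        k1 = deriv(s)
        k2 = deriv(tuple(s[i] + 0.5 * step * k1[i] for i in range(4)))
        k3 = deriv(tuple(s[i] + 0.5 * step * k2[i] for i in range(4)))
        k4 = deriv(tuple(s[i] + step * k3[i] for i in range(4)))
        s = tuple(
            s[i] + step / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
            for i in range(4)
        )
    return s


def rk4_tree_loglik(tree: TimeTree, states: dict, params, f=1.0, h=1e-4,
                    root_mode="weighted"):
    """Post-order BiSSE pruning with the fixed-step RK4 branch oracle."""
    vals = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            st = states[TimeTree._label(nd)]
            d0 = f if st in (0, None) else 0.0
            d1 = f if st in (1, None) else 0.0
            y = (1.0 - f, 1.0 - f, d0, d1)
        else:
            kids = nd.child_nodes()
            yl, yr = vals[id(kids[0])], vals[id(kids[1])]
            y = (
                0.5 * (yl[0] + yr[0]),
                0.5 * (yl[1] + yr[1]),
                params.lambda0 * yl[2] * yr[2],
                params.lambda1 * yl[3] * yr[3],
            )
        if nd.parent_node is not None and (nd.edge.length or 0.0) > 0:
            y = rk4_branch(y, params, nd.edge.length, h=h)
        vals[id(nd)] = y
    e0, e1, d0, d1 = vals[id(tree.root)]
    if root_mode == "weighted":
        tot = d0 + d1
        lik = (d0 * d0 + d1 * d1) / tot
    elif root_mode == "given0":
        lik = d0
    elif root_mode == "given1":
        lik = d1
    else:  # flat
        lik = 0.5 * (d0 + d1)
    return math.log(lik)


def clade_ages_by_path(tree: TimeTree, labels):
    """Crown/stem ages of the MRCA of ``labels`` by exhaustive path walking."""
    paths = []
    for lab in labels:
        nd = tree.find_tip(lab)
        path = []
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(list(reversed(path)))  # root first
    k = 0
    limit = min(len(p) for p in paths)
    while k < limit and all(p[k] is paths[0][k] for p in paths):
        k += 1
    mrca = paths[0][k - 1]
    stem = mrca.parent_node.age if mrca.parent_node is not None else None
    return mrca.age, stem


def ltt_by_counting(tree: TimeTree, age: float) -> int:
    """Number of lineages crossing a given age, counted edge by edge."""
    n = 0
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.age < age <= nd.parent_node.age:
            n += 1
    return n
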