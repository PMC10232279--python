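"""Exact interventional Shapley values for decision-tree ensembles.

For one tree and one background row z, the interventional set function
``v(S) = f(x restricted to S, z elsewhere)`` routes each split node by x when
the split feature is in the coalition S and by z otherwise.  A leaf l is
therefore reached iff a conjunction of literals holds: every feature in a set
P_l (where x and z route differently and x's side leads to l) must be in S,
and every feature in a set N_l must be out of S.  The Shapley value of such a
conjunction game has a closed form:

    phi_i = +w_l * (a-1)! b! / (a+b)!   for i in P_l   (a = |P_l|, b = |N_l|)
    phi_i = -w_l * a! (b-1)! / (a+b)!   for i in N_l

with all other features exact dummies.  Summing over leaves, background rows
and trees yields the exact Shapley values of the forest's probability output
under the interventional (background-marginalised) expectation -- the local
accuracy (efficiency) axiom holds to floating-point precision.

The traversal below visits only the subtree reachable under some mixture of x
and z, branching solely at nodes where x and z disagree, with constraint
de-duplication (a feature constrained by an ancestor routes all its deeper
splits consistently).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import gammaln

_MAX_DEPTH = 256          # distinct constrained features per path
_STACK = 8192


def shapley_coefficients(max_players: int = _MAX_DEPTH) -> tuple[np.ndarray, np.ndarray]:
    """Tables C_pos[a, b] = (a-1)! b! / (a+b)!  and  C_neg[a, b] = a! (b-1)! / (a+b)!."""
    a = np.arange(max_players)[:, None].astype(float)
    b = np.arange(max_players)[None, :].astype(float)
    with np.errstate(invalid="ignore"):
        cpos = np.exp(gammaln(a) + gammaln(b + 1.0) - gammaln(a + b + 1.0))
        cneg = np.exp(gammaln(a + 1.0) + gammaln(b) - gammaln(a + b + 1.0))
    cpos[0, :] = 0.0
    cneg[:, 0] = 0.0
    return cpos, cneg


@njit(cache=True)
def _forest_shap_kernel(cl, cr, ft, th, val, starts, X, Z, cpos, cneg):  # pragma: no cover
    n, p = X.shape
    m = Z.shape[0]
    T = starts.shape[0] - 1
    phi = np.zeros((n, p))
    state = np.zeros(p, np.int8)            # 0 free, 1 must-in-S, 2 must-out-S
    pos_list = np.empty(_MAX_DEPTH, np.int64)
    neg_list = np.empty(_MAX_DEPTH, np.int64)
    sk = np.empty(_STACK, np.int8)          # 0 visit, 1 undo
    sn = np.empty(_STACK, np.int64)         # node
    sc = np.empty(_STACK, np.int8)          # constraint type
    sf = np.empty(_STACK, np.int64)         # constrained feature
    w = 1.0 / (m * T)

    for i in range(n):
        for zi in range(m):
            for t in range(T):
                top = 0
                sk[top], sn[top], sc[top], sf[top] = 0, starts[t], 0, -1
                top += 1
                a = 0
                b = 0
                while top > 0:
                    top -= 1
                    kind = sk[top]
                    if kind == 1:           # undo a constraint
                        f = sf[top]
                        if sc[top] == 1:
                            a -= 1
                        else:
                            b -= 1
                        state[f] = 0
                        continue
                    nd = sn[top]
                    ctype = sc[top]
                    if ctype == 1:
                        f = sf[top]
                        s = state[f]
                        if s == 2:
                            continue        # contradiction: leaf unreachable
                        if s == 0:
                            state[f] = 1
                            pos_list[a] = f
                            a += 1
                            sk[top], sc[top], sf[top] = 1, 1, f   # schedule undo
                            top += 1
                    elif ctype == 2:
                        f = sf[top]
                        s = state[f]
                        if s == 1:
                            continue
                        if s == 0:
                            state[f] = 2
                            neg_list[b] = f
                            b += 1
                            sk[top], sc[top], sf[top] = 1, 2, f
                            top += 1
                    # walk down agreement chain; branch at disagreements
                    while True:
                        if cl[nd] < 0:      # leaf
                            if a > 0 or b > 0:
                                wv = val[nd] * w
                                c1 = cpos[a, b]
                                c2 = cneg[a, b]
                                for q in range(a):
                                    phi[i, pos_list[q]] += wv * c1
                                for q in range(b):
                                    phi[i, neg_list[q]] -= wv * c2
                            break
                        f = ft[nd]
                        xg = X[i, f] <= th[nd]
                        zg = Z[zi, f] <= th[nd]
                        s = state[f]
                        if s == 1:          # routed by x
                            nd = cl[nd] if xg else cr[nd]
                        elif s == 2:        # routed by z
                            nd = cl[nd] if zg else cr[nd]
                        elif xg == zg:
                            nd = cl[nd] if xg else cr[nd]
                        else:
                            xchild = cl[nd] if xg else cr[nd]
                            zchild = cl[nd] if zg else cr[nd]
                            sk[top], sn[top], sc[top], sf[top] = 0, zchild, 2, f
                            top += 1
                            sk[top], sn[top], sc[top], sf[top] = 0, xchild, 1, f
                            top += 1
                            break
    return phi


def flatten_forest(estimator, positive_index: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                              np.ndarray, np.ndarray]:
    """Concatenate an sklearn tree ensemble into flat node arrays.

    ``val[node]`` is the positive-class probability at the node (meaningful at
    leaves).  Works for DecisionTree*, RandomForest* and ExtraTrees*
    classifiers, whose ensemble probability is the mean over trees.
    """
    trees = getattr(estimator, "estimators_", [estimator])
    cls, crs, fts, ths, vals, starts = [], [], [], [], [], [0]
    for est in trees:
        t = est.tree_
        cls.append(t.children_left.astype(np.int64))
        crs.append(t.children_right.astype(np.int64))
        fts.append(t.feature.astype(np.int64))
        ths.append(t.threshold.astype(np.float64))
        v = t.value[:, 0, :].astype(np.float64)
        totals = v.sum(axis=1)
        totals[totals == 0.0] = 1.0
        vals.append(v[:, positive_index] / totals)
        starts.append(starts[-1] + t.node_count)
    offs = np.array(starts[:-1])
    cl = np.concatenate([c + o for c, o in zip(cls, offs)])
    cr = np.concatenate([c + o for c, o in zip(crs, offs)])
    # leaves are marked -1 in sklearn; keep them negative after offsetting
    is_leaf = np.concatenate([c < 0 for c in cls])
    cl[is_leaf] = -1
    cr[is_leaf] = -1
    return (cl, cr, np.concatenate(fts), np.concatenate(ths),
            np.concatenate(vals), np.array(starts, dtype=np.int64))


def forest_interventional_shap(estimator, X: np.ndarray, background: np.ndarray,
                               positive_index: int) -> np.ndarray:
    """Exact interventional Shapley values (n x p) of the ensemble probability."""
    cl, cr, ft, th, val, starts = flatten_forest(estimator, positive_index)
    cpos, cneg = shapley_coefficients()
    return _forest_shap_kernel(
        cl, cr, ft, th, val, starts,
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(background, dtype=np.float64),
        cpos, cneg)
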