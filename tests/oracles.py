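"""Independent reference implementations used only as test oracles.

These deliberately avoid the vectorized code paths of the package:
the forward simulator is a scalar python loop, the gradient oracle sums
explicitly over all unrolled paths of the computational graph (O(T^2)
matrix products instead of the O(T) recursion), and the triad counter
enumerates all node triples with permutation canonicalization.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def scalar_lif_forward(params, x):
    """Step-by-step scalar simulation of a LIF layer; returns (U, S)."""
    n_out, n_in = params.w_in.shape
    T = x.shape[1]
    U = np.zeros((n_out, T))
    S = np.zeros((n_out, T), dtype=bool)
    u = [0.0] * n_out
    s = [0] * n_out
    for t in range(T):
        u_new = []
        for i in range(n_out):
            acc = u[i] * params.tau[i] * (1 - s[i])
            for j in range(n_in):
                if x[j, t]:
                    acc += params.w_in[i, j]
            for k in range(n_out):
                if s[k]:
                    acc += params.w_rec[i, k]
            acc += params.bias[i]
            u_new.append(acc)
        s = [1 if u_new[i] >= params.u_th else 0 for i in range(n_out)]
        u = u_new
        for i in range(n_out):
            U[i, t] = u[i]
            S[i, t] = bool(s[i])
    return U, S


def _surrogate(x, alpha):
    return (alpha / math.sqrt(math.pi)) * np.exp(-(alpha**2) * x * x)


def unrolled_gradients(params, x, d_s, alpha=0.7, lambda_w=0.0):
    """Full-unroll chain-rule gradients for one layer (single sample).

    The potential gradient is accumulated as an explicit sum over all
    paths t -> t' through products of the one-step Jacobians

        A_t[k, i] = delta_ki * tau_k * (1 - s_k^t)      (leak, gated)
                  + w_rec[k, i] * g'(u_i^t - u_th)      (recurrent synapse)

    sharing the convention that the reset-gate edge s^{t-1} -> u^t is not
    differentiated.  Returns a dict of gradients.
    """
    U, S = scalar_lif_forward(params, x)
    n, T = U.shape
    gp = _surrogate(U - params.u_th, alpha)
    d_s = np.asarray(d_s, dtype=float)

    # one-step Jacobians du^{t+1}/du^t
    A = []
    for t in range(T - 1):
        At = np.zeros((n, n))
        for k in range(n):
            At[k, k] += params.tau[k] * (1.0 - S[k, t])
            for i in range(n):
                At[k, i] += params.w_rec[k, i] * gp[i, t]
        A.append(At)

    d_u = np.zeros((n, T))
    for t in range(T):
        d_u[:, t] = gp[:, t] * d_s[:, t]
        M = np.eye(n)
        for tp in range(t + 1, T):
            M = A[tp - 1] @ M  # du^{tp}/du^{t}
            d_u[:, t] += M.T @ (gp[:, tp] * d_s[:, tp])

    n_in = params.n_in
    d_x = np.zeros((n_in, T))
    for j in range(n_in):
        for t in range(T):
            d_x[j, t] = sum(d_u[i, t] * params.w_in[i, j] for i in range(n))
    d_w_in = np.zeros((n, n_in))
    for i in range(n):
        for j in range(n_in):
            d_w_in[i, j] = sum(d_u[i, t] * x[j, t] for t in range(T))
            d_w_in[i, j] += lambda_w * np.sign(params.w_in[i, j])
    d_w_rec = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            d_w_rec[i, k] = sum(
                d_u[i, t] * S[k, t - 1] for t in range(1, T)
            )
            d_w_rec[i, k] += lambda_w * np.sign(params.w_rec[i, k])
    d_bias = d_u.sum(axis=1)
    d_tau = np.zeros(n)
    for i in range(n):
        d_tau[i] = sum(
            d_u[i, t] * U[i, t - 1] * (1 - S[i, t - 1])
            for t in range(1, T)
        )
    return {
        "d_u": d_u,
        "d_x": d_x,
        "d_w_in": d_w_in,
        "d_w_rec": d_w_rec,
        "d_bias": d_bias,
        "d_tau": d_tau,
    }


def _canonical_triad_code(sub):
    """Smallest 6-bit edge code over all node permutations of a 3x3 block."""
    best = None
    for perm in itertools.permutations(range(3)):
        code = 0
        bit = 0
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                if sub[perm[a], perm[b]]:
                    code |= 1 << bit
                bit += 1
        best = code if best is None else min(best, code)
    return best


def _build_code_to_name():
    """Map canonical codes to triad names using 3-node graphs only."""
    import networkx as nx

    mapping = {}
    for code in range(64):
        adj = np.zeros((3, 3), dtype=bool)
        bit = 0
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                adj[a, b] = bool(code & (1 << bit))
                bit += 1
        G = nx.from_numpy_array(adj.astype(int), create_using=nx.DiGraph)
        census = nx.triadic_census(G)
        name = next(k for k, v in census.items() if v == 1)
        mapping[_canonical_triad_code(adj)] = name
    return mapping


_CODE_TO_NAME = None


def brute_force_triad_census(adjacency, classes):
    """Count connected induced triads by exhaustive triple enumeration."""
    global _CODE_TO_NAME
    if _CODE_TO_NAME is None:
        _CODE_TO_NAME = _build_code_to_name()
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    counts = dict.fromkeys(classes, 0)
    for trio in itertools.combinations(range(n), 3):
        sub = adj[np.ix_(trio, trio)]
        und = sub | sub.T
        # weak connectivity of 3 nodes: at least 2 undirected edges and
        # no isolated node
        deg = und.sum(axis=0)
        if (deg > 0).sum() < 3 or und.sum() // 2 < 2:
            continue
        name = _CODE_TO_NAME[_canonical_triad_code(sub)]
        if name in counts:
            counts[name] += 1
    return np.array([counts[c] for c in classes], dtype=np.int64)
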