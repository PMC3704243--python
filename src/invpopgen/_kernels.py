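"""Numba-compiled inner loops for the coalescent machinery.

Genealogies are stored as flat arrays: nodes ``0..n_tips-1`` are tips,
internal nodes are appended in coalescence order (so a parent index always
exceeds its children's indices, and the last node is the root), ``parent``
holds parent pointers (-1 at the root) and ``node_time`` coalescent-unit
times (units of 2N generations).

All randomness is pre-drawn by the callers as arrays of Exp(1) and U(0,1)
variates, which keeps the kernels deterministic functions of their inputs
and lets one seeded generator thread through every stage.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = [
    "simulate_topology",
    "label_tips",
    "class_counts",
    "descendant_mask",
    "two_species_tree",
]


@numba.njit(cache=True)
def simulate_topology(n, alpha, exp_draws, pair_draws, parent, node_time):
    """Fill ``parent``/``node_time`` with a Kingman coalescent genealogy.

    With ``alpha == 0`` waiting times while k lineages remain are
    exponential with rate k(k-1)/2.  With ``alpha > 0`` the population grew
    exponentially (size N0*exp(-alpha*t) backward in time) and waiting times
    use the deterministic time rescaling: the cumulative coalescence rate
    from time t0 to t is (k(k-1)/2) * (exp(alpha*t) - exp(alpha*t0)) / alpha.
    """
    m = 2 * n - 1
    for i in range(m):
        parent[i] = -1
        node_time[i] = 0.0
    active = np.empty(n, dtype=np.int64)
    for i in range(n):
        active[i] = i
    t = 0.0
    nxt = n
    step = 0
    for k in range(n, 1, -1):
        rate = k * (k - 1) / 2.0
        e = exp_draws[step]
        if alpha == 0.0:
            t = t + e / rate
        else:
            t = np.log(np.exp(alpha * t) + alpha * e / rate) / alpha
        i = int(pair_draws[2 * step] * k)
        if i >= k:
            i = k - 1
        j = int(pair_draws[2 * step + 1] * (k - 1))
        if j >= k - 1:
            j = k - 2
        if j >= i:
            j += 1
        a = active[i]
        b = active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        lo = i if i < j else j
        hi = j if i < j else i
        active[lo] = nxt
        active[hi] = active[k - 1]
        nxt += 1
        step += 1


@numba.njit(cache=True)
def label_tips(parent, n_tips, event_branch, event_time, labels):
    """Arrangement-class label per node from inversion events on branches.

    Event ``e`` (1-based class id) sits on the branch above ``event_branch[e-1]``
    at time ``event_time[e-1]``.  A node's class is the most recent (smallest
    time) event on its path to the root; nodes with no event on the path get
    the ancestral class 0.  Relies on parent index > child index.
    """
    m = len(parent)
    own_time = np.full(m, np.inf)
    own_label = np.zeros(m, dtype=np.int64)
    for e in range(len(event_branch)):
        b = event_branch[e]
        if event_time[e] < own_time[b]:
            own_time[b] = event_time[e]
            own_label[b] = e + 1
    labels[m - 1] = own_label[m - 1] if own_time[m - 1] < np.inf else 0
    for node in range(m - 2, -1, -1):
        if own_time[node] < np.inf:
            labels[node] = own_label[node]
        else:
            labels[node] = labels[parent[node]]


@numba.njit(cache=True)
def class_counts(parent, tip_class, n_tips, n_classes):
    """Per-node descendant counts by tip class, ``(n_nodes, n_classes)``.

    ``tip_class[t] = -1`` marks a tip excluded from the count (not sampled).
    """
    m = len(parent)
    counts = np.zeros((m, n_classes), dtype=np.int64)
    for t in range(n_tips):
        c = tip_class[t]
        if c >= 0:
            counts[t, c] = 1
    for node in range(m - 1):
        p = parent[node]
        for c in range(n_classes):
            counts[p, c] += counts[node, c]
    return counts


@numba.njit(cache=True)
def descendant_mask(parent, n_tips, branches):
    """Boolean matrix: row r marks the tips descending from ``branches[r]``."""
    m = len(parent)
    child1 = np.full(m, -1, dtype=np.int64)
    child2 = np.full(m, -1, dtype=np.int64)
    for node in range(m - 1):
        p = parent[node]
        if child1[p] < 0:
            child1[p] = node
        else:
            child2[p] = node
    out = np.zeros((len(branches), n_tips), dtype=np.bool_)
    stack = np.empty(m, dtype=np.int64)
    for r in range(len(branches)):
        top = 0
        stack[0] = branches[r]
        top = 1
        while top > 0:
            top -= 1
            node = stack[top]
            if node < n_tips:
                out[r, node] = True
            else:
                stack[top] = child1[node]
                top += 1
                stack[top] = child2[node]
                top += 1
    return out


@numba.njit(cache=True)
def two_species_tree(n, T, exp_draws, pair_draws, parent, node_time):
    """Coalescent for n ingroup lineages plus one outgroup lineage.

    The outgroup (tip index ``n``) belongs to a sister population that split
    ``T`` coalescent units ago from an ancestral population of the same size:
    ingroup lineages coalesce freely, the outgroup lineage enters the active
    set at time T (memorylessness permits redrawing the waiting time at the
    entry point), and coalescence then proceeds to the common root.  Arrays
    must have length 2n+1.  Returns the number of exponential draws used.
    """
    m = 2 * n + 1
    for i in range(m):
        parent[i] = -1
        node_time[i] = 0.0
    active = np.empty(n + 1, dtype=np.int64)
    for i in range(n):
        active[i] = i
    k = n
    out_added = False
    t = 0.0
    nxt = n + 1
    step = 0
    while k > 1 or not out_added:
        if not out_added and k == 1:
            t = T
            active[k] = n
            k += 1
            out_added = True
            continue
        rate = k * (k - 1) / 2.0
        e = exp_draws[step]
        step += 1
        t_next = t + e / rate
        if not out_added and t_next >= T:
            t = T
            active[k] = n
            k += 1
            out_added = True
            continue
        t = t_next
        i = int(pair_draws[2 * (step - 1)] * k)
        if i >= k:
            i = k - 1
        j = int(pair_draws[2 * (step - 1) + 1] * (k - 1))
        if j >= k - 1:
            j = k - 2
        if j >= i:
            j += 1
        a = active[i]
        b = active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        lo = i if i < j else j
        hi = j if i < j else i
        active[lo] = nxt
        active[hi] = active[k - 1]
        nxt += 1
        k -= 1
    return step
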