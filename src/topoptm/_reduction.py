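"""Numba kernels for Vietoris-Rips clique enumeration and boundary-matrix reduction.

The persistence pairing uses the standard column reduction over GF(2),
processed one simplex dimension at a time from the top dimension down so
that columns paired in dimension d+1 can be cleared before the dimension-d
reduction (the "twist" optimization).  Columns are kept as sorted int64
index arrays; addition is symmetric difference.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _count_triangles(nbr_flat, nbr_off, adj):
    n = nbr_off.shape[0] - 1
    count = 0
    for i in range(n):
        for a in range(nbr_off[i], nbr_off[i + 1]):
            j = nbr_flat[a]
            if j <= i:
                continue
            for b in range(a + 1, nbr_off[i + 1]):
                k = nbr_flat[b]
                if adj[j, k]:
                    count += 1
    return count


@njit(cache=True)
def _fill_triangles(nbr_flat, nbr_off, adj, out):
    n = nbr_off.shape[0] - 1
    c = 0
    for i in range(n):
        for a in range(nbr_off[i], nbr_off[i + 1]):
            j = nbr_flat[a]
            if j <= i:
                continue
            for b in range(a + 1, nbr_off[i + 1]):
                k = nbr_flat[b]
                if adj[j, k]:
                    out[c, 0] = i
                    out[c, 1] = j
                    out[c, 2] = k
                    c += 1


@njit(cache=True)
def _count_tets(tris, nbr_flat, nbr_off, adj):
    count = 0
    for t in range(tris.shape[0]):
        i, j, k = tris[t, 0], tris[t, 1], tris[t, 2]
        for a in range(nbr_off[k], nbr_off[k + 1]):
            m = nbr_flat[a]
            if m > k and adj[i, m] and adj[j, m]:
                count += 1
    return count


@njit(cache=True)
def _fill_tets(tris, nbr_flat, nbr_off, adj, out):
    c = 0
    for t in range(tris.shape[0]):
        i, j, k = tris[t, 0], tris[t, 1], tris[t, 2]
        for a in range(nbr_off[k], nbr_off[k + 1]):
            m = nbr_flat[a]
            if m > k and adj[i, m] and adj[j, m]:
                out[c, 0] = i
                out[c, 1] = j
                out[c, 2] = k
                out[c, 3] = m
                c += 1


@njit(cache=True)
def _reduce_csr(col_flat, col_off, cleared, n_rows):
    """Reduce boundary columns (CSR layout) in the given filtration order.

    col_flat/col_off : concatenated row indices per column, each column's
        entries sorted ascending; row indices refer to the facet
        dimension's filtration order.
    cleared : (m,) bool — columns already known to reduce to zero.
    Returns (m,) int64 — pivot row per column, -1 for zero columns.

    Claimed (reduced, nonzero) columns are kept in a flat append-only
    buffer; the working column lives in reusable scratch arrays to keep
    the inner loop allocation-free.
    """
    m = col_off.shape[0] - 1
    pivot_of = np.full(m, -1, np.int64)
    owner_start = np.full(n_rows, -1, np.int64)
    owner_len = np.zeros(n_rows, np.int64)
    store = np.empty(max(16, col_flat.shape[0]), np.int64)
    store_used = 0
    cur = np.empty(1024, np.int64)
    tmp = np.empty(1024, np.int64)
    for j in range(m):
        if cleared[j]:
            continue
        ln = col_off[j + 1] - col_off[j]
        if cur.shape[0] < ln:
            cur = np.empty(2 * ln, np.int64)
        cur[:ln] = col_flat[col_off[j]:col_off[j + 1]]
        while ln > 0:
            p = cur[ln - 1]
            s = owner_start[p]
            if s == -1:
                if store_used + ln > store.shape[0]:
                    grown = np.empty(
                        max(2 * store.shape[0], store_used + ln), np.int64
                    )
                    grown[:store_used] = store[:store_used]
                    store = grown
                store[store_used:store_used + ln] = cur[:ln]
                owner_start[p] = store_used
                owner_len[p] = ln
                store_used += ln
                pivot_of[j] = p
                break
            ol = owner_len[p]
            if tmp.shape[0] < ln + ol:
                tmp = np.empty(2 * (ln + ol), np.int64)
            ia = ib = io = 0
            while ia < ln and ib < ol:
                av = cur[ia]
                bv = store[s + ib]
                if av < bv:
                    tmp[io] = av
                    ia += 1
                    io += 1
                elif av > bv:
                    tmp[io] = bv
                    ib += 1
                    io += 1
                else:
                    ia += 1
                    ib += 1
            while ia < ln:
                tmp[io] = cur[ia]
                ia += 1
                io += 1
            while ib < ol:
                tmp[io] = store[s + ib]
                ib += 1
                io += 1
            hold = cur
            cur = tmp
            tmp = hold
            ln = io
    return pivot_of


@njit(cache=True)
def _kruskal(edge_ends, n):
    """Union-find pass over edges already in filtration order.

    Returns (is_tree_edge bool array, number of final components).
    """
    parent = np.arange(n)
    is_tree = np.zeros(edge_ends.shape[0], np.bool_)
    comps = n
    for e in range(edge_ends.shape[0]):
        a, b = edge_ends[e, 0], edge_ends[e, 1]
        ra = a
        while parent[ra] != ra:
            ra = parent[ra]
        rb = b
        while parent[rb] != rb:
            rb = parent[rb]
        # path compression
        while parent[a] != ra:
            a, parent[a] = parent[a], ra
        while parent[b] != rb:
            b, parent[b] = parent[b], rb
        if ra != rb:
            parent[rb] = ra
            is_tree[e] = True
            comps -= 1
    return is_tree, comps
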