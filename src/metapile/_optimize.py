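"""Numba kernel for two-sided stability hill climbing.

The objective (see :mod:`metapile.partition`) decomposes, up to the 1/(2|V|)
normalization, into

    sum over nodes and sides of  h(v, side)  -  2 * sum_m s_m * log(s_m/V)

where for a node with internal weight ``win`` out of total ``wtot`` on one
side, ``h = log(win/wtot)`` when ``win > 0`` and a flat floor constant when
``win == 0`` (no internal edge on that side).  Tracking, per metacell, the
member count ``s_m`` and the number of floored sides ``nfloor[m]`` makes the
score change of moving one node computable from the node's incident edges
alone, in O(degree) per candidate metacell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-10


@njit(cache=True, inline="always")
def _L(s, V):
    # log(s / V), with the s = 0 convention 0 (empty metacells contribute nothing)
    if s <= 0:
        return 0.0
    return np.log(s / V)


@njit(cache=True)
def _sweep(
    indptr_out, idx_out, w_out,
    indptr_in, idx_in, w_in,
    mc, sizes, nfloor,
    win_out, win_in, wtot_out, wtot_in,
    lam, lam_node, floor, order, moved,
):
    """One optimization sweep; mutates the state in place, returns move count.

    ``moved`` is a boolean scratch array; entries of nodes that changed
    metacell are set True (it is the caller's job to clear it).
    """
    V = float(mc.shape[0])
    inv2V = 1.0 / (2.0 * V)
    moves = 0
    max_deg = 0
    for v in range(mc.shape[0]):
        deg = (indptr_out[v + 1] - indptr_out[v]) + (indptr_in[v + 1] - indptr_in[v])
        if deg > max_deg:
            max_deg = deg
    cand = np.empty(max_deg, dtype=np.int64)
    cand_wout = np.empty(max_deg, dtype=np.float64)
    cand_win = np.empty(max_deg, dtype=np.float64)

    for oi in range(order.shape[0]):
        v = order[oi]
        a = mc[v]
        ncand = 0
        # gather candidate metacells and v's would-be internal weights
        for e in range(indptr_out[v], indptr_out[v + 1]):
            b = mc[idx_out[e]]
            if b == a or b < 0:
                continue
            slot = -1
            for c in range(ncand):
                if cand[c] == b:
                    slot = c
                    break
            if slot < 0:
                slot = ncand
                cand[slot] = b
                cand_wout[slot] = 0.0
                cand_win[slot] = 0.0
                ncand += 1
            cand_wout[slot] += w_out[e]
        for e in range(indptr_in[v], indptr_in[v + 1]):
            b = mc[idx_in[e]]
            if b == a or b < 0:
                continue
            slot = -1
            for c in range(ncand):
                if cand[c] == b:
                    slot = c
                    break
            if slot < 0:
                slot = ncand
                cand[slot] = b
                cand_wout[slot] = 0.0
                cand_win[slot] = 0.0
                ncand += 1
            cand_win[slot] += w_in[e]
        if ncand == 0:
            continue

        s_a = sizes[a]
        fo_old = win_out[v] <= 0.0 or wtot_out[v] <= 0.0
        fi_old = win_in[v] <= 0.0 or wtot_in[v] <= 0.0
        old_out = floor if fo_old else np.log(win_out[v] / wtot_out[v])
        old_in = floor if fi_old else np.log(win_in[v] / wtot_in[v])
        stab_old = (floor if fo_old else old_out - _L(s_a, V)) + \
                   (floor if fi_old else old_in - _L(s_a, V))

        best_c = -1
        best_delta = _EPS
        for c in range(ncand):
            b = cand[c]
            s_b = sizes[b]
            dnf_a = 0
            dnf_b = 0
            d_sides = 0.0

            # v's own sides
            if fo_old:
                dnf_a -= 1
            nwo = cand_wout[c]
            fo_new = nwo <= 0.0 or wtot_out[v] <= 0.0
            new_out = floor if fo_new else np.log(nwo / wtot_out[v])
            if fo_new:
                dnf_b += 1
            d_sides += new_out - old_out

            if fi_old:
                dnf_a -= 1
            nwi = cand_win[c]
            fi_new = nwi <= 0.0 or wtot_in[v] <= 0.0
            new_in = floor if fi_new else np.log(nwi / wtot_in[v])
            if fi_new:
                dnf_b += 1
            d_sides += new_in - old_in

            # neighbors in a lose the edge to v; neighbors in b gain it
            for e in range(indptr_out[v], indptr_out[v + 1]):
                t = idx_out[e]
                mt = mc[t]
                w = w_out[e]
                if mt == a:
                    neww = win_in[t] - w
                    if neww <= _EPS:
                        d_sides += floor - np.log(win_in[t] / wtot_in[t])
                        dnf_a += 1
                    else:
                        d_sides += np.log(neww / win_in[t])
                elif mt == b:
                    if win_in[t] <= 0.0:
                        d_sides += np.log(w / wtot_in[t]) - floor
                        dnf_b -= 1
                    else:
                        d_sides += np.log((win_in[t] + w) / win_in[t])
            for e in range(indptr_in[v], indptr_in[v + 1]):
                s = idx_in[e]
                ms = mc[s]
                w = w_in[e]
                if ms == a:
                    neww = win_out[s] - w
                    if neww <= _EPS:
                        d_sides += floor - np.log(win_out[s] / wtot_out[s])
                        dnf_a += 1
                    else:
                        d_sides += np.log(neww / win_out[s])
                elif ms == b:
                    if win_out[s] <= 0.0:
                        d_sides += np.log(w / wtot_out[s]) - floor
                        dnf_b -= 1
                    else:
                        d_sides += np.log((win_out[s] + w) / win_out[s])

            # size-dependent aggregate terms
            nfa, nfb = nfloor[a], nfloor[b]
            d_agg = (
                (nfa + dnf_a) * _L(s_a - 1, V) + (nfb + dnf_b) * _L(s_b + 1, V)
                - 2.0 * ((s_a - 1) * _L(s_a - 1, V) + (s_b + 1) * _L(s_b + 1, V))
            ) - (
                nfa * _L(s_a, V) + nfb * _L(s_b, V)
                - 2.0 * (s_a * _L(s_a, V) + s_b * _L(s_b, V))
            )

            delta = (d_sides + d_agg) * inv2V
            if lam > 0.0 and lam_node[v] > 0.0:
                stab_new = (floor if fo_new else new_out - _L(s_b + 1, V)) + \
                           (floor if fi_new else new_in - _L(s_b + 1, V))
                delta += lam * lam_node[v] * (stab_new - stab_old)
            if delta > best_delta:
                best_delta = delta
                best_c = c

        if best_c < 0:
            continue

        # apply the move v: a -> b
        b = cand[best_c]
        for e in range(indptr_out[v], indptr_out[v + 1]):
            t = idx_out[e]
            mt = mc[t]
            w = w_out[e]
            if mt == a:
                neww = win_in[t] - w
                if neww <= _EPS:
                    neww = 0.0
                    nfloor[a] += 1
                win_in[t] = neww
            elif mt == b:
                if win_in[t] <= 0.0:
                    nfloor[b] -= 1
                win_in[t] += w
        for e in range(indptr_in[v], indptr_in[v + 1]):
            s = idx_in[e]
            ms = mc[s]
            w = w_in[e]
            if ms == a:
                neww = win_out[s] - w
                if neww <= _EPS:
                    neww = 0.0
                    nfloor[a] += 1
                win_out[s] = neww
            elif ms == b:
                if win_out[s] <= 0.0:
                    nfloor[b] -= 1
                win_out[s] += w
        if fo_old:
            nfloor[a] -= 1
        if fi_old:
            nfloor[a] -= 1
        win_out[v] = cand_wout[best_c]
        win_in[v] = cand_win[best_c]
        if win_out[v] <= 0.0 or wtot_out[v] <= 0.0:
            nfloor[b] += 1
        if win_in[v] <= 0.0 or wtot_in[v] <= 0.0:
            nfloor[b] += 1
        sizes[a] -= 1
        sizes[b] += 1
        mc[v] = b
        moved[v] = True
        moves += 1
    return moves
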