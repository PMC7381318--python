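"""Numba kernels for the subset local search.

One kernel per objective family; all follow the same seeded
random-descent protocol (uniform initial k-subset per restart, uniform
single-swap proposals, accept strictly improving) so results are
bit-reproducible for a given seed.  Scores are maximized internally;
A-NE is negated by its kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STAT_SD = 0
STAT_EH = 1
STAT_AC = 2


@njit(cache=True)
def _ene_refresh(V, sel, d1, d2, ncol):
    k = sel.size
    for i in range(k):
        b1 = np.inf
        b2 = np.inf
        a1 = -1
        for j in range(k):
            if j == i:
                continue
            d = V[sel[i], sel[j]]
            if d < b1:
                b2 = b1
                b1 = d
                a1 = j
            elif d < b2:
                b2 = d
        d1[i] = b1
        d2[i] = b2
        ncol[i] = a1


@njit(cache=True)
def ene_search(V, k, seed, max_evals, patience, restarts):
    np.random.seed(seed)
    n = V.shape[0]
    best_sel = np.empty(k, np.int64)
    best_score = -np.inf
    evals = 0
    d1 = np.empty(k)
    d2 = np.empty(k)
    ncol = np.empty(k, np.int64)
    for _ in range(restarts):
        if evals >= max_evals:
            break
        perm = np.random.permutation(n)
        sel = perm[:k].copy()
        unsel = perm[k:].copy()
        _ene_refresh(V, sel, d1, d2, ncol)
        score = d1.sum() / k
        evals += 1
        stale = 0
        while evals < max_evals and stale < patience and unsel.size > 0:
            pos = np.random.randint(0, k)
            upos = np.random.randint(0, n - k)
            cand_idx = unsel[upos]
            total = 0.0
            rmin = np.inf
            for i in range(k):
                ri = V[sel[i], cand_idx]
                if i == pos:
                    continue
                if ri < rmin:
                    rmin = ri
                base = d2[i] if ncol[i] == pos else d1[i]
                total += ri if ri < base else base
            cand = (total + rmin) / k
            evals += 1
            if cand > score:
                old = sel[pos]
                sel[pos] = cand_idx
                unsel[upos] = old
                _ene_refresh(V, sel, d1, d2, ncol)
                score = cand
                stale = 0
            else:
                stale += 1
        if score > best_score:
            best_score = score
            best_sel[:] = sel
    return best_sel, best_score


@njit(cache=True)
def _ane_refresh(V, sel, d1, d2, near):
    n = V.shape[0]
    k = sel.size
    for i in range(n):
        b1 = np.inf
        b2 = np.inf
        a1 = -1
        for j in range(k):
            d = V[i, sel[j]]
            if d < b1:
                b2 = b1
                b1 = d
                a1 = sel[j]
            elif d < b2:
                b2 = d
        d1[i] = b1
        d2[i] = b2
        near[i] = a1


@njit(cache=True)
def ane_search(V, k, seed, max_evals, patience, restarts):
    np.random.seed(seed)
    n = V.shape[0]
    best_sel = np.empty(k, np.int64)
    best_score = -np.inf
    evals = 0
    d1 = np.empty(n)
    d2 = np.empty(n)
    near = np.empty(n, np.int64)
    for _ in range(restarts):
        if evals >= max_evals:
            break
        perm = np.random.permutation(n)
        sel = perm[:k].copy()
        unsel = perm[k:].copy()
        _ane_refresh(V, sel, d1, d2, near)
        score = -d1.sum() / n
        evals += 1
        stale = 0
        while evals < max_evals and stale < patience and unsel.size > 0:
            pos = np.random.randint(0, k)
            upos = np.random.randint(0, n - k)
            cand_idx = unsel[upos]
            out = sel[pos]
            total = 0.0
            for i in range(n):
                base = d2[i] if near[i] == out else d1[i]
                ri = V[i, cand_idx]
                total += ri if ri < base else base
            cand = -total / n
            evals += 1
            if cand > score:
                sel[pos] = cand_idx
                unsel[upos] = out
                _ane_refresh(V, sel, d1, d2, near)
                score = cand
                stale = 0
            else:
                stale += 1
        if score > best_score:
            best_score = score
            best_sel[:] = sel
    return best_sel, best_score


@njit(cache=True)
def _pooled_stat(counts, k, m, stat, full_ref, full_alt, denom):
    """Statistic from per-locus reference-allele counts (of 2k alleles)."""
    if stat == STAT_SD:
        total = 2.0 * k * m
        s = 0.0
        for l in range(m):
            c = counts[l]
            a = 2 * k - c
            if c > 0:
                s += c * np.log(c)
            if a > 0:
                s += a * np.log(a)
        return np.log(total) - s / total
    elif stat == STAT_EH:
        s = 0.0
        inv = 1.0 / (2.0 * k)
        for l in range(m):
            p = counts[l] * inv
            s += 1.0 - p * p - (1.0 - p) * (1.0 - p)
        return s / m
    else:  # allele coverage
        hit = 0
        for l in range(m):
            if full_ref[l] and counts[l] > 0:
                hit += 1
            if full_alt[l] and counts[l] < 2 * k:
                hit += 1
        return hit / denom


@njit(cache=True)
def pooled_search(X2, k, stat, full_ref, full_alt, denom, seed, max_evals, patience, restarts):
    """Search for SD / EH / AC; `X2` holds dosages doubled (0/1/2 ints)."""
    np.random.seed(seed)
    n, m = X2.shape
    best_sel = np.empty(k, np.int64)
    best_score = -np.inf
    evals = 0
    counts = np.empty(m, np.int64)
    cand_counts = np.empty(m, np.int64)
    for _ in range(restarts):
        if evals >= max_evals:
            break
        perm = np.random.permutation(n)
        sel = perm[:k].copy()
        unsel = perm[k:].copy()
        counts[:] = 0
        for i in range(k):
            counts += X2[sel[i]]
        score = _pooled_stat(counts, k, m, stat, full_ref, full_alt, denom)
        evals += 1
        stale = 0
        while evals < max_evals and stale < patience and unsel.size > 0:
            pos = np.random.randint(0, k)
            upos = np.random.randint(0, n - k)
            cand_idx = unsel[upos]
            out = sel[pos]
            for l in range(m):
                cand_counts[l] = counts[l] + X2[cand_idx, l] - X2[out, l]
            cand = _pooled_stat(cand_counts, k, m, stat, full_ref, full_alt, denom)
            evals += 1
            if cand > score:
                counts[:] = cand_counts
                sel[pos] = cand_idx
                unsel[upos] = out
                score = cand
                stale = 0
            else:
                stale += 1
        if score > best_score:
            best_score = score
            best_sel[:] = sel
    return best_sel, best_score
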