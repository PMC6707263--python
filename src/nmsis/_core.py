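"""Compiled event loop for the exact non-Markovian SIS simulation.

One realization is a sequence of absolute-time events drawn from a binary
min-heap: node recoveries and directed-edge transmissions.  Waiting times are
sampled by survival inversion from closed forms.  Heap entries are
invalidated lazily: every (re)schedule or cancellation bumps a per-entity
version counter, and stale entries are discarded on pop.

Edge-activation mechanisms (directed edge e runs src -> dst):

* type-I  — e is active iff src is infected AND dst is susceptible; a
  transmission consumes the edge; any state change of either endpoint that
  re-establishes the predicate re-arms the clock from age zero.
* type-II — e is active iff src is infected, regardless of dst; a
  transmission re-arms the same edge from age zero; dst-side changes never
  touch the clock (this absence of susceptible-side resets is what makes the
  mechanism exactly reducible to a Markovian process in the steady state).

Tie-breaking for equal event times is lexicographic on
(time, kind with recovery < transmission, entity id) for reproducibility.
"""

import numpy as np
from numba import njit

MECH_TYPE1 = 1
MECH_TYPE2 = 2

KIND_RECOVERY = 0
KIND_TRANSMISSION = 1

# family codes must match distributions.py
_FAM_WEIBULL = 0
_FAM_BETA_SIGMA1 = 1
_FAM_EXPONENTIAL = 2


@njit(cache=True, inline="always")
def _sample_time(fam, p1, p2):
    """Survival-inversion sample using the numba-local RandomState."""
    u = 1.0 - np.random.random()  # uniform on (0, 1]
    if fam == _FAM_WEIBULL:
        return p2 * np.log(1.0 / u) ** (1.0 / p1)
    elif fam == _FAM_BETA_SIGMA1:
        return 1.0 - u ** (1.0 / p1)
    else:  # exponential
        return np.log(1.0 / u) / p1


@njit(cache=True, inline="always")
def _heap_less(ht, hk, hi, a, b):
    if ht[a] != ht[b]:
        return ht[a] < ht[b]
    if hk[a] != hk[b]:
        return hk[a] < hk[b]
    return hi[a] < hi[b]


@njit(cache=True)
def _ensure_capacity(heap, n_items, needed):
    """Return a heap tuple with room for `needed` more entries (amortized)."""
    ht, hk, hi, hv = heap
    cap = ht.shape[0]
    if n_items + needed <= cap:
        return heap
    new_cap = max(2 * cap, n_items + needed)
    nht = np.empty(new_cap)
    nhk = np.empty(new_cap, dtype=np.int8)
    nhi = np.empty(new_cap, dtype=np.int64)
    nhv = np.empty(new_cap, dtype=np.int64)
    nht[:n_items] = ht[:n_items]
    nhk[:n_items] = hk[:n_items]
    nhi[:n_items] = hi[:n_items]
    nhv[:n_items] = hv[:n_items]
    return (nht, nhk, nhi, nhv)


@njit(cache=True)
def _heap_push(heap, n_items, t, kind, idx, ver):
    ht, hk, hi, hv = heap
    pos = n_items
    ht[pos] = t
    hk[pos] = kind
    hi[pos] = idx
    hv[pos] = ver
    while pos > 0:
        parent = (pos - 1) >> 1
        if _heap_less(ht, hk, hi, pos, parent):
            ht[pos], ht[parent] = ht[parent], ht[pos]
            hk[pos], hk[parent] = hk[parent], hk[pos]
            hi[pos], hi[parent] = hi[parent], hi[pos]
            hv[pos], hv[parent] = hv[parent], hv[pos]
            pos = parent
        else:
            break
    return n_items + 1


@njit(cache=True)
def _heap_pop(heap, n_items):
    ht, hk, hi, hv = heap
    t, kind, idx, ver = ht[0], hk[0], hi[0], hv[0]
    n_items -= 1
    if n_items > 0:
        ht[0], hk[0], hi[0], hv[0] = ht[n_items], hk[n_items], hi[n_items], hv[n_items]
        pos = 0
        while True:
            left = 2 * pos + 1
            right = left + 1
            smallest = pos
            if left < n_items and _heap_less(ht, hk, hi, left, smallest):
                smallest = left
            if right < n_items and _heap_less(ht, hk, hi, right, smallest):
                smallest = right
            if smallest == pos:
                break
            ht[pos], ht[smallest] = ht[smallest], ht[pos]
            hk[pos], hk[smallest] = hk[smallest], hk[pos]
            hi[pos], hi[smallest] = hi[smallest], hi[pos]
            hv[pos], hv[smallest] = hv[smallest], hv[pos]
            pos = smallest
    return n_items, t, kind, idx, ver


@njit(cache=True)
def _audit(mechanism, status, node_time, edge_time, src, dst):
    """Active-edge predicate and node clocks must match the state exactly."""
    n = status.shape[0]
    for i in range(n):
        finite = np.isfinite(node_time[i])
        if finite != (status[i] == 1):
            return False
    for e in range(src.shape[0]):
        if mechanism == MECH_TYPE1:
            should = status[src[e]] == 1 and status[dst[e]] == 0
        else:
            should = status[src[e]] == 1
        if np.isfinite(edge_time[e]) != should:
            return False
    return True


@njit(cache=True)
def run_realization(indptr, dst, src, pair, seeds, mechanism,
                    inf_fam, inf_p1, inf_p2, rec_fam, rec_p1, rec_p2,
                    t_max, sample_times, rng_seed, audit_every):
    """Simulate one SIS realization; return the sampled infected counts.

    Returns (counts, extinct_time, n_transmissions, n_recoveries, ok) where
    counts[k] is the number of infected nodes at sample_times[k] (step
    interpolation of the jump process), extinct_time is the absolute time the
    last infected node recovered (nan if still endemic at t_max), and ok
    flags the periodic state/heap consistency audit.
    """
    np.random.seed(rng_seed)
    n = indptr.shape[0] - 1
    n_dir = dst.shape[0]

    status = np.zeros(n, dtype=np.int8)
    node_time = np.full(n, np.inf)
    node_ver = np.zeros(n, dtype=np.int64)
    edge_time = np.full(n_dir, np.inf)
    edge_ver = np.zeros(n_dir, dtype=np.int64)

    max_deg = 0
    for i in range(n):
        deg = indptr[i + 1] - indptr[i]
        if deg > max_deg:
            max_deg = deg

    cap = 4 * (n + n_dir) + 64
    ht = np.empty(cap)
    hk = np.empty(cap, dtype=np.int8)
    hi = np.empty(cap, dtype=np.int64)
    hv = np.empty(cap, dtype=np.int64)
    heap = (ht, hk, hi, hv)
    n_items = 0

    n_inf = 0
    for s in seeds:
        status[s] = 1
        n_inf += 1
    # seed recovery clocks (infection age zero) and initial active edges
    for s in seeds:
        tau = _sample_time(rec_fam, rec_p1, rec_p2)
        node_time[s] = tau
        node_ver[s] += 1
        n_items = _heap_push(heap, n_items, tau, KIND_RECOVERY, s, node_ver[s])
        for e in range(indptr[s], indptr[s + 1]):
            if mechanism == MECH_TYPE2 or status[dst[e]] == 0:
                kappa = _sample_time(inf_fam, inf_p1, inf_p2)
                edge_time[e] = kappa
                edge_ver[e] += 1
                n_items = _heap_push(heap, n_items, kappa, KIND_TRANSMISSION,
                                     e, edge_ver[e])

    n_samples = sample_times.shape[0]
    counts = np.zeros(n_samples, dtype=np.int64)
    sp = 0
    t = 0.0
    extinct_time = np.nan
    n_trans = 0
    n_rec = 0
    n_events = 0
    ok = True

    while n_items > 0:
        heap = _ensure_capacity(heap, n_items, 2 * max_deg + 2)
        n_items, et, kind, idx, ver = _heap_pop(heap, n_items)
        # drop stale entries
        if kind == KIND_RECOVERY:
            if ver != node_ver[idx] or not np.isfinite(node_time[idx]):
                continue
        else:
            if ver != edge_ver[idx] or not np.isfinite(edge_time[idx]):
                continue
        if et > t_max:
            t = t_max
            break
        # flush sample times strictly before this event
        while sp < n_samples and sample_times[sp] < et:
            counts[sp] = n_inf
            sp += 1
        t = et

        if kind == KIND_RECOVERY:
            j = idx
            n_rec += 1
            status[j] = 0
            node_time[j] = np.inf
            node_ver[j] += 1
            n_inf -= 1
            for e in range(indptr[j], indptr[j + 1]):
                # out-edges of j lose their infected source under both rules
                if np.isfinite(edge_time[e]):
                    edge_time[e] = np.inf
                    edge_ver[e] += 1
                if mechanism == MECH_TYPE1:
                    # reverse edge j <- neighbor: j just became susceptible,
                    # so an infected neighbor activates it from age zero
                    re = pair[e]
                    if status[dst[e]] == 1:
                        kappa = _sample_time(inf_fam, inf_p1, inf_p2)
                        edge_time[re] = t + kappa
                        edge_ver[re] += 1
                        n_items = _heap_push(heap, n_items, edge_time[re],
                                             KIND_TRANSMISSION, re, edge_ver[re])
            if n_inf == 0:
                extinct_time = t
        else:
            e = idx
            d = dst[e]
            n_trans += 1
            if mechanism == MECH_TYPE2:
                # the used edge re-arms from age zero (source still infected)
                kappa = _sample_time(inf_fam, inf_p1, inf_p2)
                edge_time[e] = t + kappa
                edge_ver[e] += 1
                n_items = _heap_push(heap, n_items, edge_time[e],
                                     KIND_TRANSMISSION, e, edge_ver[e])
            else:
                edge_time[e] = np.inf
                edge_ver[e] += 1
            if status[d] == 0:
                # infect d with infection age zero
                status[d] = 1
                n_inf += 1
                tau = _sample_time(rec_fam, rec_p1, rec_p2)
                node_time[d] = t + tau
                node_ver[d] += 1
                n_items = _heap_push(heap, n_items, node_time[d],
                                     KIND_RECOVERY, d, node_ver[d])
                for f in range(indptr[d], indptr[d + 1]):
                    k = dst[f]
                    if mechanism == MECH_TYPE2 or status[k] == 0:
                        # d's out-edges activate from age zero
                        kappa = _sample_time(inf_fam, inf_p1, inf_p2)
                        edge_time[f] = t + kappa
                        edge_ver[f] += 1
                        n_items = _heap_push(heap, n_items, edge_time[f],
                                             KIND_TRANSMISSION, f, edge_ver[f])
                    if mechanism == MECH_TYPE1:
                        # incoming edges lose their susceptible target
                        rf = pair[f]
                        if np.isfinite(edge_time[rf]):
                            edge_time[rf] = np.inf
                            edge_ver[rf] += 1

        n_events += 1
        if audit_every > 0 and n_events % audit_every == 0:
            if not _audit(mechanism, status, node_time, edge_time, src, dst):
                ok = False
                break

    # remaining sample times see the final state
    while sp < n_samples:
        counts[sp] = n_inf
        sp += 1
    return counts, extinct_time, n_trans, n_rec, ok
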