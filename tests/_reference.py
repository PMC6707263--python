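"""Independent pure-Python event-driven SIS simulator used as a test oracle.

Re-derived directly from the mechanism definitions with plain heapq and
dicts; shares no code with the compiled production core.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def run_reference(n, edges, mechanism, inf_dist, rec_dist, seed_nodes,
                  t_max, sample_times, rng):
    """Return infected counts at sample_times for one realization."""
    nbrs = {i: [] for i in range(n)}
    for u, v in edges:
        nbrs[int(u)].append(int(v))
        nbrs[int(v)].append(int(u))

    infected = set(int(s) for s in seed_nodes)
    rec_time = {}
    edge_time = {}   # directed (src, dst) -> scheduled absolute time
    heap = []

    def draw(dist):
        return float(dist.ppf_survival(1.0 - rng.random()))

    def schedule_node(j, t):
        rec_time[j] = t + draw(rec_dist)
        heapq.heappush(heap, (rec_time[j], 0, j))

    def arm(src, dst, t):
        edge_time[(src, dst)] = t + draw(inf_dist)
        heapq.heappush(heap, (edge_time[(src, dst)], 1, (src, dst)))

    def disarm(src, dst):
        edge_time.pop((src, dst), None)

    for j in infected:
        schedule_node(j, 0.0)
    for j in infected:
        for i in nbrs[j]:
            if mechanism == "type2" or i not in infected:
                arm(j, i, 0.0)

    counts = []
    sp = 0
    t = 0.0
    while heap:
        et, kind, payload = heapq.heappop(heap)
        if kind == 0:
            j = payload
            if rec_time.get(j) != et:
                continue
        else:
            if edge_time.get(payload) != et:
                continue
        if et > t_max:
            break
        while sp < len(sample_times) and sample_times[sp] < et:
            counts.append(len(infected))
            sp += 1
        t = et
        if kind == 0:
            j = payload
            infected.discard(j)
            rec_time.pop(j, None)
            for i in nbrs[j]:
                disarm(j, i)
                if mechanism == "type1" and i in infected:
                    arm(i, j, t)
        else:
            src, dst = payload
            if mechanism == "type2":
                arm(src, dst, t)
            else:
                disarm(src, dst)
            if dst not in infected:
                infected.add(dst)
                schedule_node(dst, t)
                for k in nbrs[dst]:
                    if mechanism == "type2" or k not in infected:
                        arm(dst, k, t)
                    if mechanism == "type1":
                        disarm(k, dst)
    while sp < len(sample_times):
        counts.append(len(infected))
        sp += 1
    return np.array(counts)
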