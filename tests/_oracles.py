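"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit set arithmetic, BFS by
hand, exhaustive enumeration. No herbnet internals are imported.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def tanimoto_sets(a: set[int], b: set[int]) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def pearson_sums(x, y) -> float:
    """Pearson r via the raw Σ formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def bfs_distances(edges: set[frozenset], source: str) -> dict[str, int]:
    """Unweighted shortest-path distances by hand-rolled BFS."""
    adj: dict[str, set[str]] = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closeness_bruteforce(gene, targets, edges) -> float:
    dist = bfs_distances(edges, gene) if any(gene in e for e in edges) else {}
    return sum(
        math.exp(-(dist[t] ** 2)) for t in targets if t in dist
    )


def hypergeom_pmf(k, M, n, N) -> float:
    """P(X = k) for k successes drawing N from M with n successes."""
    return (
        math.comb(n, k) * math.comb(M - n, N - k) / math.comb(M, N)
    )


def fisher_tail(overlap, M, n, N) -> float:
    """P(X >= overlap) by exhaustive summation over the support."""
    return sum(
        hypergeom_pmf(k, M, n, N)
        for k in range(overlap, min(n, N) + 1)
    )


def bh_stepup(p):
    """BH adjusted values via the min-over-j>=i formula."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adjusted[i] = running
    return adjusted


def one_hop_union(seeds, edges):
    """Seed set plus all direct interaction partners."""
    out = set(seeds)
    for e in edges:
        a, b = tuple(e)
        if a in seeds:
            out.add(b)
        if b in seeds:
            out.add(a)
    return out


# --- mechanism-pattern oracle -------------------------------------------------

def _reachable(node, label, edges):
    """Nodes reachable from node along label-matching edges (node excluded)."""
    seen, stack = set(), [node]
    while stack:
        x = stack.pop()
        for u, v, l in edges:
            if u == x and l == label and v not in seen:
                seen.add(v)
                stack.append(v)
    seen.discard(node)
    return seen


def oracle_mechanisms(ta, tb, edges, loops):
    """Exhaustive enumeration of the four synergy patterns.

    ``edges``: (source, target, label) triples. ``loops``: iterables of
    node sets. Returns a set of canonical tuples, one per deduplicated
    mechanism:
      ("same_pathway", pathway, upstream, downstream)
      ("crosstalk_convergence", sorted targets, sorted pathways, node)
      ("feedback_loop", sorted member pair)
      ("compensation", sorted targets, sorted pathways, sorted regulated)
    """
    nodes = {x for u, v, _ in edges for x in (u, v)}
    ta = set(ta) & nodes
    tb = set(tb) & nodes
    labels = {l for _, _, l in edges}
    on = {p: {x for u, v, l in edges if l == p for x in (u, v)} for p in labels}
    down = {(n, p): _reachable(n, p, edges) for n in ta | tb for p in labels}
    succ_any = {n: {v for u, v, _ in edges if u == n} for n in nodes}
    succ_lab = {
        (n, p): {v for u, v, l in edges if u == n and l == p}
        for n in nodes
        for p in labels
    }
    found = set()

    for p, u, v in itertools.product(labels, ta, tb):
        if u == v or u not in on[p] or v not in on[p]:
            continue
        for up, dn in ((u, v), (v, u)):
            if dn in down[(up, p)] and down[(dn, p)]:
                found.add(("same_pathway", p, up, dn))

    for p, q, u, v in itertools.product(labels, labels, ta, tb):
        if p == q or u == v or u not in on[p] or v not in on[q]:
            continue
        for node in down[(u, p)] & down[(v, q)]:
            found.add(
                (
                    "crosstalk_convergence",
                    tuple(sorted((u, v))),
                    tuple(sorted((p, q))),
                    node,
                )
            )

    for loop in loops:
        loop = set(loop)
        drive = any(succ_any[w] & loop for w in (ta | tb) - loop)
        if not drive:
            continue
        for x, y in itertools.product(ta & loop, tb & loop):
            if x != y:
                found.add(("feedback_loop", tuple(sorted((x, y)))))

    loop_of = {}
    for loop in loops:
        for m in loop:
            loop_of[m] = frozenset(loop)
    node_labels = {
        n: {l for u, v, l in edges if n in (u, v)} for n in nodes
    }
    for p, q, u, v in itertools.product(labels, labels, ta, tb):
        if p == q or u == v or u not in on[p] or v not in on[q]:
            continue
        if down[(u, p)] & down[(v, q)]:
            continue
        for x in succ_lab[(u, p)]:
            for y in succ_lab[(v, q)]:
                related = (
                    loop_of.get(x) is not None and loop_of.get(x) == loop_of.get(y)
                ) or bool(node_labels[x] & node_labels[y])
                if (
                    x != y
                    and x not in ta | tb
                    and y not in ta | tb
                    and x not in down[(v, q)] | {v}
                    and y not in down[(u, p)] | {u}
                    and related
                ):
                    found.add(
                        (
                            "compensation",
                            tuple(sorted((u, v))),
                            tuple(sorted((p, q))),
                            tuple(sorted((x, y))),
                        )
                    )
    return found


def canonical_records(records):
    """Map implementation MechanismRecords onto the oracle's tuple space."""
    out = set()
    for r in records:
        ev = r.evidence_dict
        if r.kind == "same_pathway":
            out.add((r.kind, ev["pathway"], ev["upstream"], ev["downstream"]))
        elif r.kind == "crosstalk_convergence":
            out.add(
                (
                    r.kind,
                    tuple(ev["targets"].split(",")),
                    tuple(ev["pathways"].split(",")),
                    ev["convergence"],
                )
            )
        elif r.kind == "feedback_loop":
            out.add((r.kind, tuple(ev["members"].split(","))))
        else:
            out.add(
                (
                    r.kind,
                    tuple(ev["targets"].split(",")),
                    tuple(ev["pathways"].split(",")),
                    tuple(ev["regulated"].split(",")),
                )
            )
    return out
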