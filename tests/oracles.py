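"""Independent brute-force oracles for the core combinatorial operations.

These deliberately share no code with the package: clustering is done by
explicit edge enumeration over all pairs, AUROC by enumerating every
pathogenic-benign pair, and predictive values by direct counting at a
threshold.
"""

from __future__ import annotations

from itertools import combinations


def _ham(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def directional_clusters_bruteforce(counts: dict[str, int]) -> list[set[str]]:
    """Directional network collapse by explicit edge enumeration.

    Edge u->v iff Hamming(u, v) <= 1 and count(u) >= 2*count(v) - 1.
    Seeds are taken in descending (count, reverse-lex) order; each seed
    claims every not-yet-claimed node reachable through directed edges
    among unclaimed nodes.
    """
    edges: dict[str, set[str]] = {u: set() for u in counts}
    for u, v in combinations(counts, 2):
        if _ham(u, v) <= 1:
            if counts[u] >= 2 * counts[v] - 1:
                edges[u].add(v)
            if counts[v] >= 2 * counts[u] - 1:
                edges[v].add(u)
    claimed: set[str] = set()
    clusters = []
    for seed in sorted(counts, key=lambda t: (-counts[t], t)):
        if seed in claimed:
            continue
        cluster = {seed}
        changed = True
        while changed:
            changed = False
            for node in list(cluster):
                for nb in edges[node]:
                    if nb not in claimed and nb not in cluster:
                        cluster.add(nb)
                        changed = True
        claimed |= cluster
        clusters.append(cluster)
    return clusters


def adjacency_cluster_count_bruteforce(counts: dict[str, int]) -> int:
    """Adjacency collapse: seeds by descending count absorb unclaimed
    neighbours at distance <= 1 (single hop)."""
    claimed: set[str] = set()
    n = 0
    for seed in sorted(counts, key=lambda t: (-counts[t], t)):
        if seed in claimed:
            continue
        n += 1
        claimed.add(seed)
        for other in counts:
            if other not in claimed and _ham(seed, other) <= 1:
                claimed.add(other)
    return n


def auroc_bruteforce(scores: dict[str, float], labels: dict[str, str]) -> float:
    """AUROC by enumerating all pathogenic-benign pairs (ties: half)."""
    pos = [scores[v] for v in labels if labels[v] == "pathogenic"]
    neg = [scores[v] for v in labels if labels[v] == "benign"]
    wins = 0.0
    for p in pos:
        for b in neg:
            wins += 1.0 if p > b else 0.5 if p == b else 0.0
    return wins / (len(pos) * len(neg))


def predictive_values_bruteforce(
    scores: dict[str, float], labels: dict[str, str], threshold: float
) -> tuple[float | None, float | None]:
    """(PPV, NPV) at one threshold by direct counting."""
    ge = [v for v in labels if scores[v] >= threshold]
    le = [v for v in labels if scores[v] <= threshold]
    ppv = (
        sum(labels[v] == "pathogenic" for v in ge) / len(ge) if ge else None
    )
    npv = sum(labels[v] == "benign" for v in le) / len(le) if le else None
    return ppv, npv


def assignment_bruteforce(
    table: dict[str, dict[str, int]]
) -> dict[str, str | None]:
    """Direct evaluation of the three cell-to-variant validity criteria."""
    out: dict[str, str | None] = {}
    for cell, counts in table.items():
        total = sum(counts.values())
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top_bc, top_n = ranked[0]
        second_n = ranked[1][1] if len(ranked) > 1 else 0
        ok = (
            total >= 3
            and top_n / total > 0.5
            and second_n / total <= 0.25
        )
        out[cell] = top_bc if ok else None
    return out
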