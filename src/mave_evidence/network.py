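"""Error-aware barcode/UMI network clustering.

Implements the two network-collapse strategies used for short random
oligo tags in pooled sequencing experiments:

``directional``
    An edge runs from tag A to tag B when Hamming(A, B) <= max_edit and
    count(A) >= 2 * count(B) - 1; clusters are the nodes reachable from
    count-descending seeds. This asymmetric count rule prevents two
    genuinely distinct, similarly abundant tags from merging while still
    absorbing low-count sequencing-error satellites.

``adjacency``
    Seeds are visited in descending count order; each unclustered seed
    absorbs its still-unclustered neighbours at Hamming distance
    <= max_edit (single hop, no count condition).

Both operate on a mapping ``tag -> read count`` and return clusters as
lists of member tags with a representative (the highest-count member,
ties broken lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagCluster:
    """A cluster of near-identical tags with read counts."""

    representative: str
    members: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


def _neighbour_map(tags: Sequence[str], max_edit: int) -> dict[str, list[str]]:
    """All pairs within ``max_edit`` substitutions (O(n^2); tag sets here
    are small: designed barcodes plus their error satellites, or the UMIs
    of a single cell)."""
    lengths = {len(t) for t in tags}
    if len(lengths) > 1:
        raise ValueError("tags must all have equal length")
    neighbours: dict[str, list[str]] = {t: [] for t in tags}
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            if hamming(a, b) <= max_edit:
                neighbours[a].append(b)
                neighbours[b].append(a)
    return neighbours


def cluster_tags(
    counts: Mapping[str, int],
    max_edit: int = 1,
    method: str = "directional",
) -> list[TagCluster]:
    """Cluster tags by substitution-distance network collapse.

    Every input tag lands in exactly one cluster (a partition). Clusters
    are returned in descending order of their seed count.
    """
    if method not in ("directional", "adjacency"):
        raise ValueError("method must be 'directional' or 'adjacency'")
    if not counts:
        return []
    # descending count, lexicographic tie-break -> fully deterministic
    order = sorted(counts, key=lambda t: (-counts[t], t))
    neighbours = _neighbour_map(order, max_edit)
    assigned: set[str] = set()
    clusters: list[TagCluster] = []
    for seed in order:
        if seed in assigned:
            continue
        cluster = TagCluster(representative=seed, members={seed: counts[seed]})
        assigned.add(seed)
        if method == "adjacency":
            for nb in sorted(neighbours[seed]):
                if nb not in assigned:
                    cluster.members[nb] = counts[nb]
                    assigned.add(nb)
        else:
            frontier = [seed]
            while frontier:
                node = frontier.pop()
                for nb in sorted(neighbours[node]):
                    if nb in assigned:
                        continue
                    if counts[node] >= 2 * counts[nb] - 1:
                        cluster.members[nb] = counts[nb]
                        assigned.add(nb)
                        frontier.append(nb)
        clusters.append(cluster)
    return clusters


def n_clusters(counts: Mapping[str, int], max_edit: int = 1, method: str = "adjacency") -> int:
    """Number of clusters after collapse (the 'unique tag' count)."""
    return len(cluster_tags(counts, max_edit=max_edit, method=method))
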