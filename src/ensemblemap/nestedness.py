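"""The nestedness abstraction: structures -> feature vectors -> clusters.

A nested secondary structure is a forest of helices.  The abstraction keeps
which stem/stack elements exist and where, while ignoring their sizes:
for every outermost helix (a helix whose closing pair sits in the external
loop), count the helices in its subtree plus the internal loops/bulges
separating consecutively nested helices, and place that count at the
helix's outermost 5' position.  Structures sharing a vector form one
structure cluster; elongating a helix on its 3'-interior side, or growing a
loop, does not change the vector, so clusters group structures of identical
architecture.

Hairpin and multibranch loops are not counted: for a nested helix tree they
add no discrimination beyond the helix counts themselves (every helix ends
in exactly one hairpin or branches), whereas internal loops mark genuine
interruptions of a stacked stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structures import SecondaryStructure


@dataclass
class Helix:
    """A maximal run of contiguously stacked pairs (start5+t, end3-t)."""

    start5: int   # 1-based outermost 5' nucleotide
    end3: int     # 1-based outermost 3' nucleotide
    length: int   # number of stacked pairs
    parent: Optional["Helix"] = None
    children: List["Helix"] = field(default_factory=list)

    def inner_pair(self) -> Tuple[int, int]:
        return self.start5 + self.length - 1, self.end3 - self.length + 1


def decompose_helices(structure: SecondaryStructure,
                      min_helix: int = 1) -> List[Helix]:
    """Maximal helices of a nested structure, as a parent-linked forest.

    Helices shorter than ``min_helix`` pairs are removed (default 1 keeps
    everything; 3 reproduces the optional simplification that ignores
    stems of fewer than three base pairs).  Parent/child links are rebuilt
    over the surviving helices.  Returned in 5'-to-3' order of ``start5``.
    """
    pt = structure.pair_table  # construction already rejected pseudoknots
    helices: List[Helix] = []
    seen = set()
    for i, j in structure.pairs():
        if (i, j) in seen:
            continue
        # extend the stack inward from its outermost pair
        if i > 1 and pt[i - 2] == j + 1:
            continue  # not outermost: handled from the pair that starts it
        length = 0
        a, b = i, j
        while a < b and pt[a - 1] == b:
            seen.add((a, b))
            length += 1
            a, b = a + 1, b - 1
        helices.append(Helix(start5=i, end3=j, length=length))
    helices = [h for h in helices if h.length >= min_helix]
    helices.sort(key=lambda h: h.start5)
    # parent = nearest enclosing surviving helix
    for h in helices:
        best = None
        for g in helices:
            if g is h:
                continue
            if g.start5 < h.start5 and h.end3 < g.end3:
                if best is None or g.start5 > best.start5:
                    best = g
        h.parent = best
        if best is not None:
            best.children.append(h)
    return helices


def nestedness_vector(structure: SecondaryStructure,
                      min_helix: int = 1) -> np.ndarray:
    """Length-N integer vector abstracting the structure's architecture.

    For each outermost helix, the entry at its 5' start position holds the
    number of helices in its subtree plus the number of internal
    loops/bulges (single-child junctions) within that subtree.  All other
    entries are zero; the all-unpaired structure maps to the zero vector.
    """
    n = len(structure)
    v = np.zeros(n, dtype=int)
    helices = decompose_helices(structure, min_helix=min_helix)

    def subtree_count(h: Helix) -> int:
        count = 1  # the helix itself
        if len(h.children) == 1:
            count += 1  # internal loop or bulge to the single nested helix
        for c in h.children:
            count += subtree_count(c)
        return count

    for h in helices:
        if h.parent is None:
            v[h.start5 - 1] = subtree_count(h)
    return v


@dataclass
class StructureCluster:
    """All sampled structures sharing one nestedness vector."""

    cluster_id: int
    vector: np.ndarray
    members: List[SecondaryStructure]
    medoid: SecondaryStructure
    frequency: int

    @property
    def size(self) -> int:
        return len(self.members)


def _medoid(members: Sequence[SecondaryStructure]) -> SecondaryStructure:
    """Member minimizing summed Euclidean distance of binary paired vectors.

    Ties resolve to the lowest input index.
    """
    if len(members) == 1:
        return members[0]
    M = np.vstack([m.paired_mask().astype(float) for m in members])
    # pairwise squared distances via the Gram trick
    sq = (M ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    d2 = np.maximum(d2, 0.0)
    totals = np.sqrt(d2).sum(axis=1)
    return members[int(np.argmin(totals))]


def cluster_by_vector(structures: Sequence[SecondaryStructure],
                      min_helix: int = 1) -> List[StructureCluster]:
    """Partition structures into clusters of identical nestedness vectors.

    Cluster ids are assigned in order of first appearance in the input, so
    the result is deterministic for a fixed structure sequence.
    """
    if not structures:
        return []
    lengths = {len(s) for s in structures}
    if len(lengths) != 1:
        raise ValueError(f"structures have mixed lengths: {sorted(lengths)}")
    groups: Dict[Tuple[int, ...], List[SecondaryStructure]] = {}
    order: List[Tuple[int, ...]] = []
    for s in structures:
        key = tuple(nestedness_vector(s, min_helix=min_helix))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    clusters = []
    for cid, key in enumerate(order):
        members = groups[key]
        clusters.append(
            StructureCluster(
                cluster_id=cid,
                vector=np.array(key, dtype=int),
                members=members,
                medoid=_medoid(members),
                frequency=len(members),
            )
        )
    return clusters


def cluster_diversity(cluster: StructureCluster) -> Tuple[float, float, float]:
    """(max_frequency, mean_jaccard, diversity) of a cluster.

    * ``max_frequency`` — share of the modal full structure.
    * ``mean_jaccard`` — mean pairwise Jaccard similarity of the binary
      paired/unpaired representations (1.0 for a singleton).
    * ``diversity`` — u/n with u the number of distinct full structures:
      1 when every member is unique.
    """
    members = cluster.members
    if not members:
        raise ValueError("cluster_diversity requires a non-empty cluster")
    n = len(members)
    counts: Dict[Tuple[int, ...], int] = {}
    for m in members:
        counts[m.pair_table] = counts.get(m.pair_table, 0) + 1
    max_frequency = max(counts.values()) / n
    diversity = len(counts) / n
    if n == 1:
        mean_jaccard = 1.0
    else:
        M = np.vstack([m.paired_mask().astype(float) for m in members])
        inter = M @ M.T
        sizes = M.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore"):
            J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
        iu = np.triu_indices(n, k=1)
        mean_jaccard = float(J[iu].mean())
    return float(max_frequency), float(mean_jaccard), float(diversity)


def cluster_table(clusters: Sequence[StructureCluster]) -> "pandas.DataFrame":
    """Cluster summary as a DataFrame (vector, size, medoid, diversity)."""
    import pandas as pd

    rows = []
    for c in clusters:
        max_f, mean_j, div = cluster_diversity(c)
        rows.append({
            "cluster_id": c.cluster_id,
            "vector": ",".join(map(str, c.vector)),
            "size": c.size,
            "medoid": c.medoid.to_dotbracket(),
            "max_frequency": max_f,
            "mean_jaccard": mean_j,
            "diversity": div,
        })
    return pd.DataFrame(rows)
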