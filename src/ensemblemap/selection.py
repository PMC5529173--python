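"""Selecting maximally diverse ensembles from the mutant panel.

Two filters run in sequence.  First, each RNA's partition function is scored
by ensemble Shannon entropy

    H_i = - sum_j P(x_ij) * log10 P(x_ij)

summed over nucleotides; the lowest-entropy quarter of the panel is
discarded, keeping RNAs whose ensembles are genuinely mixed.  Second, the
surviving RNAs are ordered by structural divergence of their base-pairing
probability vectors P(x_i) = sum_j P(x_ij): hierarchical clustering
(Euclidean distance) identifies the two most divergent partition functions,
and the remainder follow in farthest-point (max-min distance) order.  The
map-building iteration consumes RNAs in this order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from .structures import BasePairProbabilityMatrix


@dataclass(frozen=True)
class EntropyScore:
    """Ensemble Shannon entropy of one RNA's pairing-partner distributions."""

    sequence_id: str
    per_nucleotide_H: np.ndarray
    total_H: float


@dataclass(frozen=True)
class PairingProbabilityVector:
    """P(x_i): the partition function collapsed to per-nucleotide pairing."""

    sequence_id: str
    P_i: np.ndarray


@dataclass(frozen=True)
class DivergenceOrdering:
    """Ordering of RNAs by ensemble divergence.

    ``ids[0:2]`` realize the maximum cophenetic separation of the
    hierarchical clustering (equivalently the maximum pairwise Euclidean
    distance); subsequent ids are in farthest-point order.  ``min_distances``
    holds, for each id, its minimum Euclidean distance to the previously
    selected set (the first entry is the founding pair distance).
    """

    ids: Tuple[str, ...]
    min_distances: Tuple[float, ...]
    degenerate: bool = False


def shannon_entropy(bppm: BasePairProbabilityMatrix) -> EntropyScore:
    """Per-nucleotide and total base-10 Shannon entropy of pairing partners.

    The sum runs over pairing partners only (the unpaired residual mass is
    not a term) and 0*log(0) is taken as 0.
    """
    P = bppm.P
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0.0, -P * np.log10(np.where(P > 0.0, P, 1.0)), 0.0)
    per_nt = terms.sum(axis=1)
    return EntropyScore(
        sequence_id=bppm.sequence_id,
        per_nucleotide_H=per_nt,
        total_H=float(per_nt.sum()),
    )


def pairing_probability_vector(bppm: BasePairProbabilityMatrix) -> PairingProbabilityVector:
    return PairingProbabilityVector(
        sequence_id=bppm.sequence_id, P_i=bppm.pairing_probabilities()
    )


def filter_by_entropy(scores: Sequence[EntropyScore],
                      retain_frac: float = 0.75,
                      always_keep: Sequence[str] = ()) -> List[str]:
    """Retain the ceil(retain_frac * M) highest-entropy RNAs.

    Ties are broken by lexicographic sequence id for determinism.  Ids in
    ``always_keep`` are retained regardless of rank (used to guarantee the
    wild type survives the filter); they do not displace ranked RNAs.
    """
    if not scores:
        raise ValueError("filter_by_entropy requires at least one score")
    if not 0.0 < retain_frac <= 1.0:
        raise ValueError("retain_frac must be in (0, 1]")
    n_keep = math.ceil(retain_frac * len(scores))
    ranked = sorted(scores, key=lambda s: (-s.total_H, s.sequence_id))
    kept = [s.sequence_id for s in ranked[:n_keep]]
    for sid in always_keep:
        if sid not in kept and any(s.sequence_id == sid for s in scores):
            kept.append(sid)
    return kept


def select_divergent(vectors: Sequence[PairingProbabilityVector],
                     k: Optional[int] = None,
                     method: str = "complete") -> DivergenceOrdering:
    """Order RNAs by divergence of their pairing-probability vectors.

    Hierarchical clustering (``method`` linkage, Euclidean metric) supplies
    cophenetic separations; the founding pair maximizes cophenetic
    separation, with ties resolved by larger Euclidean distance and then by
    lexicographic id.  Remaining RNAs are appended greedily, each maximizing
    its minimum Euclidean distance to the already-selected set.
    """
    if len(vectors) < 2:
        raise ValueError("select_divergent requires at least two vectors")
    lengths = {len(v.P_i) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"pairing vectors have mixed lengths: {sorted(lengths)}")
    if k is None:
        k = len(vectors)
    if k > len(vectors):
        warnings.warn(
            f"requested k={k} exceeds the {len(vectors)} available RNAs; "
            "returning all", stacklevel=2,
        )
        k = len(vectors)

    ids = [v.sequence_id for v in vectors]
    X = np.vstack([v.P_i for v in vectors])
    dvec = pdist(X, metric="euclidean")
    D = squareform(dvec)
    if np.all(dvec == 0.0):
        warnings.warn("degenerate: zero diversity among pairing vectors",
                      stacklevel=2)
        order = sorted(range(len(ids)), key=lambda a: ids[a])[:k]
        return DivergenceOrdering(
            ids=tuple(ids[a] for a in order),
            min_distances=tuple(0.0 for _ in order),
            degenerate=True,
        )

    coph = squareform(cophenet(linkage(dvec, method=method)))
    iu = np.triu_indices(len(ids), k=1)
    cands = list(zip(iu[0], iu[1]))
    # max cophenetic separation; ties -> max Euclidean -> lexicographic ids
    best = max(
        cands,
        key=lambda ab: (
            coph[ab], D[ab],
            tuple(sorted((ids[ab[0]], ids[ab[1]]), reverse=True)),
        ),
    )
    a, b = sorted(best, key=lambda x: ids[x])
    selected = [a, b]
    dists = [float(D[a, b]), float(D[a, b])]
    remaining = [x for x in range(len(ids)) if x not in (a, b)]
    while remaining and len(selected) < k:
        min_d = {x: float(D[x, selected].min()) for x in remaining}
        nxt = max(remaining, key=lambda x: (min_d[x], ids[x]))
        selected.append(nxt)
        dists.append(min_d[nxt])
        remaining.remove(nxt)
    return DivergenceOrdering(
        ids=tuple(ids[x] for x in selected[:k]),
        min_distances=tuple(dists[:k]),
    )


def entropy_table(scores: Sequence[EntropyScore],
                  retained: Sequence[str]) -> "pandas.DataFrame":
    """Entropy ranking as a DataFrame (id, total_H, retained flag)."""
    import pandas as pd

    retained_set = set(retained)
    rows = [
        {"id": s.sequence_id, "total_H": s.total_H,
         "retained": s.sequence_id in retained_set}
        for s in sorted(scores, key=lambda s: (-s.total_H, s.sequence_id))
    ]
    return pd.DataFrame(rows)
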