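"""Building the stable 2D map of conformational space.

The map pipeline: generate the disruptive point-mutant panel, compute each
partition function, discard the lowest-entropy quarter, order the survivors
by divergence of their pairing-probability vectors, then Boltzmann-sample
the two most divergent RNAs (1000 structures each by default), abstract the
samples to nestedness vectors, and keep adding the next most divergent
RNA's ensemble until the number of unique structure clusters converges.
The converged clusters are embedded in 2D by metric multidimensional
scaling that minimizes the normalized stress

    Stress = sum_ij (d_ij - ||x_i - x_j||)^2 / sum_ij d_ij^2

over the Euclidean distances d_ij between cluster nestedness vectors,
starting from the classical-scaling eigenvector solution and descending
along the stress gradient with a backtracking line search.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .nestedness import StructureCluster, cluster_by_vector
from .selection import (
    filter_by_entropy,
    pairing_probability_vector,
    select_divergent,
    shannon_entropy,
)
from .sequences import SequenceRecord, generate_point_mutants
from .structures import SecondaryStructure


@dataclass
class ConvergenceTrace:
    """Per-iteration record of the unique-cluster accumulation."""

    rna_ids: List[str] = field(default_factory=list)
    cumulative_clusters: List[int] = field(default_factory=list)

    def record(self, rna_id: str, cumulative: int) -> None:
        if self.cumulative_clusters and cumulative < self.cumulative_clusters[-1]:
            raise ValueError("cumulative cluster count must be non-decreasing")
        self.rna_ids.append(rna_id)
        self.cumulative_clusters.append(cumulative)


def has_converged(trace: Union[ConvergenceTrace, Sequence[int]],
                  window: int = 3, tol: float = 0.0) -> bool:
    """True when cluster-count growth over the last ``window`` additions
    is at most ``tol`` (relative); ``tol=0`` demands no new clusters."""
    counts = (trace.cumulative_clusters
              if isinstance(trace, ConvergenceTrace) else list(trace))
    if len(counts) < window + 1:
        return False
    ref = counts[-1 - window]
    if ref == 0:
        return counts[-1] == 0
    return (counts[-1] - ref) / ref <= tol


def stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Normalized metric-MDS stress between D and the embedded distances."""
    D = np.asarray(D, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if D.shape[0] != coords.shape[0]:
        raise ValueError("distance matrix and coordinates disagree in size")
    iu = np.triu_indices(D.shape[0], k=1)
    d = D[iu]
    denom = (d ** 2).sum()
    if denom == 0.0:
        return 0.0
    delta = squareform(pdist(coords))[iu]
    return float(((d - delta) ** 2).sum() / denom)


def _stress_gradient(D: np.ndarray, coords: np.ndarray,
                     denom: float) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    delta = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(delta, 1.0)
    factor = (delta - D) / delta
    np.fill_diagonal(factor, 0.0)
    return 2.0 * (factor[:, :, None] * diff).sum(axis=1) / denom


def _classical_init(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)[None, :]
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
    return coords


def mds_embed(D: np.ndarray, seed: int = 0, max_iter: int = 300,
              tol: float = 1e-9,
              history: Optional[List[float]] = None
              ) -> Tuple[np.ndarray, float]:
    """Metric MDS: classical-scaling start, gradient descent on the stress.

    Returns ``(coords, final_stress)``.  Coordinates are defined up to
    rigid motion; coincident points are separated by a seeded 1e-9 jitter
    so the gradient is defined.  The backtracking line search guarantees
    the stress never increases between iterations; pass a list as
    ``history`` to receive the per-iteration stress values.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    n = D.shape[0]
    if n == 1:
        return np.zeros((1, 2)), 0.0
    coords = _classical_init(D)
    # coincident embedded points with nonzero target distance: jitter
    rng = np.random.default_rng(seed)
    delta = squareform(pdist(coords))
    mask = np.triu(delta == 0, k=1) & (D > 0)
    if mask.any():
        coords = coords + rng.normal(scale=1e-9, size=coords.shape)
    iu = np.triu_indices(n, k=1)
    denom = (D[iu] ** 2).sum()
    if denom == 0.0:
        return np.zeros((n, 2)), 0.0
    current = stress(D, coords)
    if history is not None:
        history.append(current)
    step = 1.0
    for _ in range(max_iter):
        grad = _stress_gradient(D, coords, denom)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0.0:
            break
        improved = False
        trial_step = step
        for _ in range(40):
            cand = coords - trial_step * grad
            cand_stress = stress(D, cand)
            if cand_stress < current:
                improved = True
                break
            trial_step *= 0.5
        if not improved:
            break
        coords, step = cand, trial_step * 2.0
        improvement = current - cand_stress
        current = cand_stress
        if history is not None:
            history.append(current)
        if improvement < tol:
            break
    return coords, float(current)


@dataclass
class ConformationalMap:
    """The converged cluster set with its 2D embedding.

    The map is the *stable space*: projections of new ensembles never alter
    cluster identities, positions, or the embedding — only bubble sizes.
    """

    sequence_id: str
    sequence: str
    clusters: List[StructureCluster]
    D: np.ndarray
    coords: np.ndarray
    stress: float
    provenance: List[Tuple[str, int]]
    params: Dict[str, object]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def vectors(self) -> np.ndarray:
        return np.vstack([c.vector for c in self.clusters])

    # --- serialization (documented JSON schema; lossless round trip) -----
    #
    # {"format": "ensemblemap-map/1", "sequence_id": ..., "sequence": ...,
    #  "params": {...}, "stress": float, "provenance": [[rna_id, n], ...],
    #  "clusters": [{"cluster_id": int, "vector": [int...], "size": int,
    #                "medoid_dotbracket": str, "coords": [x, y]}, ...]}
    #
    # Cluster member structures other than the medoid are not serialized;
    # distances are recomputed from the vectors on load (they are exact
    # integers-derived Euclidean values, so the round trip is lossless).

    def to_json(self) -> str:
        payload = {
            "format": "ensemblemap-map/1",
            "sequence_id": self.sequence_id,
            "sequence": self.sequence,
            "params": self.params,
            "stress": self.stress,
            "provenance": [[rid, n] for rid, n in self.provenance],
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "vector": [int(x) for x in c.vector],
                    "size": c.frequency,
                    "medoid_dotbracket": c.medoid.to_dotbracket(),
                    "coords": [float(self.coords[k, 0]), float(self.coords[k, 1])],
                }
                for k, c in enumerate(self.clusters)
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "ConformationalMap":
        payload = json.loads(text)
        if payload.get("format") != "ensemblemap-map/1":
            raise ValueError("not an ensemblemap map file")
        clusters = []
        coords = []
        for entry in payload["clusters"]:
            medoid = SecondaryStructure.from_dotbracket(
                entry["medoid_dotbracket"], sequence_id=payload["sequence_id"]
            )
            clusters.append(
                StructureCluster(
                    cluster_id=entry["cluster_id"],
                    vector=np.array(entry["vector"], dtype=int),
                    members=[medoid],
                    medoid=medoid,
                    frequency=entry["size"],
                )
            )
            coords.append(entry["coords"])
        vectors = np.vstack([c.vector for c in clusters])
        D = squareform(pdist(vectors.astype(float)))
        return cls(
            sequence_id=payload["sequence_id"],
            sequence=payload["sequence"],
            clusters=clusters,
            D=D,
            coords=np.array(coords, dtype=float),
            stress=float(payload["stress"]),
            provenance=[(rid, int(n)) for rid, n in payload["provenance"]],
            params=payload["params"],
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ConformationalMap":
        return cls.from_json(Path(path).read_text())


def _child_seed(seed: int, index: int) -> int:
    """Deterministic per-RNA sampling seed derived from the master seed."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2 ** 31))


def build_map(seq: SequenceRecord, engine, n_samples: int = 1000,
              min_helix: int = 1, retain_frac: float = 0.75,
              window: int = 3, tol: float = 0.0, max_added: int = 50,
              seed: int = 0, include_wildtype: bool = True,
              ) -> Tuple[ConformationalMap, ConvergenceTrace]:
    """Run the full map-building pipeline for one sequence.

    Deterministic for a fixed (engine, seed).  ``max_added`` caps the number
    of sampled RNAs; hitting the cap emits a warning.  The wild type is
    exempt from the entropy filter and its ensemble is always merged into
    the map (sampled last if convergence arrives before its turn), so the
    projection target space contains every wild-type-reachable cluster.
    """
    min_hairpin = getattr(getattr(engine, "model", None), "min_hairpin", 3)
    if len(seq) < min_hairpin + 2:
        raise ValueError(
            f"sequence of length {len(seq)} is too short to fold "
            f"(minimum {min_hairpin + 2})"
        )
    panel = [seq] + generate_point_mutants(seq)
    records = {seq.id: seq}
    for m in panel[1:]:
        records[m.id] = SequenceRecord(id=m.id, sequence=m.sequence)
    bppms = {rid: engine.compute_partition(rec) for rid, rec in records.items()}
    scores = [shannon_entropy(b) for b in bppms.values()]
    always = (seq.id,) if include_wildtype else ()
    retained = filter_by_entropy(scores, retain_frac=retain_frac, always_keep=always)
    vectors = [pairing_probability_vector(bppms[rid]) for rid in sorted(retained)]
    ordering = select_divergent(vectors)

    trace = ConvergenceTrace()
    all_structures: List[SecondaryStructure] = []
    provenance: List[Tuple[str, int]] = []
    sampled_ids: List[str] = []

    def add_ensemble(rid: str) -> None:
        rec = records[rid]
        structs = engine.sample_boltzmann(
            rec, n_samples, seed=_child_seed(seed, len(sampled_ids))
        )
        all_structures.extend(structs)
        sampled_ids.append(rid)
        provenance.append((rid, n_samples))
        n_clusters = len(cluster_by_vector(all_structures, min_helix=min_helix))
        trace.record(rid, n_clusters)

    capped = False
    for rid in ordering.ids:
        add_ensemble(rid)
        if len(sampled_ids) >= 2 and has_converged(trace, window=window, tol=tol):
            break
        if len(sampled_ids) >= max_added:
            capped = True
            break
    if capped:
        warnings.warn(
            f"map building stopped at the cap of {max_added} sampled RNAs "
            "before the cluster count converged", stacklevel=2,
        )
    if include_wildtype and seq.id not in sampled_ids:
        add_ensemble(seq.id)

    clusters = cluster_by_vector(all_structures, min_helix=min_helix)
    V = np.vstack([c.vector for c in clusters]).astype(float)
    D = squareform(pdist(V))
    coords, final_stress = mds_embed(D, seed=seed)
    cmap = ConformationalMap(
        sequence_id=seq.id,
        sequence=seq.sequence,
        clusters=clusters,
        D=D,
        coords=coords,
        stress=final_stress,
        provenance=provenance,
        params={
            "engine": getattr(engine, "name", str(engine)),
            "n_samples": n_samples,
            "min_helix": min_helix,
            "retain_frac": retain_frac,
            "converge_window": window,
            "converge_tol": tol,
            "max_added": max_added,
            "seed": seed,
            "include_wildtype": include_wildtype,
        },
    )
    return cmap, trace
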