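"""Projecting ensembles onto a fixed map, and SHAPE comparison analytics.

A projection assigns every structure of a (possibly SHAPE-directed)
Boltzmann sample to a cluster of an existing map by exact nestedness-vector
match, falling back to the nearest cluster by Euclidean distance (logged,
ties to the lowest cluster id).  Cluster frequencies become bubble
diameters; positions and colors come from the map alone, so two
projections on the same map differ only in bubble sizes — the property
that makes condition-to-condition comparison meaningful.

SHAPE profile analytics mirror the comparative figures: a windowed Pearson
correlation across window sizes (trapezoid heatmap) and a 50-nt
deviation-from-median track where positive values flag less-structured
segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

plt.rcParams["svg.hashsalt"] = "ensemblemap"  # deterministic SVG element ids


def _save(fig, out_path: Union[str, Path]) -> Path:
    out_path = Path(out_path)
    kwargs = {}
    if out_path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}  # drop the volatile timestamp
    fig.savefig(out_path, **kwargs)
    plt.close(fig)
    return out_path

from .mapping import ConformationalMap
from .nestedness import StructureCluster, cluster_diversity, nestedness_vector
from .structures import SecondaryStructure, ShapeProfile


@dataclass
class EnsembleProjection:
    """Frequencies of one ensemble over a fixed map's clusters."""

    map: ConformationalMap
    counts: Dict[int, int]
    fractions: Dict[int, float]
    diversity: Dict[int, Tuple[float, float, float]]
    fallback_log: List[Tuple[int, int, float]]  # (structure idx, cluster, dist)
    n: int


def project_ensemble(structures: Sequence[SecondaryStructure],
                     cmap: ConformationalMap,
                     min_helix: Optional[int] = None) -> EnsembleProjection:
    """Assign each structure to a map cluster and tally frequencies.

    ``min_helix`` defaults to the value the map was built with; overriding
    it projects through a different abstraction and is rarely wanted.
    """
    if min_helix is None:
        min_helix = int(cmap.params.get("min_helix", 1))
    n_map = len(cmap.sequence)
    for s in structures:
        if len(s) != n_map:
            raise ValueError(
                f"structure length {len(s)} does not match map sequence "
                f"length {n_map}"
            )
    vec_to_cluster = {tuple(c.vector): c.cluster_id for c in cmap.clusters}
    V = cmap.vectors().astype(float)
    counts: Dict[int, int] = {c.cluster_id: 0 for c in cmap.clusters}
    members: Dict[int, List[SecondaryStructure]] = {
        c.cluster_id: [] for c in cmap.clusters
    }
    fallback: List[Tuple[int, int, float]] = []
    for idx, s in enumerate(structures):
        v = nestedness_vector(s, min_helix=min_helix)
        cid = vec_to_cluster.get(tuple(v))
        if cid is None:
            dists = np.linalg.norm(V - v.astype(float), axis=1)
            best = float(dists.min())
            # ties resolve to the lowest cluster_id; cluster order == row order
            cid = cmap.clusters[int(np.argmin(dists))].cluster_id
            fallback.append((idx, cid, best))
        counts[cid] += 1
        members[cid].append(s)
    n = len(structures)
    fractions = {cid: (c / n if n else 0.0) for cid, c in counts.items()}
    by_id = {c.cluster_id: c for c in cmap.clusters}
    diversity = {
        cid: cluster_diversity(
            StructureCluster(cid, by_id[cid].vector, mem, mem[0], len(mem))
        )
        for cid, mem in members.items() if mem
    }
    return EnsembleProjection(
        map=cmap, counts=counts, fractions=fractions,
        diversity=diversity, fallback_log=fallback, n=n,
    )


def projection_table(projection: EnsembleProjection) -> pd.DataFrame:
    rows = []
    for c in projection.map.clusters:
        cid = c.cluster_id
        div = projection.diversity.get(cid)
        rows.append({
            "cluster_id": cid,
            "count": projection.counts[cid],
            "fraction": projection.fractions[cid],
            "max_frequency": div[0] if div else np.nan,
            "mean_jaccard": div[1] if div else np.nan,
            "diversity": div[2] if div else np.nan,
        })
    return pd.DataFrame(rows)


def _map_colors(cmap: ConformationalMap) -> np.ndarray:
    """Viridis colors indexed by each cluster's 2D distance rank.

    Distances are measured from the embedding centroid, so clusters that
    sit close together in the map take nearby colors; the assignment
    depends only on the map, never on the projected ensemble.
    """
    coords = cmap.coords
    d = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    order = np.argsort(np.argsort(d, kind="stable"), kind="stable")
    t = order / max(len(d) - 1, 1)
    return plt.get_cmap("viridis")(t)


def render_bubble_chart(projection: EnsembleProjection,
                        out_path: Union[str, Path],
                        title: Optional[str] = None,
                        max_bubble_area: float = 2000.0,
                        min_marker_area: float = 15.0) -> Path:
    """Scatter the map with bubble areas proportional to cluster fractions.

    Zero-frequency clusters stay visible as small outline-only markers so
    that paired charts remain visually aligned on the same stable space.
    """
    cmap = projection.map
    colors = _map_colors(cmap)
    fig, ax = plt.subplots(figsize=(6, 5))
    for k, c in enumerate(cmap.clusters):
        frac = projection.fractions[c.cluster_id]
        x, y = cmap.coords[k]
        if frac > 0:
            ax.scatter([x], [y], s=min_marker_area + frac * max_bubble_area,
                       color=colors[k], edgecolors="black", linewidths=0.5,
                       zorder=3)
        else:
            ax.scatter([x], [y], s=min_marker_area, facecolors="none",
                       edgecolors=colors[k], linewidths=1.0, zorder=2)
        ax.annotate(str(c.cluster_id), (x, y), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    min_helix = cmap.params.get("min_helix", 1)
    note = f"min helix = {min_helix}" if int(min_helix) > 1 else ""
    ax.set_title(title or f"{cmap.sequence_id} ensemble projection"
                 + (f" ({note})" if note else ""))
    fig.tight_layout()
    return _save(fig, out_path)


def compare_projections(a: EnsembleProjection, b: EnsembleProjection
                        ) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Per-cluster fraction differences (b - a) and dominant-cluster report.

    Both projections must target the identical map (same stable space).
    """
    if a.map is not b.map and a.map.to_json() != b.map.to_json():
        raise ValueError("projections target different maps; comparison "
                         "requires the identical stable space")
    rows = []
    for c in a.map.clusters:
        cid = c.cluster_id
        fa, fb = a.fractions[cid], b.fractions[cid]
        rows.append({"cluster_id": cid, "fraction_a": fa,
                     "fraction_b": fb, "difference": fb - fa})
    table = pd.DataFrame(rows)
    dom_a = max(a.fractions, key=lambda cid: (a.fractions[cid], -cid))
    dom_b = max(b.fractions, key=lambda cid: (b.fractions[cid], -cid))
    summary = {
        "dominant_a": dom_a,
        "dominant_b": dom_b,
        "dominant_switched": dom_a != dom_b,
    }
    return table, summary


def render_comparison(a: EnsembleProjection, b: EnsembleProjection,
                      out_path: Union[str, Path],
                      labels: Tuple[str, str] = ("A", "B")) -> Path:
    """Side-by-side bubble charts of two projections on one map."""
    cmap = a.map
    compare_projections(a, b)  # validates identical map
    colors = _map_colors(cmap)
    fig, axes = plt.subplots(1, 2, figsize=(11, 5), sharex=True, sharey=True)
    for ax, proj, label in zip(axes, (a, b), labels):
        for k, c in enumerate(cmap.clusters):
            frac = proj.fractions[c.cluster_id]
            x, y = cmap.coords[k]
            if frac > 0:
                ax.scatter([x], [y], s=15.0 + frac * 2000.0, color=colors[k],
                           edgecolors="black", linewidths=0.5)
            else:
                ax.scatter([x], [y], s=15.0, facecolors="none",
                           edgecolors=colors[k])
        ax.set_title(label)
        ax.set_xlabel("dimension 1")
    axes[0].set_ylabel("dimension 2")
    fig.tight_layout()
    return _save(fig, out_path)


# --------------------------------------------------------------------------
# SHAPE comparison analytics
# --------------------------------------------------------------------------

def windowed_correlation(p1: ShapeProfile, p2: ShapeProfile,
                         wmin: int = 40, wmax: int = 140, wstep: int = 5,
                         min_coverage: float = 0.8) -> np.ma.MaskedArray:
    """Sliding-window Pearson correlation between two SHAPE profiles.

    Returns a masked array of shape ``(n_window_sizes, N)``: row k holds
    window size ``wmin + k*wstep``; column s the correlation of the window
    starting at nucleotide s+1 (start positions step by 1).  Entries are
    masked where the window does not fit, where either profile has fewer
    than ``min_coverage`` non-missing entries in the window, or where a
    window is constant (undefined correlation).
    """
    if len(p1) != len(p2):
        raise ValueError(
            f"profile lengths differ: {len(p1)} vs {len(p2)}"
        )
    n = len(p1)
    sizes = list(range(wmin, wmax + 1, wstep))
    out = np.ma.masked_all((len(sizes), n))
    m1, m2 = p1.missing_mask(), p2.missing_mask()
    v1 = np.where(m1, np.nan, p1.reactivity)
    v2 = np.where(m2, np.nan, p2.reactivity)
    for k, w in enumerate(sizes):
        for s in range(0, n - w + 1):
            a = v1[s:s + w]
            b = v2[s:s + w]
            ok = ~(np.isnan(a) | np.isnan(b))
            cov1 = (~np.isnan(a)).sum() / w
            cov2 = (~np.isnan(b)).sum() / w
            if cov1 < min_coverage or cov2 < min_coverage:
                continue
            aa, bb = a[ok], b[ok]
            if aa.size < 2 or aa.std() == 0.0 or bb.std() == 0.0:
                continue
            r = np.corrcoef(aa, bb)[0, 1]
            out[k, s] = r
    return out


def median_deviation_track(p: ShapeProfile, window: int = 50
                           ) -> np.ma.MaskedArray:
    """Windowed mean reactivity minus the profile's global median.

    Positive values mark segments less structured than the RNA overall.
    Missing entries are excluded; all-missing windows are masked.  The
    track has ``N - window + 1`` entries, one per window start.
    """
    if len(p) < window:
        raise ValueError(
            f"profile length {len(p)} is shorter than the window {window}"
        )
    vals = p.values_masked()
    global_median = np.ma.median(vals)
    n = len(p)
    out = np.ma.masked_all(n - window + 1)
    for s in range(n - window + 1):
        seg = vals[s:s + window]
        if seg.count() == 0:
            continue
        out[s] = seg.mean() - global_median
    return out


def correlation_frame(mat: np.ma.MaskedArray, wmin: int = 40,
                      wstep: int = 5) -> pd.DataFrame:
    """Masked correlation matrix as a DataFrame (rows = window sizes)."""
    sizes = [wmin + k * wstep for k in range(mat.shape[0])]
    return pd.DataFrame(
        mat.filled(np.nan), index=pd.Index(sizes, name="window_size"),
        columns=pd.RangeIndex(1, mat.shape[1] + 1, name="start"),
    )


def render_correlation_trapezoid(mat: np.ma.MaskedArray,
                                 out_path: Union[str, Path],
                                 wmin: int = 40, wstep: int = 5,
                                 title: str = "windowed SHAPE correlation"
                                 ) -> Path:
    """Trapezoid heatmap: window size on the vertical axis, start on the
    horizontal; white = high correlation, blue = low."""
    sizes = [wmin + k * wstep for k in range(mat.shape[0])]
    fig, ax = plt.subplots(figsize=(8, 3.5))
    pcm = ax.pcolormesh(
        np.arange(1, mat.shape[1] + 2), np.array(sizes + [sizes[-1] + wstep]),
        mat, cmap="Blues_r", vmin=-1.0, vmax=1.0,
    )
    fig.colorbar(pcm, ax=ax, label="Pearson r")
    ax.set_xlabel("window start (nt)")
    ax.set_ylabel("window size (nt)")
    ax.set_title(title)
    fig.tight_layout()
    return _save(fig, out_path)
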