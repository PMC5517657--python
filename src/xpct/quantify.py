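"""Neurovascular quantification of reconstructed volumes.

The measurements mirror the study design: vessels are extracted by
histogram-based intensity segmentation inside a region of interest, reduced
to centrelines by 3D topological thinning, and summarised as a branch count
(skeleton segments between junctions/endpoints, after spur pruning); motor
neurons are detected in the ventral-horn mask as bright connected components
whose equivalent diameter falls in the typical soma band; groups
(naive / EAE / EAE+MSC at 1 and 5 dpo, n samples each) are summarised as
mean ± sample SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class UnimodalHistogramError(ValueError):
    """Intensity histogram has no usable bimodal structure."""

    def __init__(self, msg: str, histogram=None, bin_edges=None):
        super().__init__(msg)
        self.histogram = histogram
        self.bin_edges = bin_edges


@dataclass
class VesselGraph:
    """Pruned skeleton graph of a vessel mask."""

    graph: nx.Graph
    voxel_size_um: float
    prune_length_um: float

    @property
    def branch_count(self) -> int:
        return self.graph.number_of_edges()

    @property
    def junction_count(self) -> int:
        return sum(1 for n in self.graph.nodes if self.graph.degree(n) >= 3)

    def count(self, mode: str = "segments") -> int:
        if mode == "segments":
            return self.branch_count
        if mode == "junctions":
            return self.junction_count
        raise ValueError(f"unknown counting mode {mode!r}")


@dataclass
class NeuronDetection:
    centroids_um: np.ndarray  # (n, 3) in µm (z, y, x)
    diameters_um: np.ndarray
    threshold: float
    percentile: float
    size_band_um: tuple[float, float]

    @property
    def count(self) -> int:
        return len(self.diameters_um)


# --------------------------------------------------------------------------
# vessel segmentation
# --------------------------------------------------------------------------

def segment_vessels(volume: np.ndarray, roi_mask: np.ndarray,
                    polarity: str = "bright", min_size_vox: int = 27,
                    threshold: Optional[float] = None) -> np.ndarray:
    """Histogram-based vessel segmentation inside a region of interest.

    The threshold comes from a between-class-variance analysis of the ROI
    histogram: a three-class Otsu split (parenchyma, partial-volume halo,
    lumen) whose upper boundary is pushed halfway toward the lumen-class
    mean — under the blur of the imaging chain the raw class boundary sits
    in the halo skirt and would over-segment thin vessels.  ``polarity``
    selects whether vessels are bright (micro: residual blood/contrast) or
    dark relative to the surround.  Components smaller than ``min_size_vox``
    voxels are removed.
    """
    volume = np.asarray(volume, dtype=float)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume must be finite")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    vals = volume[roi_mask]
    signed = vals if polarity == "bright" else -vals
    if polarity not in ("bright", "dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    lo, hi = float(signed.min()), float(signed.max())
    if threshold is None:
        hist, edges = np.histogram(signed, bins=256)
        if hi - lo < 1e-12 * max(abs(hi), 1.0) or hi == lo:
            raise UnimodalHistogramError(
                "ROI histogram is degenerate (constant intensity)", hist, edges)
        t_top = float(threshold_multiotsu(signed, classes=3)[-1])
        top = signed[signed > t_top]
        fg = top.size / signed.size
        if fg <= 1e-6 or fg >= 1 - 1e-6:
            raise UnimodalHistogramError(
                f"histogram threshold collapsed to an extremum (foreground "
                f"fraction {fg:.2g})", hist, edges)
        thr = 0.5 * (t_top + float(top.mean()))
    else:
        thr = float(threshold) if polarity == "bright" else -float(threshold)
    mask = np.zeros(volume.shape, dtype=bool)
    sgn_vol = volume if polarity == "bright" else -volume
    mask[roi_mask] = sgn_vol[roi_mask] > thr
    if min_size_vox > 1 and mask.any():
        lbl, n = ndimage.label(mask, structure=_STRUCT26)
        sizes = np.bincount(lbl.ravel())
        sizes[0] = 0
        mask = (sizes >= min_size_vox)[lbl]
    return mask


# --------------------------------------------------------------------------
# skeleton graph / branch counting
# --------------------------------------------------------------------------

def _neighbor_offsets():
    offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    return np.array(offs)


_OFFS = _neighbor_offsets()


def _skeleton_graph(skel: np.ndarray) -> nx.MultiGraph:
    """Raw skeleton graph: junction voxels (>= 3 neighbours) clustered into
    single nodes, chains of degree-2 voxels traced into edges."""
    skel = skel.astype(bool)
    coords = np.argwhere(skel)
    g = nx.MultiGraph()
    if len(coords) == 0:
        return g
    nb_count = ndimage.convolve(skel.astype(np.uint8), _STRUCT26.astype(np.uint8),
                                mode="constant") - skel.astype(np.uint8)
    nb_count[~skel] = 0
    node_mask = skel & (nb_count != 2)
    # a closed loop has no node voxel; seed one arbitrarily per such component
    lbl_all, n_all = ndimage.label(skel, structure=_STRUCT26)
    has_node = np.zeros(n_all + 1, dtype=bool)
    nodes_lbls = lbl_all[node_mask]
    has_node[nodes_lbls] = True
    for comp in range(1, n_all + 1):
        if not has_node[comp]:
            zyx = np.argwhere(lbl_all == comp)[0]
            node_mask[tuple(zyx)] = True
    clusters, n_clusters = ndimage.label(node_mask, structure=_STRUCT26)
    centroids = ndimage.center_of_mass(node_mask, clusters, range(1, n_clusters + 1))
    for nid, cen in enumerate(centroids, start=1):
        g.add_node(nid, pos_vox=np.asarray(cen))
    shape = skel.shape
    visited = np.zeros(shape, dtype=bool)

    def neighbors(p):
        for off in _OFFS:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if 0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2] \
                    and skel[q]:
                yield q

    # note: two 26-adjacent node voxels always share a cluster, so every edge
    # is a chain of at least one degree-2 voxel; chains are marked visited so
    # each is traced exactly once
    node_voxels = np.argwhere(node_mask)
    for p in map(tuple, node_voxels):
        src = clusters[p]
        for q in neighbors(p):
            if node_mask[q] or visited[q]:
                continue
            path = [p, q]
            visited[q] = True
            prev, cur = p, q
            length = float(np.linalg.norm(np.subtract(q, p)))
            while True:
                cand = [r for r in neighbors(cur) if r != prev]
                ends = [r for r in cand if node_mask[r]]
                if ends:
                    # terminate on a node voxel (prefer one outside src when
                    # the chain leaves and re-enters the same cluster)
                    nxt_v = ends[0]
                    length += float(np.linalg.norm(np.subtract(nxt_v, cur)))
                    path.append(nxt_v)
                    g.add_edge(src, int(clusters[nxt_v]), length_vox=length,
                               path=list(path))
                    break
                cand = [r for r in cand if not visited[r]]
                if not cand:
                    # loose chain tip (possible on seeded closed loops)
                    tip = g.number_of_nodes() + 1
                    g.add_node(tip, pos_vox=np.asarray(cur, float))
                    g.add_edge(src, tip, length_vox=length, path=list(path))
                    break
                prev, cur = cur, cand[0]
                visited[cur] = True
                length += float(np.linalg.norm(np.subtract(cur, prev)))
                path.append(cur)
    return g


def _prune_graph(g: nx.MultiGraph, prune_len_vox: float) -> nx.MultiGraph:
    """Iteratively remove short spurs and short junction-junction links, then
    contract pass-through nodes."""
    g = nx.MultiGraph(g)
    changed = True
    while changed:
        changed = False
        # short leaf spurs
        for u, v, k, data in list(g.edges(keys=True, data=True)):
            if data["length_vox"] >= prune_len_vox:
                continue
            du, dv = g.degree(u), g.degree(v)
            if (du == 1 and dv >= 3) or (dv == 1 and du >= 3):
                g.remove_edge(u, v, key=k)
                changed = True
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
        # short internal junction-junction links: contract
        for u, v, k, data in list(g.edges(keys=True, data=True)):
            if u == v or data["length_vox"] >= prune_len_vox:
                continue
            if g.degree(u) >= 3 and g.degree(v) >= 3:
                g.remove_edge(u, v, key=k)
                g = nx.contracted_nodes(g, u, v, self_loops=False)
                changed = True
                break
        # contract degree-2 pass-through nodes
        for n in list(g.nodes):
            if g.degree(n) != 2 and g.degree(n) != 0:
                continue
            if g.degree(n) == 0:
                g.remove_node(n)
                changed = True
                continue
            ed = list(g.edges(n, keys=True, data=True))
            if len(ed) != 2:
                continue  # double edge to the same neighbour
            (u1, v1, k1, d1), (u2, v2, k2, d2) = ed
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            if a == n or b == n:
                continue  # self loop
            g.remove_edge(u1, v1, key=k1)
            g.remove_edge(u2, v2, key=k2)
            g.remove_node(n)
            g.add_edge(a, b, length_vox=d1["length_vox"] + d2["length_vox"],
                       path=list(d1["path"]) + list(d2["path"]),
                       key=("merged", a, b, d1["length_vox"] + d2["length_vox"]))
            changed = True
        # drop tiny self loops (thinning artefacts around thick junctions)
        for u, v, k, data in list(g.edges(keys=True, data=True)):
            if u == v and data["length_vox"] < prune_len_vox:
                g.remove_edge(u, v, key=k)
                changed = True
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return g


def count_branches(mask: np.ndarray, voxel_size_um: float = 1.0,
                   prune_length_um: Optional[float] = None,
                   count_mode: str = "segments") -> tuple[VesselGraph, int]:
    """Skeletonize a vessel mask and count its branches.

    Branches are skeleton segments between junctions/endpoints surviving
    spur pruning; the default pruning length is twice the maximal vessel
    radius (from the distance transform of the mask), which removes thinning
    artefacts but is shorter than any genuine branch.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty vessel mask: branch count 0", stacklevel=2)
        return VesselGraph(nx.Graph(), voxel_size_um, 0.0), 0
    rmax_vox = float(ndimage.distance_transform_edt(mask).max())
    if prune_length_um is None:
        prune_length_um = 2.0 * rmax_vox * voxel_size_um
    # topological thinning is reliable for tubes a few voxels thick but can
    # swallow junctions of much thicker ones; normalise the scale first
    while rmax_vox > 5.0 and min(mask.shape) > 8:
        mask = ndimage.zoom(mask.astype(float), 0.5, order=1) > 0.5
        voxel_size_um *= 2.0
        rmax_vox = float(ndimage.distance_transform_edt(mask).max())
    skel = skeletonize(mask)
    raw = _skeleton_graph(skel)
    pruned = _prune_graph(raw, prune_length_um / voxel_size_um)
    out = nx.Graph()
    dist = ndimage.distance_transform_edt(mask)
    for n, data in pruned.nodes(data=True):
        kind = "junction" if pruned.degree(n) >= 3 else "endpoint"
        out.add_node(n, pos_um=np.asarray(data.get("pos_vox", (0, 0, 0))) * voxel_size_um,
                     kind=kind)
    for i, (u, v, data) in enumerate(pruned.edges(data=True)):
        path = np.asarray(data["path"])
        radii = dist[tuple(path.T)] if len(path) else np.array([0.0])
        key = (u, v, i)
        if out.has_edge(u, v):
            # parallel edges (loops): keep both by inserting a midpoint node
            mid = max(out.nodes, default=0) + 1
            midpos = path[len(path) // 2] * voxel_size_um
            out.add_node(mid, pos_um=midpos, kind="endpoint")
            half = max(data["length_vox"] / 2, 1e-9) * voxel_size_um
            out.add_edge(u, mid, length_um=half, mean_radius_um=float(radii.mean()) * voxel_size_um)
            out.add_edge(mid, v, length_um=half, mean_radius_um=float(radii.mean()) * voxel_size_um)
            continue
        out.add_edge(u, v, length_um=max(data["length_vox"], 1e-9) * voxel_size_um,
                     mean_radius_um=float(radii.mean()) * voxel_size_um)
    vg = VesselGraph(out, voxel_size_um, prune_length_um)
    return vg, vg.count(count_mode)


# --------------------------------------------------------------------------
# neuron detection
# --------------------------------------------------------------------------

def tubular_components(mask: np.ndarray, min_elongation: float = 2.5) -> np.ndarray:
    """Subset of a binary mask made of tube-like (elongated) components.

    Used to blank out vasculature from the neuron-detection ROI without
    also removing somata that an intensity segmentation may have caught:
    vessels are strongly anisotropic, somata are not.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    lbl, n = ndimage.label(mask, structure=_STRUCT26)
    for comp in range(1, n + 1):
        pts = np.argwhere(lbl == comp)
        if len(pts) < 4:
            continue
        ev = np.linalg.eigvalsh(np.cov(pts.T.astype(float)))
        if np.sqrt(max(ev[-1], 1e-9) / max(ev[0], 1e-9)) >= min_elongation:
            out[lbl == comp] = True
    return out

def detect_neurons(volume: np.ndarray, ventral_mask: np.ndarray,
                   size_band_um: tuple[float, float] = (12.0, 45.0),
                   intensity_percentile: float = 98.0,
                   voxel_size_um: float = 1.0,
                   max_elongation: float = 2.5) -> NeuronDetection:
    """Detect motor-neuron somata: bright, round blobs of soma-like size
    inside the ventral-horn mask (anatomy + typical size principle).

    Seeds are voxels above the given intensity percentile within the mask;
    each seeded component is grown by watershed down to the skirt of the
    blob (halfway between the seed threshold and the mask median) so that
    the measured size reflects the soma rather than its eroded core.
    Components are kept when their equivalent spherical diameter falls
    inside ``size_band_um`` and their principal-axis elongation stays below
    ``max_elongation`` — vessels crossing the horn are tube-like and
    rejected by shape, somata are near-spherical.  Oversized components
    (touching somata whose seeds merged) are split by re-thresholding
    their cores at successively higher levels.
    """
    volume = np.asarray(volume, dtype=float)
    ventral_mask = np.asarray(ventral_mask, dtype=bool)
    lo_vox = size_band_um[0] / voxel_size_um
    hi_vox = size_band_um[1] / voxel_size_um
    if size_band_um[1] <= 2 * voxel_size_um or size_band_um[1] <= size_band_um[0]:
        raise ValueError("size band is empty after voxel conversion")
    vals = volume[ventral_mask]
    thr = float(np.percentile(vals, intensity_percentile))
    if float(np.ptp(vals)) > 1e-12:
        # the percentile alone tracks object density, not brightness: in a
        # depleted horn the top 2% is background ripple.  Otsu's split of
        # the ROI histogram provides an intensity floor.
        thr = max(thr, float(threshold_otsu(vals)))
    low = 0.5 * (thr + float(np.median(vals)))
    bw = ventral_mask & (volume > low)
    if not (ventral_mask & (volume > thr)).any():
        return NeuronDetection(np.empty((0, 3)), np.empty(0), thr,
                               intensity_percentile, size_band_um)

    accepted: list[tuple[np.ndarray, float]] = []  # (centroid_vox, eq_d_vox)

    def elongation(pts: np.ndarray) -> float:
        if len(pts) <= 3:
            return 1.0
        ev = np.linalg.eigvalsh(np.cov(pts.T.astype(float)))
        return float(np.sqrt(max(ev[-1], 1e-9) / max(ev[0], 1e-9)))

    def evaluate(region_mask: np.ndarray, seed_thr: float, depth: int) -> None:
        seeds = region_mask & (volume > seed_thr)
        if not seeds.any():
            return
        markers, _ = ndimage.label(seeds, structure=_STRUCT26)
        lbl = watershed(-volume, markers=markers, mask=region_mask)
        counts = np.bincount(lbl.ravel())
        for comp in np.unique(lbl[seeds]):
            if comp == 0:
                continue
            eq_d = 2.0 * (3.0 * counts[comp] / (4.0 * np.pi)) ** (1.0 / 3.0)
            comp_mask = lbl == comp
            pts = np.argwhere(comp_mask)
            elong = elongation(pts)
            if lo_vox <= eq_d <= hi_vox and elong <= max_elongation:
                accepted.append((pts.mean(axis=0), eq_d))
                continue
            if eq_d >= lo_vox and depth < 4:
                # oversized or elongated blob: could be touching somata whose
                # seeds merged — raise the core threshold and re-split; true
                # vessel fragments stay elongated and die out in recursion
                peak = float(volume[comp_mask].max())
                new_thr = 0.5 * (seed_thr + peak)
                if new_thr > seed_thr:
                    evaluate(comp_mask, new_thr, depth + 1)

    evaluate(bw, thr, 0)
    if not accepted:
        return NeuronDetection(np.empty((0, 3)), np.empty(0), thr,
                               intensity_percentile, size_band_um)
    centroids = np.stack([a[0] for a in accepted]) * voxel_size_um
    diam = np.array([a[1] for a in accepted]) * voxel_size_um
    return NeuronDetection(centroids, diam, thr, intensity_percentile, size_band_um)


# --------------------------------------------------------------------------
# group summary
# --------------------------------------------------------------------------

GROUP_KEYS = ["condition", "timepoint_dpo"]
SAMPLE_FIELDS = ["sample_id", "condition", "timepoint_dpo", "branch_count",
                 "neuron_count", "vessel_volume_fraction"]


@dataclass
class QuantReport:
    """Per-sample measurements and per-group mean ± SD (sample SD, n-1)."""

    per_sample: pd.DataFrame
    per_group: pd.DataFrame

    def to_csv(self, path) -> None:
        s = self.per_sample.copy()
        s.insert(0, "row_type", "sample")
        group = self.per_group.copy()
        group.insert(0, "row_type", "group")
        pd.concat([s, group], ignore_index=True).to_csv(
            path, index=False, float_format="%.6g")


def group_summary(samples: Sequence[dict] | pd.DataFrame) -> QuantReport:
    """Aggregate per-sample counts into group means with sample SD.

    Groups are (condition, timepoint) pairs; a group with a single sample
    gets SD 0 with a warning.  Sample order does not affect the summary.
    """
    df = pd.DataFrame(samples).copy()
    missing = [k for k in GROUP_KEYS if k not in df.columns]
    if missing:
        raise ValueError(f"samples lack group keys: {missing}")
    if len(df) == 0:
        raise ValueError("no samples to summarise")
    metrics = [c for c in df.columns
               if c not in GROUP_KEYS + ["sample_id", "seed", "status"]
               and np.issubdtype(df[c].dtype, np.number)]
    rows = []
    for (cond, tp), sub in df.groupby(GROUP_KEYS, sort=True):
        row = {"condition": cond, "timepoint_dpo": tp, "n": len(sub)}
        if len(sub) == 1:
            warnings.warn(f"group ({cond}, {tp} dpo) has n = 1: SD reported as 0",
                          stacklevel=2)
        for m in metrics:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    per_group = pd.DataFrame(rows).sort_values(GROUP_KEYS).reset_index(drop=True)
    order = df.sort_values([c for c in ["condition", "timepoint_dpo", "sample_id"]
                            if c in df.columns]).reset_index(drop=True)
    return QuantReport(order, per_group)
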