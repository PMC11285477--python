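"""Watershed feature characterization with Wolf pruning (ISO 25178-2 feature group).

Dales are the catchment basins of the surface's pits, hills the catchments of
its peaks (watershed of the inverted surface), both with 8-connectivity.
Wolf pruning removes insignificant features: every pit/peak whose prominence
(height difference to the saddle connecting it to a deeper/higher feature) is
below ``prune_fraction × Sz`` is merged into its neighbour across that saddle.
Pruning is implemented as persistence thresholding on the saddle merge tree
(Kruskal union-find with the elder rule: the deeper extremum survives, ties
broken row-major), which yields the same surviving set as iteratively merging
the least prominent feature first.

Pixel flooding is delegated to :func:`skimage.segmentation.watershed`; the
merge tree, pruning, and the nine feature parameters are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .surface_io import HeightMap, fill_nonmeasured

_EIGHT = np.ones((3, 3), dtype=bool)
# forward shifts covering all 8-neighbour pairs exactly once
_SHIFTS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class Feature:
    """One significant dale (pit) or hill (peak)."""

    label: int
    row: int
    col: int
    height: float  # signed extremum height on the original surface (µm)
    prominence: float  # height to the connecting saddle (µm)
    area: float  # closed area (µm²); full catchment area for open features
    volume: float  # volume between feature surface and closing saddle (µm³)
    closed: bool  # feature does not touch the map border


@dataclass
class SegmentationResult:
    dale_labels: np.ndarray
    hill_labels: np.ndarray
    dales: list[Feature]
    hills: list[Feature]
    threshold: float  # pruning threshold used (µm)
    surface: HeightMap
    filled: bool = False
    flags: set = field(default_factory=set)


def _region_edges(labels: np.ndarray, z: np.ndarray):
    """Minimum saddle height between each pair of 8-adjacent label regions.

    The saddle candidate of an adjacent pixel pair is max(z1, z2); the saddle
    of a region pair is the minimum candidate along their shared boundary.
    Returns (lo, hi, saddle) arrays with lo < hi.
    """
    ny, nx = labels.shape
    keys = []
    sads = []
    nlab = int(labels.max())
    base = np.int64(nlab + 1)
    for dr, dc in _SHIFTS:
        c0 = max(0, -dc)
        c1 = nx - max(0, dc)
        a = labels[0 : ny - dr, c0:c1]
        b = labels[dr:ny, c0 + dc : c1 + dc]
        za = z[0 : ny - dr, c0:c1]
        zb = z[dr:ny, c0 + dc : c1 + dc]
        diff = a != b
        if not diff.any():
            continue
        lo = np.minimum(a[diff], b[diff]).astype(np.int64)
        hi = np.maximum(a[diff], b[diff]).astype(np.int64)
        keys.append(lo * base + hi)
        sads.append(np.maximum(za[diff], zb[diff]))
    if not keys:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    keys = np.concatenate(keys)
    sads = np.concatenate(sads)
    uniq, inv = np.unique(keys, return_inverse=True)
    saddle = np.full(uniq.size, np.inf)
    np.minimum.at(saddle, inv, sads)
    return (uniq // base).astype(int), (uniq % base).astype(int), saddle


def _segment_single(z: np.ndarray, threshold: float):
    """Watershed + Wolf pruning of the pits of ``z``.

    Returns (final label image with labels 1..K, list of per-region dicts).
    """
    minima = local_minima(z, connectivity=2)
    markers, nmark = ndimage.label(minima, structure=_EIGHT)
    labels = watershed(z, markers, connectivity=2)

    # representative pit pixel per marker: first row-major pixel of the minimum plateau
    flat = np.flatnonzero(minima.ravel())
    mk = markers.ravel()[flat]
    order = np.argsort(mk, kind="stable")
    ids, first = np.unique(mk[order], return_index=True)
    rep = np.zeros(nmark + 1, dtype=np.int64)
    rep[ids] = flat[order][first]
    pit_h = np.full(nmark + 1, np.inf)
    pit_h[ids] = z.ravel()[rep[ids]]

    # Kruskal over saddle edges, elder rule: deeper pit survives, ties row-major
    lo, hi, sad = _region_edges(labels, z)
    eorder = np.lexsort((lo, hi, sad))
    parent = np.arange(nmark + 1)
    persistence = np.full(nmark + 1, np.inf)
    died_into = np.zeros(nmark + 1, dtype=np.int64)

    def find(m):
        root = m
        while parent[root] != root:
            root = parent[root]
        while parent[m] != root:
            parent[m], m = root, parent[m]
        return root

    for e in eorder:
        ra, rb = find(lo[e]), find(hi[e])
        if ra == rb:
            continue
        # elder: deeper pit, ties broken by row-major pit position
        if (pit_h[ra], rep[ra]) <= (pit_h[rb], rep[rb]):
            elder, younger = ra, rb
        else:
            elder, younger = rb, ra
        persistence[younger] = sad[e] - pit_h[younger]
        died_into[younger] = elder
        parent[younger] = elder

    zmax = float(z.max())
    persistence[persistence == np.inf] = np.inf  # global root keeps inf
    significant = persistence >= threshold
    significant[0] = False

    # resolve every marker to its significant ancestor
    anc = np.arange(nmark + 1)
    for m in range(1, nmark + 1):
        a = m
        while not significant[a]:
            a = died_into[a]
        anc[m] = a
    sig_ids = np.flatnonzero(significant)
    # deterministic compact labels ordered by row-major pit position
    sig_ids = sig_ids[np.argsort(rep[sig_ids], kind="stable")]
    lut = np.zeros(nmark + 1, dtype=np.int64)
    lut[sig_ids] = np.arange(1, sig_ids.size + 1)
    final = lut[anc[labels]]

    # per-region geometry on the pruned segmentation
    k = sig_ids.size
    areas_px = np.bincount(final.ravel(), minlength=k + 1)
    border = np.zeros(k + 1, dtype=bool)
    for edge in (final[0, :], final[-1, :], final[:, 0], final[:, -1]):
        border[np.unique(edge)] = True
    flo, fhi, fsad = _region_edges(final, z)
    closing = np.full(k + 1, np.inf)
    np.minimum.at(closing, flo, fsad)
    np.minimum.at(closing, fhi, fsad)
    if k == 1:
        # a single catchment closes at the lowest point of the map border
        closing[1] = min(z[0, :].min(), z[-1, :].min(), z[:, 0].min(), z[:, -1].min())
    vol_px = np.maximum(closing[final] - z, 0.0)
    vols = np.bincount(final.ravel(), weights=vol_px.ravel(), minlength=k + 1)

    ny, nx = z.shape
    regions = []
    for j, m in enumerate(sig_ids, start=1):
        r, c = divmod(int(rep[m]), nx)
        prom = float(persistence[m]) if np.isfinite(persistence[m]) else zmax - float(pit_h[m])
        regions.append(
            dict(
                label=j,
                row=r,
                col=c,
                pit_height=float(pit_h[m]),
                prominence=prom,
                area_px=int(areas_px[j]),
                volume_px=float(vols[j]),
                closed=not bool(border[j]),
            )
        )
    return final, regions


def segment(hm: HeightMap, prune_fraction: float = 0.05) -> SegmentationResult:
    """Full feature segmentation of a surface: dales, hills and pruning.

    ``prune_fraction`` is the Wolf threshold as a fraction of Sz (max minus
    min height of this surface); the standard DMTA setting is 5%.
    """
    filled = bool(hm.mask.any())
    if filled:
        hm = fill_nonmeasured(hm)
    z = hm.heights
    sz = float(np.ptp(z))
    if sz == 0.0:
        empty = np.zeros(hm.shape, dtype=np.int64)
        return SegmentationResult(
            empty, empty.copy(), [], [], 0.0, hm, filled, flags={"degenerate_surface"}
        )
    t = prune_fraction * sz
    px_area = hm.dx * hm.dy

    dale_labels, dale_regions = _segment_single(z, t)
    hill_labels, hill_regions = _segment_single(-z, t)

    def to_features(regions, sign):
        out = []
        for r in regions:
            out.append(
                Feature(
                    label=r["label"],
                    row=r["row"],
                    col=r["col"],
                    height=sign * r["pit_height"],
                    prominence=r["prominence"],
                    area=r["area_px"] * px_area,
                    volume=r["volume_px"] * px_area,
                    closed=r["closed"],
                )
            )
        return out

    return SegmentationResult(
        dale_labels=dale_labels,
        hill_labels=hill_labels,
        dales=to_features(dale_regions, +1),
        hills=to_features(hill_regions, -1),
        threshold=t,
        surface=hm,
        filled=filled,
    )


def _mean_curvature_at(z, rows, cols, dx, dy):
    """-(z_xx + z_yy)/2 by the 5-point Laplacian, edge-replicated."""
    zp = np.pad(z, 1, mode="edge")
    r = np.asarray(rows) + 1
    c = np.asarray(cols) + 1
    d2x = (zp[r, c + 1] - 2 * zp[r, c] + zp[r, c - 1]) / dx**2
    d2y = (zp[r + 1, c] - 2 * zp[r, c] + zp[r - 1, c]) / dy**2
    return -0.5 * (d2x + d2y)


def feature_parameters(seg: SegmentationResult) -> tuple[dict, set]:
    """The nine feature parameters from a pruned segmentation.

    Spd counts all significant peaks per unit area; the "closed" means
    Sda/Sha/Sdv/Shv average only features that do not touch the map border.
    With fewer than five significant peaks (pits), S5p (S5v) averages the
    available ones and sets a shortfall flag.
    """
    hm = seg.surface
    flags: set[str] = set(seg.flags)
    area = hm.shape[0] * hm.shape[1] * hm.dx * hm.dy
    peaks = seg.hills
    pits = seg.dales

    if not peaks and not pits:
        flags.add("degenerate_surface")
        return {p: 0.0 for p in ("Spd", "Spc", "S10z", "S5p", "S5v", "Sda", "Sha", "Sdv", "Shv")}, flags

    # peak ordering: by height (descending), ties row-major
    def order_desc(feats, key):
        return sorted(feats, key=lambda f: (-key(f), f.row, f.col))

    top_peaks = order_desc(peaks, lambda f: f.height)
    top_pits = order_desc(pits, lambda f: -f.height)
    if len(top_peaks) < 5 or len(top_pits) < 5:
        flags.add("feature_shortfall")
    s5p = float(np.mean([f.height for f in top_peaks[:5]])) if top_peaks else 0.0
    s5v = float(np.mean([-f.height for f in top_pits[:5]])) if top_pits else 0.0

    if peaks:
        curv = _mean_curvature_at(
            hm.heights, [f.row for f in peaks], [f.col for f in peaks], hm.dx, hm.dy
        )
        spc = float(np.mean(curv))
    else:
        spc = 0.0

    def closed_mean(feats, attr):
        vals = [getattr(f, attr) for f in feats if f.closed]
        if not vals:
            flags.add("no_closed_features")
            return 0.0
        return float(np.mean(vals))

    params = {
        "Spd": len(peaks) / area,
        "Spc": spc,
        "S5p": s5p,
        "S5v": s5v,
        "S10z": s5p + s5v,
        "Sda": closed_mean(pits, "area"),
        "Sha": closed_mean(peaks, "area"),
        "Sdv": closed_mean(pits, "volume"),
        "Shv": closed_mean(peaks, "volume"),
    }
    return params, flags
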