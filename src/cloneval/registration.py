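"""Locating DNA clones on the chip: stitching, matching, and mapping.

The sequencer reports cluster coordinates in image pixel space; the motorized
stage that drives the retrieval laser lives in its own coordinate system.  The
chain implemented here recovers the mapping:

1. :func:`detect_spots` - sub-pixel spot centroids in each camera frame;
2. :func:`stitch_frames` - global float-valued frame offsets reconciled by
   least squares over the frame adjacency graph (offsets are *never* rounded
   to integers, so stitching error does not accumulate along long chains);
3. :func:`match_point_patterns` - correspondence between observed spots and
   expected cluster positions via triangle descriptors that are invariant to
   translation, rotation and scale;
4. :func:`fit_similarity_lsq` - the pixel-to-stage similarity transform in
   closed form from the least-squares criterion;
5. :func:`map_and_plan` - stage coordinates and well assignments for every
   selected clone, traceable back to its read.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .select import CoordinateIndex


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = s R(theta) x + t, with s > 0 (reflections excluded: a chip
    cannot mirror)."""

    scale: float = 1.0
    rotation: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array(
            [
                [self.scale * c, -self.scale * s, self.tx],
                [self.scale * s, self.scale * c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out[0] if np.ndim(points) == 1 else out

    def inverse(self) -> "SimilarityTransform":
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        inv_s = 1.0 / self.scale
        tx = -inv_s * (c * self.tx - s * self.ty)
        ty = -inv_s * (s * self.tx + c * self.ty)
        return SimilarityTransform(inv_s, -self.rotation, tx, ty)

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``inner`` first, then ``self``."""
        m = self.matrix @ inner.matrix
        rot = np.arctan2(m[1, 0], m[0, 0])
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        return SimilarityTransform(scale, float(rot), float(m[0, 2]), float(m[1, 2]))


def fit_similarity_lsq(
    src: np.ndarray,
    dst: np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> tuple[SimilarityTransform, float]:
    """Closed-form least-squares similarity transform mapping src -> dst.

    The optimum follows from centering both point sets and taking the
    cross-covariance of the centered coordinates: with p_i = src - mean(src),
    q_i = dst - mean(dst),

        a = sum(p_i . q_i),  b = sum(p_i x q_i),
        theta = atan2(b, a),  s = sqrt(a^2 + b^2) / sum(|p_i|^2),

    and the translation carries the centroids onto each other.  Returns the
    transform and the RMS residual.  Coincident source points (zero variance)
    are rejected; two distinct points suffice.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if correspondence is not None:
        ii = [i for i, _ in correspondence]
        jj = [j for _, j in correspondence]
        src, dst = src[ii], dst[jj]
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    if len(src) < 2:
        raise ValueError("need at least 2 correspondences")
    p = src - src.mean(axis=0)
    q = dst - dst.mean(axis=0)
    denom = float((p * p).sum())
    if denom < 1e-12:
        raise ValueError("degenerate (coincident) source points")
    a = float((p * q).sum())
    b = float((p[:, 0] * q[:, 1] - p[:, 1] * q[:, 0]).sum())
    theta = float(np.arctan2(b, a))
    s = float(np.hypot(a, b)) / denom
    if s <= 0:
        raise ValueError("degenerate configuration: zero scale")
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -sn], [sn, c]])
    t = dst.mean(axis=0) - s * rot @ src.mean(axis=0)
    tf = SimilarityTransform(s, theta, float(t[0]), float(t[1]))
    rms = float(np.sqrt(((tf(src) - dst) ** 2).sum(axis=1).mean()))
    return tf, rms


# ---------------------------------------------------------------------------
# spot detection


@dataclass
class SpotSet:
    """Sub-pixel spot centroids for one camera frame, ordered by (y, x)."""

    xy: np.ndarray  # (n, 2) float, columns x, y
    weights: np.ndarray  # (n,) positive
    frame_id: object = None
    n_dropped: int = 0  # spots discarded because a neighbor was too close

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.xy)


def detect_spots(
    image: np.ndarray,
    min_intensity: float,
    min_separation: float = 4.0,
    window: int = 3,
) -> SpotSet:
    """Local maxima above ``min_intensity`` refined to sub-pixel centroids.

    Peak pairs closer than ``min_separation`` cannot be retrieved without
    hitting both clones, so *both* are dropped (and counted in ``n_dropped``).
    The sub-pixel position comes from three-point Gaussian (log-quadratic)
    interpolation through the peak - exact for a sampled Gaussian spot - with
    an intensity-weighted centroid over a ``(2*window+1)`` square as the
    fallback when interpolation is undefined (borders, flat patches).
    """
    from skimage.feature import peak_local_max

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    peaks = peak_local_max(
        img, min_distance=1, threshold_abs=min_intensity, exclude_border=False
    )
    if len(peaks) == 0:
        return SpotSet(np.empty((0, 2)), np.empty(0))
    keep = np.ones(len(peaks), dtype=bool)
    if len(peaks) > 1:
        tree = cKDTree(peaks.astype(float))
        for i, j in tree.query_pairs(min_separation):
            keep[i] = keep[j] = False
    n_dropped = int((~keep).sum())
    peaks = peaks[keep]
    cents, weights = [], []
    h, w = img.shape
    for r, c in peaks:
        if not (0 < r < h - 1 and 0 < c < w - 1):
            continue  # clipped by the frame border: unreliable center
        xy = _gaussian_interp(img, r, c)
        if xy is None:
            r0, r1 = max(0, r - window), min(h, r + window + 1)
            c0, c1 = max(0, c - window), min(w, c + window + 1)
            patch = img[r0:r1, c0:c1]
            wts = np.clip(patch - patch.min(), 0, None)
            total = wts.sum()
            if total <= 0:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            xy = ((wts * cc).sum() / total, (wts * rr).sum() / total)
        cents.append(xy)
        weights.append(img[r, c])
    cents_a = np.array(cents).reshape(-1, 2)
    order = np.lexsort((cents_a[:, 0], cents_a[:, 1]))  # y, then x
    return SpotSet(cents_a[order], np.array(weights)[order], n_dropped=n_dropped)


def _gaussian_interp(img: np.ndarray, r: int, c: int) -> tuple[float, float] | None:
    """Sub-pixel peak via log-quadratic interpolation along each axis."""
    h, w = img.shape
    if not (0 < r < h - 1 and 0 < c < w - 1):
        return None
    vals = img[r - 1 : r + 2, c - 1 : c + 2]
    if (vals <= 0).any():
        return None
    ln = np.log(vals)

    def vertex(lm, l0, lp):
        denom = lm - 2 * l0 + lp
        if denom >= -1e-12:  # not a concave peak
            return None
        return 0.5 * (lm - lp) / denom

    dx = vertex(ln[1, 0], ln[1, 1], ln[1, 2])
    dy = vertex(ln[0, 1], ln[1, 1], ln[2, 1])
    if dx is None or dy is None or abs(dx) > 1 or abs(dy) > 1:
        return None
    return (c + dx, r + dy)


# ---------------------------------------------------------------------------
# stitching


@dataclass
class StitchResult:
    """Float-valued global offsets per frame (reference frame at (0, 0))."""

    offsets: dict  # frame_id -> np.ndarray (2,)
    residuals: dict  # (frame_i, frame_j) -> float
    dead_reckoned: tuple = ()

    def global_xy(self, frame_id, local_xy: np.ndarray) -> np.ndarray:
        return np.asarray(local_xy, dtype=float) + self.offsets[frame_id]


def _pair_offset(
    xy_i: np.ndarray, xy_j: np.ndarray, nominal: np.ndarray, search_radius: float
) -> tuple[np.ndarray, int]:
    """Estimate o_j - o_i from shared spots; returns (offset, n_matched)."""
    est = np.asarray(nominal, dtype=float)
    n_matched = 0
    for _ in range(2):  # one re-match with the refined estimate
        if len(xy_i) == 0 or len(xy_j) == 0:
            return est, 0
        proj = xy_j + est  # j's spots in i's frame
        tree_i = cKDTree(xy_i)
        d_ij, idx_i = tree_i.query(proj, distance_upper_bound=search_radius)
        tree_j = cKDTree(proj)
        _, idx_j = tree_j.query(xy_i, distance_upper_bound=search_radius)
        pairs = [
            (idx_i[j], j)
            for j in range(len(proj))
            if np.isfinite(d_ij[j]) and idx_i[j] < len(xy_i) and idx_j[idx_i[j]] == j
        ]
        if not pairs:
            return est, 0
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        est = (xy_i[ii] - xy_j[jj]).mean(axis=0)
        n_matched = len(pairs)
    return est, n_matched


def stitch_frames(
    spot_sets: Mapping,
    frame_adjacency: Sequence[tuple],
    overlap_margin: float,
    search_radius: float = 3.0,
    reference_frame=None,
    integer_offsets: bool = False,
) -> StitchResult:
    """Reconcile pairwise frame offsets into global float offsets.

    ``spot_sets`` maps frame id to a :class:`SpotSet` (or an (n, 2) array of
    frame-local centroids); ``frame_adjacency`` lists
    ``(frame_i, frame_j, nominal_offset)`` edges with the nominal relative
    offset ``o_j - o_i`` (e.g. from the stage raster).  Pairwise offsets are
    estimated from mutual-nearest-neighbor spot pairs in the overlap and then
    reconciled globally by least squares over the whole graph rather than
    chained sequentially.  ``integer_offsets=True`` rounds each pairwise
    estimate to whole pixels first - the naive baseline, kept only so the
    accumulation error of rounding can be measured against the float pipeline.
    """
    if overlap_margin <= 0:
        raise ValueError("overlap_margin must be positive")
    frames = list(spot_sets)
    if reference_frame is None:
        reference_frame = frames[0]
    coords = {
        f: (s.xy if isinstance(s, SpotSet) else np.asarray(s, dtype=float))
        for f, s in spot_sets.items()
    }
    if len(frames) == 1:
        return StitchResult({frames[0]: np.zeros(2)}, {})

    index = {f: k for k, f in enumerate(frames)}
    edges, d_est, dead = [], [], []
    for fi, fj, nominal in frame_adjacency:
        est, n = _pair_offset(coords[fi], coords[fj], nominal, search_radius)
        if n == 0:
            warnings.warn(
                f"no shared spots between frames {fi!r} and {fj!r}; "
                "stitching this edge by dead reckoning"
            )
            dead.append((fi, fj))
            est = np.asarray(nominal, dtype=float)
        if integer_offsets:
            est = np.round(est)
        edges.append((index[fi], index[fj]))
        d_est.append(est)

    # least squares over the graph: minimize sum || (o_j - o_i) - d_ij ||^2
    nf = len(frames)
    a = np.zeros((len(edges) + 1, nf))
    bx = np.zeros(len(edges) + 1)
    by = np.zeros(len(edges) + 1)
    for row, ((i, j), d) in enumerate(zip(edges, d_est)):
        a[row, i] = -1.0
        a[row, j] = 1.0
        bx[row], by[row] = d
    a[-1, index[reference_frame]] = 1.0  # anchor the reference frame at 0
    sol_x, *_ = np.linalg.lstsq(a, bx, rcond=None)
    sol_y, *_ = np.linalg.lstsq(a, by, rcond=None)
    offsets = {f: np.array([sol_x[k], sol_y[k]]) for f, k in index.items()}
    residuals = {
        (frames[i], frames[j]): float(
            np.hypot(*(offsets[frames[j]] - offsets[frames[i]] - d))
        )
        for (i, j), d in zip(edges, d_est)
    }
    return StitchResult(offsets, residuals, tuple(dead))


# ---------------------------------------------------------------------------
# point-pattern matching


class NoMatchError(RuntimeError):
    """The observed spot pattern could not be matched to the expected one
    (wrong chip region, or too few consistent points)."""


def _triangles(n: int, cap: int = 40) -> np.ndarray:
    idx = np.arange(n)
    if n > cap:  # deterministic thinning for large point sets
        idx = np.unique(np.linspace(0, n - 1, cap).round().astype(int))
    return np.array(list(itertools.combinations(idx, 3)), dtype=int)


def _descriptors(points: np.ndarray, tris: np.ndarray):
    """Similarity-invariant triangle descriptors (sorted side ratios) with the
    vertex order canonicalized as (opposite longest, middle, shortest side)."""
    descs, orders = [], []
    for t in tris:
        p = points[t]
        sides = np.array(
            [
                np.linalg.norm(p[1] - p[2]),  # opposite vertex 0
                np.linalg.norm(p[0] - p[2]),
                np.linalg.norm(p[0] - p[1]),
            ]
        )
        c = sides.max()
        if c < 1e-9:
            continue
        ratios = np.sort(sides / c)
        if ratios[0] < 0.15:  # nearly degenerate triangle: unstable
            continue
        order = np.argsort(-sides)  # vertex opposite longest side first
        descs.append(ratios[:2])
        orders.append(t[order])
    return np.array(descs).reshape(-1, 2), np.array(orders, dtype=int).reshape(-1, 3)


def match_point_patterns(
    observed: "SpotSet | np.ndarray",
    expected: np.ndarray,
    min_inlier_fraction: float = 0.5,
    descriptor_tol: float = 0.02,
    match_tol: float = 3.0,
) -> tuple[list[tuple[int, int]], float, SimilarityTransform]:
    """Correspondence between observed spots and expected cluster positions.

    Triangle descriptors (pairwise distance ratios) propose vertex
    correspondences; each proposal is turned into a similarity transform and
    verified by consensus - the transform mapping the most observed points
    onto distinct expected points within ``match_tol`` (expected-space units)
    wins, and is refined on its inliers.  Returns
    ``(pairs, inlier_fraction, transform)`` with pairs as (observed index,
    expected index).  Raises :class:`NoMatchError` when the best consensus
    stays below ``min_inlier_fraction``.
    """
    obs = observed.xy if isinstance(observed, SpotSet) else np.asarray(observed, float)
    exp = np.asarray(expected, dtype=float)
    if len(obs) < 3 or len(exp) < 3:
        raise ValueError("need at least 3 points on each side")

    tris_o = _triangles(len(obs))
    tris_e = _triangles(len(exp))
    desc_o, ord_o = _descriptors(obs, tris_o)
    desc_e, ord_e = _descriptors(exp, tris_e)
    if len(desc_o) == 0 or len(desc_e) == 0:
        raise NoMatchError("all candidate triangles were degenerate")

    tree = cKDTree(desc_e)
    dist, nearest = tree.query(desc_o, distance_upper_bound=descriptor_tol)
    exp_tree = cKDTree(exp)

    best: tuple[int, float, list, SimilarityTransform] | None = None
    order = np.argsort(dist)  # try the most confident descriptor pairs first
    tried = 0
    for k in order:
        if not np.isfinite(dist[k]):
            break
        tried += 1
        if best is not None and tried > 200:
            break
        src = obs[ord_o[k]]
        dst = exp[ord_e[nearest[k]]]
        try:
            tf, _ = fit_similarity_lsq(src, dst)
        except ValueError:
            continue
        proj = tf(obs)
        d, j = exp_tree.query(proj, distance_upper_bound=match_tol)
        pairs: dict[int, tuple[float, int]] = {}
        for i in range(len(obs)):
            if np.isfinite(d[i]) and j[i] < len(exp):
                cur = pairs.get(j[i])
                if cur is None or d[i] < cur[0]:
                    pairs[j[i]] = (d[i], i)
        inliers = [(i, jj) for jj, (_, i) in pairs.items()]
        rms = float(np.mean([d for d, _ in pairs.values()])) if pairs else np.inf
        key = (len(inliers), -rms)
        if best is None or key > (best[0], -best[1]):
            best = (len(inliers), rms, inliers, tf)
            if len(inliers) == min(len(obs), len(exp)):
                break
    if best is None:
        raise NoMatchError("no triangle descriptor agreement between patterns")

    _, _, inliers, tf = best
    # refine on the consensus set and re-derive the final correspondence
    if len(inliers) >= 2:
        tf, _ = fit_similarity_lsq(obs, exp, correspondence=inliers)
        proj = tf(obs)
        d, j = exp_tree.query(proj, distance_upper_bound=match_tol)
        claimed: dict[int, tuple[float, int]] = {}
        for i in range(len(obs)):
            if np.isfinite(d[i]) and j[i] < len(exp):
                cur = claimed.get(j[i])
                if cur is None or d[i] < cur[0]:
                    claimed[j[i]] = (d[i], i)
        inliers = sorted((i, jj) for jj, (_, i) in claimed.items())
    frac = len(inliers) / min(len(obs), len(exp))
    if frac < min_inlier_fraction:
        raise NoMatchError(
            f"inlier fraction {frac:.2f} below minimum {min_inlier_fraction:.2f}"
        )
    return inliers, float(frac), tf


# ---------------------------------------------------------------------------
# retrieval plan


PLATE_FORMATS = {96: ("ABCDEFGH", 12), 384: ("ABCDEFGHIJKLMNOP", 24)}


@dataclass
class RetrievalPlan:
    """Ordered stage targets with plate/well traceability."""

    table: pd.DataFrame  # read_id, stage_x, stage_y, plate, well, collision
    plate_format: int

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plate_map(self) -> pd.DataFrame:
        """Long-format plate map (plate, well, read_id) covering every well."""
        rows, ncols = PLATE_FORMATS[self.plate_format]
        assigned = {
            (r.plate, r.well): r.read_id for r in self.table.itertuples()
        }
        records = []
        for plate in sorted(self.table["plate"].unique()):
            for r in rows:
                for c in range(1, ncols + 1):
                    well = f"{r}{c}"
                    records.append(
                        {"plate": plate, "well": well,
                         "read_id": assigned.get((plate, well), "")}
                    )
        return pd.DataFrame(records)


def _boustrophedon_order(xy: np.ndarray) -> np.ndarray:
    """Deterministic near-minimal-travel ordering: y bands, alternating x."""
    n = len(xy)
    if n == 0:
        return np.array([], dtype=int)
    nbands = int(np.ceil(np.sqrt(n)))
    by_y = np.lexsort((xy[:, 0], xy[:, 1]))
    bands = np.array_split(by_y, nbands)
    order = []
    for b, idx in enumerate(bands):
        if len(idx) == 0:
            continue
        sub = idx[np.argsort(xy[idx, 0])]
        order.extend(sub if b % 2 == 0 else sub[::-1])
    return np.array(order, dtype=int)


def map_and_plan(
    index: CoordinateIndex,
    transform: SimilarityTransform,
    stitch: StitchResult | None = None,
    plate_format: int = 96,
    laser_radius: float = 3.0,
    skip_collisions: bool = False,
) -> RetrievalPlan:
    """Stage coordinates and well assignments for every indexed clone.

    Wells are assigned in plan order (A1, A2, ... row-major, spilling onto
    additional plates), so each retrieved clone's read is traceable from its
    well.  Clones with a neighbor within ``laser_radius`` pixels are flagged
    as collision risks and optionally skipped.
    """
    if plate_format not in PLATE_FORMATS:
        raise ValueError(f"plate_format must be one of {sorted(PLATE_FORMATS)}")
    if len(index) == 0:
        raise ValueError("empty coordinate index")
    ids, pixel = index.pixel_array()
    stage = transform(pixel).reshape(-1, 2)

    collision = np.zeros(len(ids), dtype=bool)
    if len(ids) > 1:
        tree = cKDTree(pixel)
        for i, j in tree.query_pairs(laser_radius):
            collision[i] = collision[j] = True

    keep = ~collision if skip_collisions else np.ones(len(ids), dtype=bool)
    sel = np.where(keep)[0]
    order = sel[_boustrophedon_order(stage[sel])]

    rows, ncols = PLATE_FORMATS[plate_format]
    capacity = len(rows) * ncols
    records = []
    for slot, i in enumerate(order):
        plate = slot // capacity + 1
        w = slot % capacity
        well = f"{rows[w // ncols]}{w % ncols + 1}"
        records.append(
            {
                "read_id": ids[i],
                "stage_x": stage[i, 0],
                "stage_y": stage[i, 1],
                "plate": plate,
                "well": well,
                "collision": bool(collision[i]),
            }
        )
    table = pd.DataFrame(
        records, columns=["read_id", "stage_x", "stage_y", "plate", "well", "collision"]
    )
    for read_id, plate, well in zip(table["read_id"], table["plate"], table["well"]):
        index.wells[read_id] = (str(plate), well)
    return RetrievalPlan(table, plate_format)
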