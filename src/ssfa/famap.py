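"""Fracture-Attention Map construction and iterative update.

The FA Map is a 3-channel per-pixel prior attached to every training image:

* two Thickness-Sensitive maps (TS Map 1 / TS Map 2), one per network branch,
  scoring thin branches higher via a multi-threshold erosion ladder over the
  Euclidean distance transform of each binarized prediction;
* one Difference-Sensitive map (DS Map) marking regions where the two branch
  predictions disagree semantically (skeleton-level mismatch), while boundary
  jitter of near-identical masks is suppressed.

During training the map for image i at epoch r is the convex blend

    A_r = (1 - k) * A_0 + k * A_hat_r

of the initial map A_0 (from a supervised single-network prediction) and the
map A_hat_r rebuilt from the current epoch's dual predictions; ``k`` in [0,1]
is the update weight (k=0 freezes the map, k=1 replaces it outright).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skeletonize

DEFAULT_LEVELS = 10          # attention levels L of the threshold ladder
DS_SUPPRESSION_RADIUS = 2.0  # px tolerance for skeleton jitter in the DS map
BINARIZE_THRESHOLD = 0.5

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _as_mask(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    return mask.astype(bool)


def skeletonize(mask) -> np.ndarray:
    """One-pixel-wide medial representation; empty in, empty out."""
    mask = _as_mask(mask)
    if not mask.any():
        return np.zeros_like(mask)
    return _skeletonize(mask).astype(bool)


@dataclass(frozen=True)
class DistanceMap:
    """Euclidean distance transform with skeleton-support extrema.

    ``pixels`` is zero exactly on background; an isolated foreground pixel has
    value 1 (distance to the nearest background pixel).  ``dmin``/``dmax`` are
    taken over skeleton pixels only, which is where tube half-width is read.
    """

    pixels: np.ndarray
    dmin: float
    dmax: float


def distance_map(mask) -> DistanceMap:
    mask = _as_mask(mask)
    if not mask.any():
        raise ValueError("distance_map of an empty mask: dmin/dmax are undefined")
    dist = ndimage.distance_transform_edt(mask)
    skel = skeletonize(mask)
    vals = dist[skel]
    return DistanceMap(dist, float(vals.min()), float(vals.max()))


def threshold_ladder(dmin: float, dmax: float, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Linear ladder t_l = dmin + l*(dmax-dmin)/L for l = 1..L."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if dmax < dmin:
        raise ValueError(f"dmax ({dmax}) < dmin ({dmin})")
    ls = np.arange(1, levels + 1, dtype=float)
    return dmin + ls * (dmax - dmin) / levels


def ts_map(pred, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Thickness-Sensitive map of a binary prediction.

    Per ladder level l the prediction is eroded by deleting pixels whose
    distance value falls below t_l and re-skeletonized; a skeleton pixel
    "fails" level l when no pixel of the eroded skeleton lies within Chebyshev
    radius 1 of it.  Each foreground pixel inherits the fail count of its
    nearest skeleton pixel, divided by L — so thin branches, which vanish at
    low thresholds and fail many levels, score close to 1 while thick trunks
    stay near 0.  Values are multiples of 1/L, zero outside the prediction.
    """
    pred = _as_mask(pred)
    out = np.zeros(pred.shape, dtype=np.float32)
    if not pred.any():
        return out
    skel = skeletonize(pred)
    if not skel.any():
        return out
    dist = ndimage.distance_transform_edt(pred)
    vals = dist[skel]
    ladder = threshold_ladder(float(vals.min()), float(vals.max()), levels)
    fails = np.zeros(pred.shape, dtype=np.int32)
    for t in ladder:
        eroded = pred & (dist >= t)
        covered = ndimage.binary_dilation(skeletonize(eroded), structure=_STRUCT8)
        fails[skel & ~covered] += 1
    # propagate skeleton fail counts to full branch width
    _, (ir, ic) = ndimage.distance_transform_edt(~skel, return_indices=True)
    out[pred] = fails[ir[pred], ic[pred]] / float(levels)
    return out


def ds_map(pred1, pred2, rho: float = DS_SUPPRESSION_RADIUS) -> np.ndarray:
    """Difference-Sensitive map of two binary predictions.

    Marks pixels of the symmetric difference whose nearest skeleton pixel is a
    *mismatch* pixel — a skeleton pixel of one prediction with no skeleton
    pixel of the other within Euclidean radius ``rho``.  Identical predictions
    (and pure 1-px boundary jitter, whose skeletons coincide) yield zero.
    """
    p1, p2 = _as_mask(pred1), _as_mask(pred2)
    if p1.shape != p2.shape:
        raise ValueError(f"shape mismatch: {p1.shape} vs {p2.shape}")
    out = np.zeros(p1.shape, dtype=np.float32)
    if np.array_equal(p1, p2):
        return out
    s1, s2 = skeletonize(p1), skeletonize(p2)
    d1 = ndimage.distance_transform_edt(~s1) if s1.any() else np.full(p1.shape, np.inf)
    d2 = ndimage.distance_transform_edt(~s2) if s2.any() else np.full(p1.shape, np.inf)
    mismatch = (s1 & (d2 > rho)) | (s2 & (d1 > rho))
    if not mismatch.any():
        return out
    union = s1 | s2
    _, (ir, ic) = ndimage.distance_transform_edt(~union, return_indices=True)
    sym = p1 ^ p2
    out[sym & mismatch[ir, ic]] = 1.0
    return out


def compose_fa_map(ts1: np.ndarray, ts2: np.ndarray, ds: np.ndarray) -> np.ndarray:
    """Stack (TS1, TS2, DS) into a (3, H, W) float map; order is fixed."""
    maps = [np.asarray(m, dtype=np.float32) for m in (ts1, ts2, ds)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape) or maps[0].ndim != 2:
        raise ValueError("TS1, TS2 and DS must share one 2-D shape")
    fa = np.stack(maps, axis=0)
    if fa.min() < 0.0 or fa.max() > 1.0:
        raise ValueError("FA map channels must lie in [0, 1]")
    return fa


def split_fa_map(fa: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fa = np.asarray(fa)
    if fa.ndim != 3 or fa.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) FA map, got {fa.shape}")
    return fa[0], fa[1], fa[2]


@dataclass
class FAState:
    """Per-image FA-map state across epochs.

    The current map is always the non-recursive blend of the *initial* map and
    the most recent rebuilt map: current = (1-k)*a0 + k*a_hat.
    """

    a0: np.ndarray
    k: float
    current: np.ndarray = field(default=None)  # type: ignore[assignment]
    last_hat: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 <= self.k <= 1.0):
            raise ValueError(f"update weight k={self.k} outside [0, 1]")
        self.a0 = np.asarray(self.a0, dtype=np.float32)
        if self.current is None:
            self.current = self.a0.copy()


def update_fa_map(state: FAState, a_hat: np.ndarray) -> np.ndarray:
    """Blend the rebuilt map into the state: (1-k)*A0 + k*A_hat."""
    a_hat = np.asarray(a_hat, dtype=np.float32)
    if a_hat.shape != state.a0.shape:
        raise ValueError("rebuilt FA map shape differs from the initial map")
    if not (0.0 <= state.k <= 1.0):
        raise ValueError(f"update weight k={state.k} outside [0, 1]")
    state.last_hat = a_hat
    state.current = (1.0 - state.k) * state.a0 + state.k * a_hat
    return state.current


def fa_map_from_predictions(p1, p2, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Rebuild the full FA map from two binarized branch predictions."""
    return compose_fa_map(ts_map(p1, levels), ts_map(p2, levels), ds_map(p1, p2))


def init_fa_maps(predictor, images, levels: int = DEFAULT_LEVELS) -> list[np.ndarray]:
    """Initial maps A0 from a single supervised predictor.

    With only one prediction available, TS1 = TS2 and the DS channel is zero;
    disagreement information appears from the first dual-prediction update.
    """
    if not getattr(predictor, "trained", False):
        raise ValueError("init_fa_maps requires a trained predictor")
    maps = []
    for img in images:
        pred = predictor.predict_mask(np.asarray(img, dtype=np.float32),
                                      threshold=BINARIZE_THRESHOLD)
        ts = ts_map(pred, levels)
        maps.append(compose_fa_map(ts, ts, np.zeros_like(ts)))
    return maps
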