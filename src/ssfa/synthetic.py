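"""Synthetic tubular phantoms with known centerline topology.

Phantoms emulate the essential structure of thin branching biological tubes
(vessels, endoplasmic reticulum, membranes): random branching centerline
trees swept with discs of smoothly varying radius, rendered into a noisy
grayscale image with optional low-contrast "ambiguity" regions.  Because the
planted centerlines are known, ground-truth topology (branch/edge counts) is
known by construction, which makes the Fracture Rate metric testable exactly:
:func:`inject_fractures` cuts clean gaps into chosen branches without touching
any other structure.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` instances; regeneration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk

from .metrics import DEFAULT_DELTA, TopoGraph, mask_to_graph

BACKGROUND_LEVEL = 0.15
FOREGROUND_LEVEL = 0.85
MIN_BRANCH_STEPS = 15
SPAWN_MARGIN = 8  # steps kept clear of branch ends and other spawn points


class PlacementError(RuntimeError):
    """Raised when the requested trees cannot be placed in the given canvas."""


@dataclass(frozen=True)
class Branch:
    """One centerline segment between junctions/endpoints."""

    points: np.ndarray  # (n, 2) float (row, col)
    radii: np.ndarray   # (n,) float, >= 1 px everywhere


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray          # 2-D float grayscale in [0, 1]
    mask: np.ndarray           # 2-D bool, union of swept discs
    planted_graph: list[Branch]
    seed: int


@dataclass(frozen=True)
class DefectSpec:
    """Controlled defects layered onto a phantom."""

    n_fractures: int = 0
    gap_px: int = 15
    ambiguity_regions: tuple = ()  # ((row, col), radius, contrast factor)


def _rasterize(branches: list[Branch], shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for br in branches:
        for (r, c), rad in zip(br.points, br.radii):
            rr, cc = disk((r, c), float(rad) + 0.5, shape=shape)
            mask[rr, cc] = True
    return mask


def _grow_branch(rng, start, theta, n_steps, r_start, r_end, size,
                 occupancy_dist, clearance_skip):
    """Random-walk one branch with bounded curvature and a tapering radius.

    Stops early at the canvas margin or when running into already-drawn
    structure (occupancy_dist gives the distance to foreground of *other*
    branches; the first ``clearance_skip`` steps are exempt so children can
    leave their parent tube).
    """
    pts, radii = [], []
    pos = np.asarray(start, dtype=float)
    amp = 0.25 * r_start
    period = rng.uniform(18.0, 40.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    margin = max(r_start, r_end) + 2.0
    for t in range(n_steps):
        frac = t / max(n_steps - 1, 1)
        rad = r_start + (r_end - r_start) * frac + amp * np.sin(
            2 * np.pi * t / period + phase)
        rad = max(rad, 1.0)
        if not (margin <= pos[0] < size - margin and
                margin <= pos[1] < size - margin):
            break
        if t >= clearance_skip and occupancy_dist is not None:
            ir, ic = int(round(pos[0])), int(round(pos[1]))
            if occupancy_dist[ir, ic] < rad + 3.0:
                break
        pts.append(pos.copy())
        radii.append(rad)
        theta += rng.normal(0.0, 0.08)
        pos = pos + np.array([np.sin(theta), np.cos(theta)])
    if not pts:
        return None
    return np.asarray(pts), np.asarray(radii), theta


def _grow_tree(rng, size, radius_range, occupancy: np.ndarray,
               branch_prob: float = 0.05) -> list[Branch] | None:
    """Grow one tree: a trunk plus probabilistic child branches, then split
    every polyline at its spawn points so each returned Branch is a
    junction-to-junction/endpoint segment of the planted topology."""
    rmin, rmax = radius_range
    occ_dist = (ndimage.distance_transform_edt(~occupancy)
                if occupancy.any() else None)
    for _ in range(80):
        start = rng.uniform(rmax + 3, size - rmax - 3, size=2)
        ir, ic = int(start[0]), int(start[1])
        if occ_dist is not None and occ_dist[ir, ic] < 1.5 * rmax + 5:
            continue
        theta = rng.uniform(0.0, 2 * np.pi)
        r0 = rng.uniform(0.6 * rmax + 0.4 * rmin, rmax)
        r1 = rng.uniform(rmin, 0.5 * (rmin + rmax))
        n_steps = int(rng.integers(int(0.45 * size), int(0.85 * size)))
        trunk = _grow_branch(rng, start, theta, n_steps, r0, r1, size,
                             occ_dist, clearance_skip=0)
        min_trunk = max(MIN_BRANCH_STEPS + 5, int(0.3 * size))
        if trunk is None or trunk[0].shape[0] < min_trunk:
            continue
        segments: list[Branch] = []
        # children spawn off the trunk only (depth 1): keeps planted topology
        # simple and junction degree 3
        pts, radii = trunk[0], trunk[1]
        # keep spawn points clear of the trunk ends: the skeleton retracts by
        # about one tube radius there, and a planted end segment must survive
        # spur pruning
        start_margin = int(radii[0]) + SPAWN_MARGIN + 2
        end_margin = int(radii[-1]) + SPAWN_MARGIN + 2
        spawn_at = []
        last = -pts.shape[0]
        for t in range(start_margin, pts.shape[0] - end_margin):
            # junction clusters in the skeleton span about one tube diameter;
            # spawn points closer than that would merge into one node
            if t - last < max(SPAWN_MARGIN, int(2 * radii[t]) + 4):
                continue
            if rng.random() < branch_prob:
                spawn_at.append(t)
                last = t
        kept_spawns = []
        tree_occ = occupancy | _rasterize([Branch(pts, radii)], occupancy.shape)
        for t in spawn_at:
            occ_dist_t = ndimage.distance_transform_edt(~tree_occ)
            side = 1.0 if rng.random() < 0.5 else -1.0
            d = pts[t + 1] - pts[t]
            theta_c = np.arctan2(d[0], d[1]) + side * rng.uniform(0.6, 1.1)
            rc0 = max(0.75 * radii[t], rmin)
            rc1 = rng.uniform(rmin, max(0.8 * rc0, rmin + 1e-6))
            n_c = int(rng.integers(MIN_BRANCH_STEPS + 5, int(0.5 * size)))
            child = _grow_branch(rng, pts[t], theta_c, n_c, rc0, rc1, size,
                                 occ_dist_t, clearance_skip=int(radii[t] + rc0 + 4))
            if child is None or child[0].shape[0] < MIN_BRANCH_STEPS:
                continue
            branch = Branch(child[0], child[1])
            segments.append(branch)
            kept_spawns.append(t)
            tree_occ |= _rasterize([branch], occupancy.shape)
        # split the trunk at surviving spawn points
        cuts = [0] + kept_spawns + [pts.shape[0] - 1]
        ok = True
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a < SPAWN_MARGIN:
                ok = False
        if not ok:
            continue
        for a, b in zip(cuts[:-1], cuts[1:]):
            segments.append(Branch(pts[a:b + 1], radii[a:b + 1]))
        return segments
    return None


def generate_phantom(seed: int, size: int = 128, n_trees: int = 3,
                     radius_range: tuple[float, float] = (2.0, 6.0),
                     noise_sd: float = 0.05, n_ambiguity: int = 2) -> Phantom:
    """Generate one tubular phantom.

    The image is a smoothed rendering of the mask at fixed fore/background
    levels, with ``n_ambiguity`` random low-contrast discs (contrast scaled by
    a factor in [0.2, 0.6] without touching the mask) and additive Gaussian
    noise of standard deviation ``noise_sd``, clipped to [0, 1].
    """
    if size < 64:
        raise PlacementError(f"size {size} too small; need >= 64")
    if radius_range[0] < 1.0:
        raise ValueError("minimum radius must be >= 1 px")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))
    shape = (size, size)
    branches: list[Branch] = []
    occupancy = np.zeros(shape, dtype=bool)
    for _ in range(n_trees):
        tree = _grow_tree(rng, size, radius_range, occupancy)
        if tree is None:
            raise PlacementError(
                f"could not place {n_trees} trees of radius {radius_range} "
                f"on a {size}x{size} canvas (seed {seed})")
        branches.extend(tree)
        occupancy |= _rasterize(tree, shape)
    mask = _rasterize(branches, shape)

    img = BACKGROUND_LEVEL + (FOREGROUND_LEVEL - BACKGROUND_LEVEL) * mask
    img = ndimage.gaussian_filter(img, sigma=1.0)
    for _ in range(n_ambiguity):
        cen = rng.uniform(0, size, size=2)
        rad = rng.uniform(0.08 * size, 0.18 * size)
        fac = rng.uniform(0.2, 0.6)
        rr, cc = disk(tuple(cen), rad, shape=shape)
        img[rr, cc] = BACKGROUND_LEVEL + (img[rr, cc] - BACKGROUND_LEVEL) * fac
    img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return Phantom(img, mask, branches, int(seed))


# ------------------------------------------------------------- defects

def eligible_edges(mask: np.ndarray, graph: TopoGraph, gap_px: int,
                   delta: int = DEFAULT_DELTA) -> list[int]:
    """Edge ids long enough to host an unambiguous gap (> gap + 2*delta) whose
    gap neighborhood stays clear of every other edge."""
    shape = mask.shape
    paths = [e.path for e in graph.edges]
    ids = []
    for i, path in enumerate(paths):
        n = path.shape[0]
        if n <= gap_px + 2 * delta:
            continue
        mid = n // 2
        seg = path[mid - gap_px // 2: mid - gap_px // 2 + gap_px]
        others = np.zeros(shape, dtype=bool)
        for j, q in enumerate(paths):
            if j != i:
                others[q[:, 0], q[:, 1]] = True
        if others.any():
            d_other = ndimage.distance_transform_edt(~others)
            if d_other[seg[:, 0], seg[:, 1]].min() <= delta + 2:
                continue
        ids.append(i)
    return ids


def inject_fractures(mask: np.ndarray, graph: TopoGraph, m: int, gap_px: int,
                     seed: int, delta: int = DEFAULT_DELTA
                     ) -> tuple[np.ndarray, list[int]]:
    """Break ``m`` graph edges with clean all-background gaps.

    Each chosen edge is interrupted by a ``gap_px``-long gap centered on the
    midpoint of its skeleton path; only pixels belonging to that edge's own
    tube are cleared, so every other edge (and its verdict under the Fracture
    Rate) is untouched.  Returns the modified mask and the broken edge ids.
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if m == 0:
        return out, []
    ok = eligible_edges(mask, graph, gap_px, delta)
    if m > len(ok):
        raise ValueError(
            f"requested {m} fractures but only {len(ok)} edges are eligible "
            f"(need path length > {gap_px + 2 * delta} px and clearance from "
            f"other edges)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF4AC]))
    chosen = sorted(rng.choice(np.asarray(ok), size=m, replace=False).tolist())
    # ownership: every foreground pixel belongs to its nearest edge path
    allp = np.zeros(mask.shape, dtype=bool)
    owner_src = np.full(mask.shape, -1, dtype=np.int32)
    for i, e in enumerate(graph.edges):
        allp[e.path[:, 0], e.path[:, 1]] = True
        owner_src[e.path[:, 0], e.path[:, 1]] = i
    _, (ir, ic) = ndimage.distance_transform_edt(~allp, return_indices=True)
    owner = owner_src[ir, ic]
    halfwidth = ndimage.distance_transform_edt(mask)
    for i in chosen:
        path = graph.edges[i].path
        n = path.shape[0]
        seg = path[n // 2 - gap_px // 2: n // 2 - gap_px // 2 + gap_px]
        clear = np.zeros(mask.shape, dtype=bool)
        for r, c in seg:
            rad = halfwidth[r, c] + 1.5
            rr, cc = disk((int(r), int(c)), rad, shape=mask.shape)
            clear[rr, cc] = True
        out &= ~(clear & (owner == i))
    return out, chosen


def apply_defects(phantom: Phantom, spec: DefectSpec, seed: int
                  ) -> tuple[np.ndarray, np.ndarray, list[int], TopoGraph]:
    """Apply a DefectSpec to a phantom.

    Fractures are cut into the mask; ambiguity regions reduce local image
    contrast (mask untouched).  Returns (image, mask, broken ids, G_Y).
    """
    gy = mask_to_graph(phantom.mask)
    broken_mask, ids = inject_fractures(phantom.mask, gy, spec.n_fractures,
                                        spec.gap_px, seed)
    img = phantom.image.copy()
    for center, radius, factor in spec.ambiguity_regions:
        rr, cc = disk(tuple(center), float(radius), shape=img.shape)
        img[rr, cc] = BACKGROUND_LEVEL + (img[rr, cc] - BACKGROUND_LEVEL) * factor
    return np.clip(img, 0.0, 1.0), broken_mask, ids, gy


# ------------------------------------------------------------- datasets

#: Desk-scale phantom conditions: 64x64 canvas, two trees of radius 1.5-4 px,
#: 5% Gaussian intensity noise.  Used by the shipped CPU training profile.
DESK_PHANTOM = dict(size=64, n_trees=2, radius_range=(1.5, 4.0), noise_sd=0.05)


def desk_dataset(seed: int, n_labeled: int = 8, n_unlabeled: int = 32,
                 n_test: int = 8) -> dict:
    """In-memory desk-scale dataset: standard split 8 labeled / 32 unlabeled /
    8 test of 64x64 phantoms.  Returns phantom lists keyed by role."""
    ss = np.random.SeedSequence(int(seed))
    child = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_labeled + n_unlabeled + n_test)]
    out, i = {}, 0
    for role, n in (("labeled", n_labeled), ("unlabeled", n_unlabeled),
                    ("test", n_test)):
        out[role] = [generate_phantom(child[i + j], **DESK_PHANTOM)
                     for j in range(n)]
        i += n
    return out

def make_dataset(out_dir, n_labeled: int, n_unlabeled: int, n_test: int,
                 seed: int, size: int = 128, n_trees: int = 3,
                 radius_range: tuple[float, float] = (2.0, 6.0),
                 noise_sd: float = 0.05, fmt: str = "png") -> dict:
    """Write a labeled/unlabeled/test phantom dataset and its manifest.

    Layout: ``<out>/<role>/img_<i>.png`` plus ``mask_<i>.png`` for labeled and
    test entries (masks stored as 0/255 PNG); ``manifest.json`` records roles,
    per-image seeds and generator parameters.  Same arguments => identical
    files.
    """
    from . import workbench

    out_dir = Path(out_dir)
    roles = [("labeled", n_labeled, True), ("unlabeled", n_unlabeled, False),
             ("test", n_test, True)]
    manifest = {
        "seed": int(seed),
        "params": {"size": size, "n_trees": n_trees,
                   "radius_range": list(radius_range), "noise_sd": noise_sd},
        "roles": {},
    }
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_labeled + n_unlabeled + n_test)]
    idx = 0
    for role, count, with_mask in roles:
        role_dir = out_dir / role
        role_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for i in range(count):
            ph = generate_phantom(child_seeds[idx], size=size, n_trees=n_trees,
                                  radius_range=radius_range, noise_sd=noise_sd)
            img_name = f"img_{i:03d}.{fmt}"
            workbench.write_image(ph.image, role_dir / img_name)
            entry = {"image": f"{role}/{img_name}", "seed": child_seeds[idx]}
            if with_mask:
                mask_name = f"mask_{i:03d}.png"
                workbench.write_mask(ph.mask, role_dir / mask_name)
                entry["mask"] = f"{role}/{mask_name}"
            entries.append(entry)
            idx += 1
        manifest["roles"][role] = entries
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
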