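"""Topology metrics: graph extraction, Fracture Rate (with brute-force oracle),
clDice, Betti errors, volumetric scores."""

import numpy as np
import pytest
from skimage.draw import disk, line

from ssfa.metrics import (betti_errors, betti_numbers, cl_dice, fracture_rate,
                          mask_to_graph, middle_segment, skeleton_to_graph,
                          volumetric_metrics)
from ssfa.synthetic import generate_phantom, inject_fractures


def tube_cross(shape=(64, 64), r=3):
    """A plus-shaped mask of two thick bars."""
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0, r1, c1) in [(shape[0] // 2, 4, shape[0] // 2, shape[1] - 4),
                             (4, shape[1] // 2, shape[0] - 4, shape[1] // 2)]:
        rr, cc = line(r0, c0, r1, c1)
        for a, b in zip(rr, cc):
            d, e = disk((a, b), r, shape=shape)
            mask[d, e] = True
    return mask


class TestSkeletonToGraph:
    def test_straight_line(self):
        sk = np.zeros((32, 64), bool)
        sk[16, 5:60] = True
        g = skeleton_to_graph(sk)
        assert len(g.nodes) == 2 and g.n_edges == 1
        assert all(n.kind == "endpoint" for n in g.nodes.values())
        path = g.edges[0].path
        assert tuple(path[0]) in [n.coord for n in g.nodes.values()]
        assert tuple(path[-1]) in [n.coord for n in g.nodes.values()]

    def test_cross_has_four_edges_one_junction(self):
        sk = np.zeros((41, 41), bool)
        sk[20, 5:36] = True
        sk[5:36, 20] = True
        g = skeleton_to_graph(sk)
        kinds = sorted(n.kind for n in g.nodes.values())
        assert g.n_edges == 4
        assert kinds == ["endpoint"] * 4 + ["junction"]

    def test_empty_skeleton(self):
        g = skeleton_to_graph(np.zeros((8, 8), bool))
        assert len(g.nodes) == 0 and g.n_edges == 0

    def test_isolated_cycle_becomes_self_loop(self):
        m = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 20)
        m[rr, cc] = True
        rr, cc = disk((32, 32), 12)
        m[rr, cc] = False
        g = mask_to_graph(m)
        assert g.n_edges == 1
        e = g.edges[0]
        assert e.a == e.b

    def test_edge_paths_are_8_connected(self, phantom128):
        g = mask_to_graph(phantom128.mask)
        for e in g.edges:
            steps = np.abs(np.diff(e.path, axis=0)).max(axis=1)
            assert (steps == 1).all()

    def test_spurs_are_pruned(self):
        sk = np.zeros((32, 64), bool)
        sk[16, 5:60] = True
        sk[13:16, 30] = True  # 3-px spur off the line
        g = skeleton_to_graph(sk)
        assert g.n_edges == 1


class TestFractureRate:
    def test_perfect_prediction_zero(self):
        m = tube_cross()
        rep = fracture_rate(m, m)
        assert rep.fracture_rate == 0.0
        assert rep.n_edges == 4

    def test_empty_prediction_hundred(self, phantom128):
        rep = fracture_rate(np.zeros_like(phantom128.mask), phantom128.mask)
        assert rep.fracture_rate == 100.0
        assert rep.n_fractured == rep.n_edges

    def test_translation_within_delta_zero(self):
        m = tube_cross()
        pred = np.roll(m, 3, axis=1)
        assert fracture_rate(pred, m, delta=5).fracture_rate == 0.0

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError, match="topology"):
            fracture_rate(np.zeros((8, 8), bool), np.zeros((8, 8), bool))

    def test_injected_fraction_exact(self, phantom128):
        gy = mask_to_graph(phantom128.mask)
        broken, ids = inject_fractures(phantom128.mask, gy, 1, 15, seed=3)
        rep = fracture_rate(broken, phantom128.mask, delta=5)
        assert rep.fracture_rate == pytest.approx(100.0 / gy.n_edges)
        assert set(rep.fractured_edge_ids) == set(ids)

    def test_monotone_in_broken_edges(self, phantom128):
        gy = mask_to_graph(phantom128.mask)
        prev = -1.0
        for m in range(0, 3):
            broken, _ = inject_fractures(phantom128.mask, gy, m, 15, seed=5)
            fr = fracture_rate(broken, phantom128.mask).fracture_rate
            assert fr >= prev
            prev = fr

    def test_monotone_nonincreasing_in_delta(self, phantom128):
        gy = mask_to_graph(phantom128.mask)
        broken, _ = inject_fractures(phantom128.mask, gy, 1, 15, seed=5)
        frs = [fracture_rate(broken, phantom128.mask, delta=d).fracture_rate
               for d in (2, 4, 6, 8)]
        assert all(a >= b for a, b in zip(frs, frs[1:]))


def brute_force_verdicts(pred, truth, delta=5):
    """Independent oracle: all-pairs scan from every middle-path pixel of the
    truth graph to every prediction-skeleton pixel."""
    gy = mask_to_graph(truth)
    sp = mask_to_graph(pred).skeleton_pixels(pred.shape)
    sp_pts = np.argwhere(sp)
    verdicts = []
    for e in gy.edges:
        mid = middle_segment(e.path, delta)
        frac = False
        for px in mid:
            if sp_pts.size == 0:
                frac = True
                break
            dmin = np.sqrt(((sp_pts - px) ** 2).sum(axis=1)).min()
            if dmin > delta:
                frac = True
                break
        verdicts.append(frac)
    return verdicts


def test_fracture_verdicts_match_brute_force_oracle():
    """Fast distance-transform implementation agrees edge-by-edge with the
    brute-force scan on small phantoms with injected defects."""
    for seed in range(1, 6):
        ph = generate_phantom(seed, 64, 2, (1.5, 4), 0.05)
        gy = mask_to_graph(ph.mask)
        n_elig = len([e for e in gy.edges if e.path.shape[0] > 25])
        broken, _ = inject_fractures(ph.mask, gy, min(1, n_elig), 15, seed=seed)
        rep = fracture_rate(broken, ph.mask, delta=5)
        fast = [i in rep.fractured_edge_ids for i in range(rep.n_edges)]
        assert fast == brute_force_verdicts(broken, ph.mask, delta=5)


class TestClDice:
    def test_perfect_match(self, phantom128):
        assert cl_dice(phantom128.mask, phantom128.mask) == 1.0

    def test_disjoint_masks_zero(self):
        p = np.zeros((32, 32), bool)
        y = np.zeros((32, 32), bool)
        p[5:10, 5:10] = True
        y[20:25, 20:25] = True
        assert cl_dice(p, y) == 0.0

    def test_half_ribbon_two_thirds(self, ribbon):
        y = ribbon(rows=(30, 37), cols=(5, 105))
        p = ribbon(rows=(30, 37), cols=(5, 55))
        val = cl_dice(p, y)
        assert val == pytest.approx(2 / 3, abs=0.05)

    def test_both_empty_one_single_empty_zero(self):
        z = np.zeros((8, 8), bool)
        m = ~z
        assert cl_dice(z, z) == 1.0
        assert cl_dice(z, m) == 0.0 and cl_dice(m, z) == 0.0


class TestBetti:
    def test_identical_masks_no_error(self, phantom128):
        assert betti_errors(phantom128.mask, phantom128.mask) == (0, 0, 0)

    def test_component_count_error(self):
        y = np.zeros((32, 32), bool)
        y[5:25, 5:25] = True
        p = y.copy()
        p[:, 14:16] = False  # split into two components
        assert betti_errors(p, y) == (1, 1, 0)

    def test_broken_ring_loses_one_hole(self):
        m = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 20)
        m[rr, cc] = True
        rr, cc = disk((32, 32), 12)
        m[rr, cc] = False
        assert betti_numbers(m) == (1, 1)
        opened = m.copy()
        opened[:22, 30:34] = False  # cut the annulus once
        assert betti_numbers(opened) == (1, 0)
        assert betti_errors(opened, m) == (1, 0, 1)


class TestVolumetric:
    def test_perfect(self, phantom128):
        assert volumetric_metrics(phantom128.mask, phantom128.mask) == (1, 1, 1)

    def test_disjoint(self):
        p = np.zeros((16, 16), bool)
        y = np.zeros((16, 16), bool)
        p[0:4, 0:4] = True
        y[8:12, 8:12] = True
        acc, dice, jac = volumetric_metrics(p, y)
        assert dice == 0.0 and jac == 0.0

    def test_closed_form_half_overlap(self):
        p = np.zeros((20, 20), bool)
        y = np.zeros((20, 20), bool)
        p.flat[:100] = True
        y.flat[50:150] = True
        acc, dice, jac = volumetric_metrics(p, y)
        assert dice == pytest.approx(0.5)
        assert jac == pytest.approx(1 / 3)

    def test_jaccard_never_exceeds_dice_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random((24, 24)) > rng.uniform(0.3, 0.9)
            y = rng.random((24, 24)) > rng.uniform(0.3, 0.9)
            acc, dice, jac = volumetric_metrics(p, y)
            b, b0, b1 = betti_errors(p, y)
            assert jac <= dice + 1e-12
            assert b == b0 + b1

    def test_both_empty_defined_as_one(self):
        z = np.zeros((8, 8), bool)
        assert volumetric_metrics(z, z)[1:] == (1.0, 1.0)


def test_cldice_and_dice_one_iff_identical(phantom64):
    m = phantom64.mask
    assert cl_dice(m, m) == 1.0 and volumetric_metrics(m, m)[1] == 1.0
    shifted = np.roll(m, 1, axis=0)
    assert volumetric_metrics(shifted, m)[1] < 1.0
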