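"""CIC criteria: containment, circularity, crescent imprint, pairing rules."""

import math

import numpy as np
import pytest
from skimage import draw

from cicquant.cic_detection import (CicParams, circularity, containment_fraction,
                                    crescent_score, detect_cic)
from cicquant.pipeline import analyze_scene, score_detection
from cicquant.segmentation import extract_objects
from cicquant.synthetic_data import SceneSpec, generate_coincubation_scene

from oracles import (containment_bruteforce, random_blob,
                     solidity_deficit_bruteforce)


def obj_from_mask(mask, label=1, cls="dead"):
    objs = extract_objects(np.asarray(mask, dtype=np.int32), cls)
    return next(o for o in objs if o.id == label)


def rect_obj(shape, r0, r1, c0, c1, cls="dead"):
    mask = np.zeros(shape, dtype=np.int32)
    mask[r0:r1, c0:c1] = 1
    return obj_from_mask(mask, cls=cls)


def disk_obj(shape, center, radius, cls="dead"):
    mask = np.zeros(shape, dtype=np.int32)
    rr, cc = draw.disk(center, radius, shape=shape)
    mask[rr, cc] = 1
    return obj_from_mask(mask, cls=cls)


class TestContainment:
    def test_subset_is_one(self):
        host = disk_obj((60, 60), (30, 30), 20, cls="viable")
        dead = disk_obj((60, 60), (30, 30), 8)
        assert containment_fraction(dead, host) == 1.0

    def test_disjoint_is_zero(self):
        host = rect_obj((40, 80), 5, 15, 5, 15, cls="viable")
        dead = rect_obj((40, 80), 25, 35, 60, 70)
        assert containment_fraction(dead, host) == 0.0

    def test_half_shifted_square(self):
        host = rect_obj((30, 30), 10, 18, 10, 18, cls="viable")  # 8x8
        dead = rect_obj((30, 30), 10, 18, 14, 22)  # shifted right by 4
        assert containment_fraction(dead, host) == 0.5

    def test_empty_dead_object_raises(self):
        host = rect_obj((10, 10), 2, 8, 2, 8, cls="viable")
        dead = replace_pixel_count_zero(host)
        with pytest.raises(ValueError):
            containment_fraction(dead, host)

    def test_matches_bruteforce_on_random_shapes(self, rng):
        # >= 20 random blob pairs vs plain-Python set arithmetic
        for _ in range(25):
            a = random_blob(rng)
            b = np.roll(random_blob(rng), (int(rng.integers(-8, 9)),
                                           int(rng.integers(-8, 9))), axis=(0, 1))
            dead = obj_from_mask(a.astype(np.int32))
            host = obj_from_mask(b.astype(np.int32), cls="viable")
            expected = containment_bruteforce(
                set(map(tuple, np.argwhere(a))), set(map(tuple, np.argwhere(b))))
            assert containment_fraction(dead, host) == pytest.approx(expected, abs=1e-12)


def replace_pixel_count_zero(obj):
    from dataclasses import replace as dc_replace

    return dc_replace(obj, pixel_count=0, coords=obj.coords[:0])


class TestCircularity:
    def test_rasterized_disk_is_nearly_circular(self):
        obj = disk_obj((64, 64), (32, 32), 20)
        assert circularity(obj) >= 0.9

    def test_thin_bar_is_elongated(self):
        obj = rect_obj((5, 40), 2, 3, 5, 35)  # 1x30 bar
        assert circularity(obj) < 0.35

    def test_single_pixel_defined_and_capped(self):
        obj = rect_obj((5, 5), 2, 3, 2, 3)
        c = circularity(obj)
        assert math.isfinite(c) and c <= 1.0

    def test_empty_object_raises(self):
        obj = replace_pixel_count_zero(rect_obj((5, 5), 1, 3, 1, 3))
        with pytest.raises(ValueError):
            circularity(obj)


def bitten_nucleus(radius=12, bite_depth=0.5, bite_radius=None, size=50):
    """Disk nucleus with a circular bite of the given depth (fraction of radius)."""
    bite_radius = bite_radius if bite_radius is not None else radius
    mask = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw.disk((size // 2, size // 2), radius, shape=mask.shape)
    mask[rr, cc] = 1
    dist = radius + bite_radius - bite_depth * radius
    rr, cc = draw.disk((size // 2, size // 2 + dist), bite_radius, shape=mask.shape)
    mask[rr, cc] = 0
    return mask


class TestCrescentScore:
    def test_convex_nucleus_scores_zero(self):
        nucleus = disk_obj((40, 40), (20, 20), 10, cls="nucleus")
        assert crescent_score(nucleus) == pytest.approx(0.0, abs=0.01)

    def test_half_radius_bite_matches_hull_enumeration(self):
        mask = bitten_nucleus(radius=12, bite_depth=0.5, bite_radius=6)
        obj = obj_from_mask(mask, cls="nucleus")
        expected = solidity_deficit_bruteforce(mask == 1)
        assert crescent_score(obj) == pytest.approx(expected, abs=0.02)
        assert crescent_score(obj) > 0

    def test_score_increases_with_bite_depth(self):
        scores = []
        for depth in (0.2, 0.4, 0.6):
            obj = obj_from_mask(bitten_nucleus(radius=12, bite_depth=depth),
                                cls="nucleus")
            scores.append(crescent_score(obj))
            # same monotonicity holds for the independent oracle
        assert scores[0] < scores[1] < scores[2]
        oracle = [solidity_deficit_bruteforce(bitten_nucleus(radius=12, bite_depth=d) == 1)
                  for d in (0.2, 0.4, 0.6)]
        assert oracle[0] < oracle[1] < oracle[2]

    def test_matches_bruteforce_on_random_shapes(self, rng):
        for _ in range(20):
            mask = random_blob(rng)
            obj = obj_from_mask(mask.astype(np.int32), cls="nucleus")
            expected = solidity_deficit_bruteforce(mask)
            assert crescent_score(obj) == pytest.approx(expected, abs=0.02)


class TestDetectCic:
    def _analyze(self, spec):
        stack, truth = generate_coincubation_scene(spec)
        return analyze_scene(stack), truth

    def test_planted_pairs_recovered_exactly(self, clean_scene):
        spec, stack, truth = clean_scene
        analysis = analyze_scene(stack)
        tp, fp, fn = score_detection(analysis, truth)
        assert (tp, fp, fn) == (len(truth.pairs), 0, 0)

    def test_half_contained_dead_cell_rejected(self):
        # dead cell straddling the host boundary: containment ~0.5 < 0.90
        shape = (80, 80)
        host = disk_obj(shape, (40, 30), 20, cls="viable")
        dead = disk_obj(shape, (40, 50), 8)
        nucleus = disk_obj(shape, (40, 25), 8, cls="nucleus")
        host.nucleus_id = 1
        events = detect_cic([host], [dead], [nucleus],
                            CicParams(require_crescent=False))
        assert len(events) == 1
        assert not events[0].accepted
        assert 0.3 < events[0].containment_fraction < 0.7

    def test_nested_hosts_resolved_to_higher_containment(self):
        # dead disk overlaps two hosts; full containment in host 2 wins
        shape = (100, 160)
        m = np.zeros(shape, dtype=np.int32)
        rr, cc = draw.disk((50, 50), 25, shape=shape)
        m[rr, cc] = 1
        rr, cc = draw.disk((50, 95), 25, shape=shape)
        m[rr, cc] = 2
        hosts = extract_objects(m, "viable")
        dead = disk_obj(shape, (50, 90), 8)
        # brute force: containment in each candidate host
        conts = {h.id: containment_fraction(dead, h) for h in hosts}
        assert conts[2] > conts[1]
        events = detect_cic(hosts, [dead], [], CicParams(require_crescent=False))
        accepted = [e for e in events if e.accepted]
        assert len(accepted) == 1 and accepted[0].host_id == 2

    def test_lowering_containment_threshold_never_loses_events(self):
        spec = SceneSpec(seed=21)
        stack, _ = generate_coincubation_scene(spec)
        counts = []
        for cmin in (0.95, 0.90, 0.70, 0.50):
            analysis = analyze_scene(stack, cic_params=CicParams(containment_min=cmin))
            counts.append(sum(e.accepted for e in analysis.events))
        assert counts == sorted(counts)

    def test_no_double_assignment_and_thresholds_hold(self):
        params = CicParams()
        for seed in range(5):
            spec = SceneSpec(seed=seed)
            stack, _ = generate_coincubation_scene(spec)
            analysis = analyze_scene(stack, cic_params=params)
            accepted = [e for e in analysis.events if e.accepted]
            dead_ids = [e.engulfed_id for e in accepted]
            assert len(dead_ids) == len(set(dead_ids))
            for e in accepted:
                assert e.containment_fraction >= params.containment_min
                assert e.circularity >= params.circularity_min
                assert e.crescent_score >= params.crescent_min

    def test_missing_nucleus_rejects_when_crescent_required(self):
        shape = (60, 60)
        host = disk_obj(shape, (30, 30), 20, cls="viable")  # nucleus_id None
        dead = disk_obj(shape, (30, 30), 8)
        events = detect_cic([host], [dead], [], CicParams())
        assert not events[0].accepted
        assert "nucleus" in events[0].reject_reason
        # without the crescent requirement the same pair is accepted
        events = detect_cic([host], [dead], [], CicParams(require_crescent=False))
        assert events[0].accepted
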