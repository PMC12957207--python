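import numpy as np
import pytest

from kennelmot.core import BoundingBox, Track, TrackEntry, ValidationError
from kennelmot.mot import (
    compute_clear_mot,
    compute_id_metrics,
    coverage_bands,
    evaluate_tracks,
    frame_match,
    reid_confusion,
)

import _reference_mot as ref
from conftest import make_box


def fb(*items):
    """FrameBoxes literal: fb(("A", 0, 0), ...) -> {id: ("cam0", box)}."""
    return {ident: ("cam0", make_box(x, y, 10, 10)) for ident, x, y in items}


def linear_tracks(idents, n, speed=4.0, y_gap=50.0, camera="cam0", start=0):
    tracks = []
    for k, ident in enumerate(idents):
        tr = Track(ident)
        for t in range(start, start + n):
            tr.append(
                TrackEntry(t, camera, make_box(10 + speed * t, 10 + y_gap * k, 20, 20),
                           "observed")
            )
        tracks.append(tr)
    return tracks


def frames_of(tracks):
    out = {}
    for tr in tracks:
        for e in tr.entries:
            out.setdefault(e.frame, {})[tr.identity] = (e.camera_id, e.box)
    return out


class TestFrameMatch:
    def test_identical_sets_match_perfectly(self):
        gt = fb(("A", 0, 0), ("B", 100, 0))
        assert frame_match(gt, gt) == {"A": "A", "B": "B"}

    def test_disjoint_sets_no_match(self):
        assert frame_match(fb(("A", 0, 0)), fb(("P", 500, 500))) == {}

    def test_best_iou_wins_other_is_false_positive(self):
        gt = {"A": ("cam0", make_box(0, 0, 10, 10))}
        pred = {
            "p_good": ("cam0", make_box(0, 0, 10, 8)),   # IoU 0.8
            "p_worse": ("cam0", make_box(0, 0, 10, 6)),  # IoU 0.6
        }
        assert frame_match(gt, pred) == {"A": "p_good"}

    def test_cross_camera_never_matches(self):
        gt = {"A": ("cam0", make_box(0, 0, 10, 10))}
        pred = {"A": ("cam1", make_box(0, 0, 10, 10))}
        assert frame_match(gt, pred) == {}


class TestClearMot:
    def test_two_missed_frames(self):
        gt = linear_tracks(["A"], 10)
        pred = [Track("P")]
        for e in gt[0].entries:
            if e.frame not in (3, 7):
                pred[0].append(e)
        res = compute_clear_mot(frames_of(gt), frames_of(pred))
        assert res["misses"] == 2
        assert res["false_positives"] == 0
        assert res["id_switches"] == 0
        assert res["mota"] == pytest.approx(0.8)

    def test_perfect_tracking(self):
        gt = linear_tracks(["A", "B"], 20)
        res = compute_clear_mot(frames_of(gt), frames_of(gt))
        assert res["mota"] == 1.0
        assert res["misses"] == res["false_positives"] == res["id_switches"] == 0

    def test_miss_fp_switch_combination(self):
        gt = linear_tracks(["A"], 10)
        gtf = frames_of(gt)
        predf = {}
        for t, boxes in gtf.items():
            if t == 4:
                continue  # one miss
            ident = "P1" if t < 7 else "P2"  # one switch at t=7
            predf[t] = {ident: boxes["A"]}
        predf[2]["FP"] = ("cam0", make_box(700, 700, 10, 10))  # one false positive
        res = compute_clear_mot(gtf, predf)
        assert (res["misses"], res["false_positives"], res["id_switches"]) == (1, 1, 1)
        assert res["mota"] == pytest.approx(0.7)
        assert res["fragmentations"] == 1  # the miss interrupts a matched run

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValidationError):
            compute_clear_mot({}, {})

    def test_removing_k_matched_frames_costs_k_over_total(self):
        gt = linear_tracks(["A", "B"], 25)
        total = 50
        for k in (1, 5, 10):
            pred = []
            for tr in gt:
                p = Track(tr.identity)
                for e in tr.entries:
                    if not (tr.identity == "A" and e.frame < k):
                        p.append(e)
                pred.append(p)
            res = compute_clear_mot(frames_of(gt), frames_of(pred))
            assert res["mota"] == pytest.approx(1.0 - k / total)


class TestIdMetrics:
    def test_perfect(self):
        gt = linear_tracks(["A", "B"], 15)
        res = compute_id_metrics(frames_of(gt), frames_of(gt))
        assert res["idf1"] == res["idp"] == res["idr"] == 1.0

    def test_six_of_ten_frames_correct_identity(self):
        """10-frame GT track; predictions carry the right identity for 6
        frames and a different one for 4: IDTP=6 -> IDF1=IDP=IDR=0.6."""
        gt = linear_tracks(["A"], 10)
        gtf = frames_of(gt)
        predf = {
            t: {("A" if t < 6 else "Z"): boxes["A"]} for t, boxes in gtf.items()
        }
        res = compute_id_metrics(gtf, predf)
        assert res["idf1"] == pytest.approx(12 / 20)
        assert res["idp"] == pytest.approx(0.6)
        assert res["idr"] == pytest.approx(0.6)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValidationError):
            compute_id_metrics({}, {0: fb(("P", 0, 0))})

    def test_idf1_is_harmonic_mean_of_idp_idr(self, rng):
        for seed in range(5):
            gtf, predf = _random_scenario(np.random.default_rng(seed), n_frames=60)
            res = compute_id_metrics(gtf, predf)
            if res["idp"] + res["idr"] > 0:
                hm = 2 * res["idp"] * res["idr"] / (res["idp"] + res["idr"])
                assert res["idf1"] == pytest.approx(hm, abs=1e-12)


class TestCoverageBands:
    @pytest.mark.parametrize(
        "coverage, band",
        [(0.85, "mostly_tracked"), (0.10, "mostly_lost"), (0.5, "partially_tracked"),
         (0.8, "partially_tracked"), (0.2, "partially_tracked")],
    )
    def test_band_boundaries(self, coverage, band):
        n = 20
        gt = linear_tracks(["A"], n)
        gtf = frames_of(gt)
        matched = int(round(coverage * n))
        corr = {t: ({"A": "P"} if t < matched else {}) for t in range(n)}
        res = coverage_bands(gtf, corr)
        assert res[band] == 1
        assert res["mostly_tracked"] + res["partially_tracked"] + res["mostly_lost"] == 1


class TestReidConfusion:
    def test_perfect_assignment_is_identity_matrix(self):
        gt = linear_tracks(["A", "B"], 10)
        conf = reid_confusion(frames_of(gt), frames_of(gt))
        assert conf["A"]["A"] == 100.0 and conf["A"]["B"] == 0.0
        assert conf["B"]["B"] == 100.0

    def test_never_assigned_identity_gives_zero_row(self):
        gt = linear_tracks(["A", "B"], 10)
        pred = [t for t in gt if t.identity == "A"]
        conf = reid_confusion(frames_of(gt), frames_of(pred))
        assert conf["B"] == {"A": 0.0}

    def test_double_ids_push_row_past_100(self):
        """Correct ID on 95 of 100 frames plus a duplicate second ID on 10
        frames: the row sums to 105%."""
        gt = linear_tracks(["A"], 100)
        gtf = frames_of(gt)
        predf = {}
        for t, boxes in gtf.items():
            predf[t] = {}
            if t < 95:
                predf[t]["A"] = boxes["A"]
            if t < 10:
                cam, b = boxes["A"]
                predf[t]["B"] = (cam, make_box(b.x + 1, b.y, b.width, b.height))
        conf = reid_confusion(gtf, predf)
        assert conf["A"]["A"] == pytest.approx(95.0)
        assert conf["A"]["B"] == pytest.approx(10.0)
        assert sum(conf["A"].values()) == pytest.approx(105.0)


def _random_scenario(rng, n_frames=60, n_animals=3, arena=400.0):
    """Random drifting gt boxes; predictions = perturbed/dropped/relabelled.

    Per-animal box sizes differ so exact IoU ties (which would make the
    optimal matching genuinely ambiguous) cannot occur even when clipping
    piles animals onto the same arena corner.
    """
    pos = rng.uniform(50, arena, size=(n_animals, 2))
    vel = rng.uniform(-4, 4, size=(n_animals, 2))
    sizes = [(40.0 + 3 * i, 30.0 + 2 * i) for i in range(n_animals)]
    gtf, predf = {}, {}
    names = [f"G{i}" for i in range(n_animals)]
    pred_names = [f"P{i}" for i in range(n_animals)]
    for t in range(n_frames):
        pos = np.clip(pos + vel, 20, arena + 80)
        gtf[t] = {}
        predf[t] = {}
        for i in range(n_animals):
            box = make_box(pos[i, 0], pos[i, 1], *sizes[i])
            gtf[t][names[i]] = ("cam0", box)
            if rng.uniform() < 0.12:
                continue  # missed
            j = i
            if rng.uniform() < 0.08:
                j = int(rng.integers(n_animals))  # identity error
            predf[t].setdefault(
                pred_names[j],
                ("cam0", make_box(pos[i, 0] + rng.normal(0, 2),
                                  pos[i, 1] + rng.normal(0, 2), *sizes[i])),
            )
        if rng.uniform() < 0.05:
            predf[t]["FP"] = ("cam0", make_box(rng.uniform(0, arena),
                                               rng.uniform(0, arena), 40, 30))
    return gtf, predf


class TestAgainstReferenceImplementation:
    def test_metrics_match_brute_force_reference(self):
        """CLEAR counts, MOTA, identity metrics and bands agree with an
        independently-coded enumeration-based reference on randomized
        scenarios."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            gtf, predf = _random_scenario(rng, n_frames=80)
            mine = compute_clear_mot(gtf, predf)
            theirs = ref.reference_clear(gtf, predf)
            for key in ("misses", "false_positives", "id_switches", "fragmentations"):
                assert mine[key] == theirs[key], (seed, key)
            assert mine["mota"] == pytest.approx(theirs["mota"], abs=1e-9)
            mine_id = compute_id_metrics(gtf, predf)
            theirs_id = ref.reference_id_metrics(gtf, predf)
            for key in ("idf1", "idp", "idr"):
                assert mine_id[key] == pytest.approx(theirs_id[key], abs=1e-9)
            bands = coverage_bands(gtf, mine["correspondences"])
            ref_bands = ref.reference_bands(gtf, theirs["correspondences"])
            for key in ("mostly_tracked", "partially_tracked", "mostly_lost"):
                assert bands[key] == ref_bands[key]


class TestEvaluateTracks:
    def test_report_fields_consistent(self):
        gt = linear_tracks(["A", "B"], 30)
        rep = evaluate_tracks(gt, gt)
        assert rep.mota == 1.0 and rep.idf1 == 1.0
        assert rep.mostly_tracked == 2 and rep.mostly_lost == 0
        assert rep.num_gt_boxes == 60

    def test_filled_entries_excluded_by_default(self):
        gt = linear_tracks(["A"], 10)
        pred = [Track("A")]
        for e in gt[0].entries:
            source = "filled" if e.frame >= 5 else "observed"
            pred[0].append(TrackEntry(e.frame, e.camera_id, e.box, source))
        rep = evaluate_tracks(gt, pred)
        assert rep.misses == 5
        rep_incl = evaluate_tracks(gt, pred, include_filled=True)
        assert rep_incl.misses == 0
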