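"""Independent brute-force reference for the tracking-evaluation metrics.

Deliberately kept algorithmically disjoint from the package: box overlap
is recomputed from corner coordinates, per-frame correspondences are
found by exhaustive enumeration of injective maps (no assignment
solver), and the trajectory matching behind the identity metrics is a
plain search over permutations.  Only usable at small scale, which is
all an oracle needs.
"""

from __future__ import annotations

from itertools import permutations


def box_overlap(a, b) -> float:
    ax1, ay1, ax2, ay2 = a.x, a.y, a.x + a.width, a.y + a.height
    bx1, by1, bx2, by2 = b.x, b.y, b.x + b.width, b.y + b.height
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def pair_iou(gt_entry, pred_entry) -> float:
    (gcam, gbox), (pcam, pbox) = gt_entry, pred_entry
    return box_overlap(gbox, pbox) if gcam == pcam else 0.0


def _enumerate_matchings(g_free, p_free, valid):
    """Yield every injective gt->pred map using only valid pairs."""
    if not g_free:
        yield {}
        return
    g = g_free[0]
    rest = g_free[1:]
    for sub in _enumerate_matchings(rest, p_free, valid):
        yield sub  # g unmatched
    for p in p_free:
        if (g, p) in valid:
            remaining = [q for q in p_free if q != p]
            for sub in _enumerate_matchings(rest, remaining, valid):
                yield {g: p, **sub}


def match_frame(gt, pred, thr, persistent):
    """Persistence + exhaustive (count, total IoU)-maximal valid matching."""
    matches = {}
    for g, p in (persistent or {}).items():
        if g in gt and p in pred and pair_iou(gt[g], pred[p]) >= thr:
            matches[g] = p
    g_free = [g for g in gt if g not in matches]
    p_free = [p for p in pred if p not in matches.values()]
    valid = {
        (g, p): pair_iou(gt[g], pred[p])
        for g in g_free
        for p in p_free
        if pair_iou(gt[g], pred[p]) >= thr
    }
    best, best_key = {}, (-1, -1.0)
    for cand in _enumerate_matchings(g_free, p_free, valid):
        key = (len(cand), sum(valid[(g, p)] for g, p in cand.items()))
        if key > best_key:
            best, best_key = cand, key
    matches.update(best)
    return matches


def reference_clear(gt_frames, pred_frames, thr=0.5):
    misses = fp = switches = frag = 0
    num_gt = sum(len(v) for v in gt_frames.values())
    last_pred, prev_matched, in_gap = {}, {}, {}
    persistent = {}
    correspondences = {}
    for frame in sorted(set(gt_frames) | set(pred_frames)):
        gt = gt_frames.get(frame, {})
        pred = pred_frames.get(frame, {})
        matches = match_frame(gt, pred, thr, persistent)
        correspondences[frame] = matches
        misses += len(gt) - len(matches)
        fp += len(pred) - len(matches)
        for g in gt:
            if g in matches:
                if g in last_pred and last_pred[g] != matches[g]:
                    switches += 1
                if in_gap.get(g):
                    frag += 1
                last_pred[g] = matches[g]
                in_gap[g] = False
            elif prev_matched.get(g) or in_gap.get(g):
                in_gap[g] = True
            prev_matched[g] = g in matches
        persistent = matches
    return {
        "mota": 1.0 - (misses + fp + switches) / num_gt,
        "misses": misses,
        "false_positives": fp,
        "id_switches": switches,
        "fragmentations": frag,
        "correspondences": correspondences,
    }


def reference_id_metrics(gt_frames, pred_frames, thr=0.5):
    gt_ids = sorted({g for v in gt_frames.values() for g in v})
    pr_ids = sorted({p for v in pred_frames.values() for p in v})
    overlap = {(g, p): 0 for g in gt_ids for p in pr_ids}
    for frame, gt in gt_frames.items():
        pred = pred_frames.get(frame, {})
        for g in gt:
            for p in pred:
                if pair_iou(gt[g], pred[p]) >= thr:
                    overlap[(g, p)] += 1
    best = 0
    if gt_ids and pr_ids:
        if len(gt_ids) <= len(pr_ids):
            for perm in permutations(pr_ids, len(gt_ids)):
                best = max(best, sum(overlap[(g, p)] for g, p in zip(gt_ids, perm)))
        else:
            for perm in permutations(gt_ids, len(pr_ids)):
                best = max(best, sum(overlap[(g, p)] for g, p in zip(perm, pr_ids)))
    total_gt = sum(len(v) for v in gt_frames.values())
    total_pred = sum(len(v) for v in pred_frames.values())
    idtp = best
    idfp = total_pred - idtp
    idfn = total_gt - idtp
    return {
        "idp": idtp / (idtp + idfp) if total_pred else 0.0,
        "idr": idtp / (idtp + idfn),
        "idf1": 2 * idtp / (2 * idtp + idfp + idfn),
    }


def reference_bands(gt_frames, correspondences):
    life, hit = {}, {}
    for frame, gt in gt_frames.items():
        for g in gt:
            life[g] = life.get(g, 0) + 1
            if g in correspondences.get(frame, {}):
                hit[g] = hit.get(g, 0) + 1
    mt = sum(1 for g in life if hit.get(g, 0) / life[g] > 0.8)
    ml = sum(1 for g in life if hit.get(g, 0) / life[g] < 0.2)
    return {"mostly_tracked": mt, "mostly_lost": ml,
            "partially_tracked": len(life) - mt - ml}
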