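"""Independent brute-force reference evaluator used as the test oracle.

Deliberately naive: explicit python pixel sets for IoU, literal greedy
matching loops, and direct transcription of the precision/recall, interpolated
precision, AP and FNR formulas.  Shares nothing with the package's evaluator
beyond the mask rasterization input format.
"""

import numpy as np

THRESHOLDS = [0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95]


def pixel_set(inst, rec):
    m = inst.rasterize(rec.width_px, rec.height_px)
    return {(int(r), int(c)) for r, c in zip(*np.nonzero(m))}


def iou_table(gt_sets, pred_sets):
    table = [[0.0] * len(gt_sets) for _ in pred_sets]
    for i, p in enumerate(pred_sets):
        for j, g in enumerate(gt_sets):
            inter = len(p & g)
            union = len(p | g)
            table[i][j] = inter / union if union else 0.0
    return table


def greedy_match(table, t):
    """Per prediction row (already score-ordered): claimed gt index or -1."""
    n_pred = len(table)
    n_gt = len(table[0]) if n_pred else 0
    taken = [False] * n_gt
    assign = []
    for i in range(n_pred):
        best_j, best = -1, t
        for j in range(n_gt):
            if not taken[j] and table[i][j] >= t and (best_j == -1 or table[i][j] > best):
                best_j, best = j, table[i][j]
        if best_j >= 0:
            taken[best_j] = True
        assign.append(best_j)
    return assign


def reference_evaluate(gt, preds, cap=3000):
    """Overall AP, per-threshold AP and AFNR by literal formula evaluation."""
    per_image = []
    n_gt_total = 0
    for image_id, rec in gt.images.items():
        g_sets = [pixel_set(m, rec) for m in gt.instances.get(image_id, [])]
        p = preds.instances.get(image_id, [])
        order = sorted(range(len(p)), key=lambda i: (-p[i].score, i))[:cap]
        p_sets = [pixel_set(p[i], rec) for i in order]
        scores = [p[i].score for i in order]
        per_image.append((iou_table(g_sets, p_sets), scores, len(g_sets)))
        n_gt_total += len(g_sets)

    ap_per_t, fnr_per_t = {}, {}
    for t in THRESHOLDS:
        flagged = []  # (score, order_index, is_tp) in image-then-rank order
        tp_total = 0
        for table, scores, _ in per_image:
            assign = greedy_match(table, t)
            for i, j in enumerate(assign):
                flagged.append((scores[i], len(flagged), j >= 0))
                if j >= 0:
                    tp_total += 1
        flagged.sort(key=lambda x: (-x[0], x[1]))  # global score order, stable
        tp = fp = 0
        recalls, precisions = [], []
        for _, _, is_tp in flagged:
            tp += is_tp
            fp += not is_tp
            precisions.append(tp / (tp + fp))
            recalls.append(tp / n_gt_total)
        # p_interp(r) = max precision at recall >= r
        p_interp = precisions[:]
        for i in range(len(p_interp) - 2, -1, -1):
            p_interp[i] = max(p_interp[i], p_interp[i + 1])
        ap = 0.0
        prev_r = 0.0
        for r, p_i in zip(recalls, p_interp):
            ap += (r - prev_r) * p_i
            prev_r = r
        ap_per_t[t] = ap
        fnr_per_t[t] = 1.0 - (tp_total / n_gt_total if n_gt_total else 0.0)
    overall = sum(ap_per_t.values()) / len(THRESHOLDS)
    afnr_val = sum(fnr_per_t.values()) / len(THRESHOLDS)
    return {"overall_ap": overall, "ap_per_threshold": ap_per_t,
            "fnr_per_threshold": fnr_per_t, "afnr": afnr_val}
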