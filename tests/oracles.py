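"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over the definitions, kept
deliberately separate from the library's vectorized/third-party-backed
code paths so the two can disagree.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# detection metrics

def box_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter) if inter > 0 else 0.0


def greedy_match(dets, gts, thr):
    """dets: list of (box, conf) in caller order. Returns list of TP flags in
    descending-confidence order plus matched gt count."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    taken = set()
    flags = []
    for i in order:
        best_j, best = None, 0.0
        for j, g in enumerate(gts):
            if j in taken:
                continue
            v = box_iou(dets[i][0], g)
            if v > best:
                best_j, best = j, v
        if best_j is not None and best >= thr:
            taken.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags, len(taken)


def average_precision(dets, gts, thr) -> float:
    """All-points interpolated AP, built point by point."""
    if not dets:
        return 0.0
    flags, _ = greedy_match(dets, gts, thr)
    points = []  # (recall, precision) after each ranked detection
    tp = fp = 0
    for is_tp in flags:
        tp += int(is_tp)
        fp += int(not is_tp)
        points.append((tp / len(gts), tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        if r > prev_r:
            p_right = max(p for (rr, p) in points if rr >= r)
            ap += (r - prev_r) * p_right
            prev_r = r
    return ap


def f1_at(dets, gts, thr) -> float:
    flags, n_matched = greedy_match(dets, gts, thr)
    tp = sum(flags)
    fp = len(flags) - tp
    fn = len(gts) - n_matched
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def mean_ap(dets, gts) -> float:
    thrs = [0.50 + 0.05 * k for k in range(10)]
    return sum(average_precision(dets, gts, t) for t in thrs) / len(thrs)


# ---------------------------------------------------------------------------
# texture

def glcm_pair_counts(q: np.ndarray, levels: int, dy: int, dx: int) -> np.ndarray:
    """Symmetric normalized co-occurrence by explicit pair enumeration."""
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                counts[q[y, x], q[y2, x2]] += 1
                counts[q[y2, x2], q[y, x]] += 1
    total = counts.sum()
    return counts / total if total else counts


def lbp_code(gray: np.ndarray, y: int, x: int) -> int:
    """Strictly-greater comparison, circular order E, NE, N, NW, W, SW, S, SE."""
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    code = 0
    for k, (dy, dx) in enumerate(offsets):
        if gray[y + dy, x + dx] > gray[y, x]:
            code |= 1 << k
    return code


def lbp_histogram(gray: np.ndarray) -> np.ndarray:
    """59-bin uniform histogram: uniform codes in ascending order, then one
    catch-all bin."""
    def transitions(code):
        bits = [(code >> k) & 1 for k in range(8)]
        return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))

    uniform_codes = [c for c in range(256) if transitions(c) <= 2]
    hist = np.zeros(len(uniform_codes) + 1)
    h, w = gray.shape
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            c = lbp_code(gray, y, x)
            if transitions(c) <= 2:
                hist[uniform_codes.index(c)] += 1
            else:
                hist[-1] += 1
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# classification

def auc_concordance(probs, labels) -> float:
    """All-pairs concordance count (ties count half)."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = len(pos) * len(neg)
    score = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                score += 1.0
            elif p == n:
                score += 0.5
    return score / total
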