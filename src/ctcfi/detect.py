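"""Polyp detection components: focal loss, curvature-blob baseline, metrics.

The focal loss FL = -w (1 - p_t)^gamma log(p_t) (with p_t = p for positive
ground truth and 1-p otherwise) is the training objective used for
detector networks under heavy class imbalance; it is provided here as a
tested, standalone component.  Detection itself uses a classical baseline
over fused filet images: connected regions of decoded curvature above a
cutoff become detections, scored by their mean normalized curvature.
Evaluation offers the per-patient counting rule (a patient with any polyp
and any detection is a single true positive regardless of how many of its
polyps were found), per-polyp recall, and precision-recall curves over
box matches at an IoU threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filet import FiletImage

_P_CLAMP = 1e-7


@dataclass
class FocalLossParams:
    gamma: float = 2.0
    class_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.class_weight <= 0:
            raise ValueError("class_weight must be positive")


def focal_loss(p, y, params: FocalLossParams | None = None):
    """FL = -w (1 - p_t)^gamma log(p_t); reduces to cross-entropy at gamma=0.

    ``p`` is the predicted probability of the positive class, clamped to
    [1e-7, 1 - 1e-7]; ``y`` the 0/1 ground truth.  Vectorized.
    """
    params = params or FocalLossParams()
    p = np.clip(np.asarray(p, dtype=np.float64), _P_CLAMP, 1.0 - _P_CLAMP)
    y = np.asarray(y)
    p_t = np.where(y == 1, p, 1.0 - p)
    out = -params.class_weight * (1.0 - p_t) ** params.gamma * np.log(p_t)
    return out if out.ndim else float(out)


@dataclass
class Detection:
    """One detected blob in a filet frame."""

    box: tuple[int, int, int, int]      # x, y, w, h pixels
    score: float
    frame_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    def to_json_dict(self) -> dict:
        return {"image_id": self.frame_id, "category": "polyp",
                "bbox": list(self.box), "score": self.score}


def wrap_box_from_pixels(rows: np.ndarray, cols: np.ndarray, width: int) -> tuple:
    """Tight xywh box of a pixel set on a cylindrical (azimuth-wrapping) image.

    When the set crosses the wrap seam, the box is the complement of the
    largest empty azimuth gap: x is in [0, width) and the box spans columns
    (x + i) mod width for i < w.
    """
    y0 = int(rows.min())
    h = int(rows.max()) - y0 + 1
    present = np.zeros(width, dtype=bool)
    present[cols] = True
    if present.all():
        return (0, y0, width, h)
    if present[0] and present[-1]:
        empty = np.flatnonzero(~present)
        runs = np.split(empty, np.where(np.diff(empty) != 1)[0] + 1)
        longest = max(runs, key=len)
        x = int(longest[-1]) + 1
        return (x % width, y0, width - len(longest), h)
    x0 = int(cols.min())
    return (x0, y0, int(cols.max()) - x0 + 1, h)


def _wrapped_components(binary: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected components of a binary image whose columns wrap around."""
    from skimage.measure import label

    lab = label(binary, connectivity=2)
    parent: dict[int, int] = {}

    def find(a):
        while parent.get(a, a) != a:
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    seam = binary[:, 0] & binary[:, -1]
    for r in np.flatnonzero(seam):
        union(int(lab[r, 0]), int(lab[r, -1]))
    groups: dict[int, list[int]] = {}
    for lid in range(1, lab.max() + 1):
        groups.setdefault(find(lid), []).append(lid)
    out = []
    for members in groups.values():
        mask = np.isin(lab, members)
        rows, cols = np.nonzero(mask)
        out.append((rows, cols))
    return out


def detect_blobs(filet: FiletImage, min_radius_px: float = 3.0,
                 curvature_cutoff: float = 0.15, frame_id: int = 0) -> list[Detection]:
    """Curvature-blob baseline detector on a fused filet image.

    Pixels whose decoded curvature exceeds ``curvature_cutoff`` (1/mm) are
    grouped into connected regions (the azimuth axis wraps, so blobs across
    the 0/360 seam stay whole); regions with equivalent radius at least
    ``min_radius_px`` become detections scored by mean normalized curvature.
    The colon wall seen from inside is concave (negative curvature), so
    only protruding structure survives the cutoff.
    """
    if filet.curvature_range is None:
        raise ValueError("filet has no fused curvature channel")
    from .surface import rgb_to_curvature

    curv = rgb_to_curvature(filet.rgb, filet.curvature_range)
    curv[filet.cell_map < 0] = 0.0
    binary = curv > curvature_cutoff
    width = binary.shape[1]
    detections = []
    for rows, cols in _wrapped_components(binary):
        if np.sqrt(len(rows) / np.pi) < min_radius_px:
            continue
        box = wrap_box_from_pixels(rows, cols, width)
        score = float(np.clip(curv[rows, cols].mean() / filet.curvature_range, 0, 1))
        detections.append(Detection(box=box, score=score, frame_id=frame_id))
    return detections


@dataclass
class PatientEval:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)

    def to_json_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "f1": self.f1}


def evaluate_per_patient(cases: list[tuple[bool, bool]],
                         healthy_detection_counts_as_fn: bool = False) -> PatientEval:
    """Per-patient counting: one (has_polyps, any_detection) pair per patient.

    A diseased patient with any detection is one TP no matter how many of
    their polyps were found.  A detection in a healthy patient counts as a
    false positive by default; the literal alternative reading (count it
    as a false negative) is available but leaves specificity degenerate.
    """
    if not cases:
        raise ValueError("empty case list")
    tp = fp = tn = fn = 0
    for has_polyps, detected in cases:
        if has_polyps and detected:
            tp += 1
        elif has_polyps and not detected:
            fn += 1
        elif not has_polyps and not detected:
            tn += 1
        elif healthy_detection_counts_as_fn:
            fn += 1
        else:
            fp += 1
    return PatientEval(tp=tp, fp=fp, tn=tn, fn=fn)


def box_iou(a: tuple, b: tuple, wrap_width: int | None = None) -> float:
    """IoU of two xywh pixel boxes.

    With ``wrap_width`` set, the x axis is treated as circular with that
    period (filet azimuth), so boxes crossing the 0/360 seam overlap
    correctly.
    """
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    iy0, iy1 = max(ay, by), min(ay + ah, by + bh)
    row_inter = max(0, iy1 - iy0)
    if wrap_width is None:
        ix0, ix1 = max(ax, bx), min(ax + aw, bx + bw)
        col_inter = max(0, ix1 - ix0)
    else:
        cols_a = np.zeros(wrap_width, dtype=bool)
        cols_a[np.arange(ax, ax + aw) % wrap_width] = True
        cols_b = np.zeros(wrap_width, dtype=bool)
        cols_b[np.arange(bx, bx + bw) % wrap_width] = True
        col_inter = int((cols_a & cols_b).sum())
    inter = row_inter * col_inter
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def match_detections(detections: list[Detection], truth_boxes: list[tuple],
                     match_iou: float = 0.3,
                     wrap_width: int | None = None) -> tuple[list[int | None], np.ndarray]:
    """Greedy score-descending matching; each truth box matched at most once.

    Returns (matched truth index or None per detection, matched flags per
    truth box).
    """
    order = np.argsort([-d.score for d in detections], kind="stable")
    taken = np.zeros(len(truth_boxes), dtype=bool)
    assignment: list[int | None] = [None] * len(detections)
    for di in order:
        best, best_iou = None, match_iou
        for ti, tb in enumerate(truth_boxes):
            if taken[ti]:
                continue
            v = box_iou(detections[di].box, tb, wrap_width)
            if v >= best_iou:
                best, best_iou = ti, v
        if best is not None:
            taken[best] = True
            assignment[di] = best
    return assignment, taken


@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    area: float


def precision_recall(detections: list[Detection], truth_boxes: list[tuple],
                     match_iou: float = 0.3,
                     wrap_width: int | None = None) -> PRCurve:
    """Threshold sweep over detection scores with greedy box matching.

    Area under the curve by trapezoid over recall.  Raises when there are
    no truth boxes (recall undefined).
    """
    if not truth_boxes:
        raise ValueError("no truth boxes: recall is undefined")
    if not 0 < match_iou < 1:
        raise ValueError("match_iou must be in (0, 1)")
    n_truth = len(truth_boxes)
    if not detections:
        return PRCurve(np.array([1.0]), np.array([0.0]), np.array([]), 0.0)
    assignment, _ = match_detections(detections, truth_boxes, match_iou,
                                     wrap_width=wrap_width)
    scores = np.array([d.score for d in detections])
    is_tp = np.array([a is not None for a in assignment])
    thresholds = np.unique(scores)[::-1]
    prec, rec = [], []
    for th in thresholds:
        keep = scores >= th
        tp = int(np.sum(is_tp & keep))
        fp = int(np.sum(~is_tp & keep))
        prec.append(tp / (tp + fp) if tp + fp else 1.0)
        rec.append(tp / n_truth)
    prec, rec = np.array(prec), np.array(rec)
    # anchor at recall 0 with the first precision
    r = np.concatenate([[0.0], rec])
    p = np.concatenate([[prec[0]], prec])
    area = float(np.trapezoid(p, r))
    return PRCurve(precision=prec, recall=rec, thresholds=thresholds, area=area)
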