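"""Training, prediction and evaluation for the segmentation network.

The protocol mirrors common practice for single-stage instance segmenters:
SGD with momentum under a cosine-annealed learning rate, task-aligned
dynamic label assignment, and a composite loss

    L = lambda_box * (1 - IoU)  +  lambda_dfl * DFL  +
        lambda_cls * BCE(class logits, soft targets)  +
        lambda_mask * BCE(assembled masks, truth masks at 1/4 resolution)

where DFL is the distribution-focal term for the discretized box sides and
the mask term is cropped to each instance's box and normalized by box area.
No data augmentation is applied.

Prediction decodes the box distributions by expectation, filters by class
confidence, applies greedy NMS and assembles masks from the prototype map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom as nd_zoom

from . import nn
from .errors import ConfigError
from .metrics import Detection, evaluate
from .orchard import OrchardSceneSpec, generate_scene

__all__ = [
    "TrainConfig", "composite_loss", "train_loop", "predict",
    "evaluate_model", "eigencam", "make_training_scenes", "summarize_repeats",
]


def summarize_repeats(values):
    """Mean +/- half-range over repeated runs (e.g. seeds 42/43/44).

    Returns ``(mean, half_range)`` — the convention used when a metric is
    reported as ``m ± e`` over n=3 independent runs.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    return float(v.mean()), float((v.max() - v.min()) / 2)


@dataclass
class TrainConfig:
    """Optimization protocol (defaults follow the reference protocol)."""

    epochs: int = 200
    batch_size: int = 8
    lr0: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: int = 3
    patience: int = 50
    seed: int = 42
    image_size: int = 640
    mask_ratio: int = 4
    augment: bool = False
    repeats: int = 3
    lambda_box: float = 7.5
    lambda_cls: float = 0.5
    lambda_dfl: float = 1.5
    lambda_mask: float = 2.5

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.image_size, self.mask_ratio) <= 0:
            raise ValueError("config values must be positive")
        if self.lr0 <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# assignment and loss
# ---------------------------------------------------------------------------


def _grid_anchors(shapes, strides):
    """Anchor centers (pixels) and per-anchor stride, flattened over scales."""
    pts, strd = [], []
    for (h, w), s in zip(shapes, strides):
        ys, xs = np.mgrid[0:h, 0:w]
        pts.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1))
        strd.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(strd)


def _decode_np(box_logits, anchors, strides, reg_max):
    """Expectation decode of (A, 4, R) logits to xyxy pixel boxes (NumPy)."""
    z = box_logits - box_logits.max(axis=2, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=2, keepdims=True)
    dist = (p * np.arange(reg_max)).sum(axis=2) * strides[:, None]  # l, t, r, b
    x1 = anchors[:, 0] - dist[:, 0]
    y1 = anchors[:, 1] - dist[:, 1]
    x2 = anchors[:, 0] + dist[:, 2]
    y2 = anchors[:, 1] + dist[:, 3]
    return np.stack([x1, y1, x2, y2], axis=1)


def _iou_matrix(gt_boxes, boxes):
    """(G, A) IoU between ground-truth and predicted xyxy boxes."""
    gx1, gy1, gx2, gy2 = [gt_boxes[:, i:i + 1] for i in range(4)]
    x1, y1, x2, y2 = [boxes[None, :, i] for i in range(4)]
    iw = np.minimum(gx2, x2) - np.maximum(gx1, x1)
    ih = np.minimum(gy2, y2) - np.maximum(gy1, y1)
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    ag = (gx2 - gx1) * (gy2 - gy1)
    ap = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    return inter / np.maximum(ag + ap - inter, 1e-9)


def _assign(gt_boxes, scores, pred_boxes, anchors, topk=10, alpha=0.5, beta=6.0):
    """Task-aligned assignment for one image.

    Candidates are anchors whose center lies inside a truth box; each truth
    keeps its ``topk`` candidates by the alignment metric
    ``score**alpha * IoU**beta``; every anchor goes to the truth for which
    its alignment is largest.  Returns (assigned gt index per anchor, -1 for
    background; soft class target per anchor).
    """
    a = anchors.shape[0]
    if len(gt_boxes) == 0:
        return np.full(a, -1, dtype=int), np.zeros(a)
    inside = (
        (anchors[None, :, 0] > gt_boxes[:, 0:1]) & (anchors[None, :, 0] < gt_boxes[:, 2:3])
        & (anchors[None, :, 1] > gt_boxes[:, 1:2]) & (anchors[None, :, 1] < gt_boxes[:, 3:4])
    )
    iou = _iou_matrix(gt_boxes, pred_boxes)
    align = (scores[None, :] ** alpha) * (iou ** beta) * inside
    # top-k per truth
    keep = np.zeros_like(align, dtype=bool)
    for gi in range(align.shape[0]):
        cand = np.nonzero(align[gi] > 0)[0]
        if len(cand) == 0:
            continue
        top = cand[np.argsort(-align[gi, cand], kind="stable")[:topk]]
        keep[gi, top] = True
    align = align * keep
    assigned = np.where(align.max(axis=0) > 0, align.argmax(axis=0), -1)
    # soft class targets: alignment normalized per truth, scaled by best IoU
    t = np.zeros(a)
    for gi in range(align.shape[0]):
        sel = assigned == gi
        if not sel.any():
            continue
        m = align[gi, sel].max()
        t[sel] = align[gi, sel] / max(m, 1e-9) * iou[gi, sel].max()
    return assigned, t


def _head_meta(out, reg_max):
    shapes = [s[0].shape[2:] for s in out["scales"]]
    return shapes


def _flatten_scales(out, nc, nm, reg_max):
    """Concatenate per-scale head maps into (A, ...) tensors."""
    boxes, clss, coefs = [], [], []
    for b, c, m in out["scales"]:
        n, _, h, w = b.shape
        boxes.append(b.reshape(n, 4, reg_max, h * w).transpose(0, 3, 1, 2))
        clss.append(c.reshape(n, nc, h * w).transpose(0, 2, 1))
        coefs.append(m.reshape(n, nm, h * w).transpose(0, 2, 1))
    return (nn.concat(boxes, 1), nn.concat(clss, 1), nn.concat(coefs, 1))


def composite_loss(out, targets, model_head, cfg: TrainConfig, image_size):
    """Loss over one batch.

    ``targets`` is a list (per image) of lists of :class:`InstanceRecord`.
    Returns (total loss Tensor, dict of float components).
    """
    reg_max, nc, nm = model_head.reg_max, model_head.nc, model_head.nm
    shapes = _head_meta(out, reg_max)
    strides = [image_size // h for (h, w) in shapes]
    anchors, strd = _grid_anchors(shapes, strides)
    box_t, cls_t, coef_t = _flatten_scales(out, nc, nm, reg_max)
    protos = out["protos"]  # (N, nm, Hp, Wp)
    n = box_t.shape[0]
    a = box_t.shape[1]
    hp, wp = protos.shape[2], protos.shape[3]

    cls_targets = np.zeros((n, a, nc), dtype=np.float32)
    loss_box = nn.Tensor(0.0)
    loss_dfl = nn.Tensor(0.0)
    loss_mask = nn.Tensor(0.0)
    n_pos_total = 0
    for i in range(n):
        recs = targets[i]
        gt_boxes = np.array([r.box_pixels() for r in recs], dtype=np.float64).reshape(-1, 4)
        scores = 1.0 / (1.0 + np.exp(-np.clip(cls_t.data[i, :, 0], -60, 60)))
        pred_boxes = _decode_np(box_t.data[i].astype(np.float64), anchors, strd, reg_max)
        assigned, soft = _assign(gt_boxes, scores, pred_boxes, anchors)
        pos = np.nonzero(assigned >= 0)[0]
        cls_targets[i, :, 0] = soft
        if len(pos) == 0:
            continue
        n_pos_total += len(pos)
        w_pos = soft[pos]
        w_sum = max(w_pos.sum(), 1e-9)
        gt_for = assigned[pos]
        gtb = gt_boxes[gt_for]

        # -- IoU term on decoded boxes (differentiable through softmax) ----
        logits = box_t[i][pos]                       # (P, 4, R)
        p = nn.softmax(logits, axis=2)
        bins = nn.Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, -1))
        dist = (p * bins).sum(axis=2) * nn.Tensor(strd[pos, None].astype(np.float32))
        ax = nn.Tensor(anchors[pos, 0].astype(np.float32))
        ay = nn.Tensor(anchors[pos, 1].astype(np.float32))
        px1, py1 = ax - dist[:, 0], ay - dist[:, 1]
        px2, py2 = ax + dist[:, 2], ay + dist[:, 3]
        tx1, ty1, tx2, ty2 = [nn.Tensor(gtb[:, k].astype(np.float32)) for k in range(4)]
        iw = (nn.minimum(px2, tx2) - nn.maximum(px1, tx1)).clamp_min(0)
        ih = (nn.minimum(py2, ty2) - nn.maximum(py1, ty1)).clamp_min(0)
        inter = iw * ih
        area_p = (px2 - px1).clamp_min(0) * (py2 - py1).clamp_min(0)
        area_t = (tx2 - tx1) * (ty2 - ty1)
        iou = inter / (area_p + area_t - inter + 1e-7)
        wt = nn.Tensor((w_pos / w_sum).astype(np.float32))
        loss_box = loss_box + ((1.0 - iou) * wt).sum()

        # -- distribution-focal term ---------------------------------------
        tdist = np.stack([
            anchors[pos, 0] - gtb[:, 0], anchors[pos, 1] - gtb[:, 1],
            gtb[:, 2] - anchors[pos, 0], gtb[:, 3] - anchors[pos, 1],
        ], axis=1) / strd[pos, None]
        tdist = np.clip(tdist, 0, reg_max - 1 - 1e-3)
        lo = np.floor(tdist).astype(int)
        hi = lo + 1
        w_hi = (tdist - lo).astype(np.float32)
        logp = (p + 1e-9).log()
        pi = np.arange(len(pos))[:, None].repeat(4, 1)
        side = np.arange(4)[None, :].repeat(len(pos), 0)
        ce = -(logp[pi, side, lo] * nn.Tensor(1.0 - w_hi) + logp[pi, side, hi] * nn.Tensor(w_hi))
        loss_dfl = loss_dfl + (ce.mean(axis=1) * wt).sum()

        # -- mask term: assembled prototypes vs truth at 1/4 resolution ----
        gt_small = np.stack([
            r.mask.reshape(hp, r.mask.shape[0] // hp, wp, r.mask.shape[1] // wp).mean(axis=(1, 3))
            for r in recs
        ]) > 0.5
        coef = coef_t[i][pos]                       # (P, nm)
        pflat = protos[i].reshape(nm, hp * wp)
        mlogits = nn.matmul(coef, pflat)            # (P, Hp*Wp)
        scale = hp / float(image_size * cfg.mask_ratio / cfg.mask_ratio) * 1.0
        del scale
        tmask = gt_small[gt_for].reshape(len(pos), hp * wp).astype(np.float32)
        # crop to the truth box, normalize by box area
        gx = np.arange(wp) + 0.5
        gy = np.arange(hp) + 0.5
        sx = wp / float(image_size)
        sy = hp / float(image_size)
        inbox = (
            (gx[None, None, :] > gtb[:, 0, None, None] * sx)
            & (gx[None, None, :] < gtb[:, 2, None, None] * sx)
            & (gy[None, :, None] > gtb[:, 1, None, None] * sy)
            & (gy[None, :, None] < gtb[:, 3, None, None] * sy)
        ).reshape(len(pos), hp * wp).astype(np.float32)
        areas = np.maximum(inbox.sum(axis=1), 1.0)
        z = mlogits.data
        bce = np.maximum(z, 0) - z * tmask + np.log1p(np.exp(-np.abs(z)))
        per_inst = (bce * inbox).sum(axis=1) / areas
        # route gradient through a weighted bce on logits
        gweight = (inbox / areas[:, None]) * (w_pos / w_sum)[:, None]
        loss_mask = loss_mask + _bce_weighted(mlogits, tmask, gweight)

    # classification over every anchor (soft targets)
    loss_cls = nn.bce_with_logits(cls_t, cls_targets, reduction="sum") * (1.0 / max(n_pos_total, 1))
    loss_box = loss_box * (1.0 / n)
    loss_dfl = loss_dfl * (1.0 / n)
    loss_mask = loss_mask * (1.0 / n)
    total = (cfg.lambda_box * loss_box + cfg.lambda_dfl * loss_dfl
             + cfg.lambda_cls * loss_cls + cfg.lambda_mask * loss_mask)
    comps = {
        "box": float(loss_box.data), "dfl": float(loss_dfl.data),
        "cls": float(loss_cls.data), "mask": float(loss_mask.data),
        "total": float(total.data),
    }
    return total, comps


def _bce_weighted(logits, targets, weights):
    """Sum of per-element BCE-with-logits times a constant weight matrix."""
    return nn.bce_with_logits(logits, targets, weight=weights, reduction="sum")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def make_training_scenes(n: int, image_size: int, seed: int, scenario_mix=True):
    """Generate (image CHW float32 in [0,1], records) pairs, scenario-cycled."""
    data = []
    for i in range(n):
        sc = "abcd"[i % 4] if scenario_mix else "a"
        spec = OrchardSceneSpec(height=image_size, width=image_size,
                                scenario=sc, seed=(seed * 100_003 + i) % (2**31))
        img, recs = generate_scene(spec)
        data.append((img.transpose(2, 0, 1).astype(np.float32) / 255.0, recs))
    return data


def train_loop(model, data, cfg: TrainConfig, val_data=None, log=None,
               eval_every: int = 0):
    """SGD training with cosine annealing and early stopping.

    ``data``/``val_data`` are lists of (image, records).  Returns
    ``(model, history)`` where history holds per-epoch mean losses (and val
    metrics when ``eval_every`` is set).  The best state (by val box+mask
    mAP50 mean, when evaluated) is restored at the end.
    """
    if not data:
        raise ConfigError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    opt = nn.SGD(params, cfg.lr0, cfg.momentum, cfg.weight_decay)
    nb = max(1, len(data) // cfg.batch_size)
    warmup_steps = max(1, cfg.warmup_epochs * nb)
    history = {"loss": [], "val": []}
    best = (-1.0, None)
    bad_epochs = 0
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(data))
        losses = []
        lr_epoch = nn.cosine_lr(cfg.lr0, epoch, cfg.epochs)
        for b in range(nb):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            imgs = np.stack([data[i][0] for i in idx])
            targets = [data[i][1] for i in idx]
            step += 1
            opt.lr = lr_epoch * min(1.0, step / warmup_steps)
            out = model.forward(imgs)
            loss, comps = composite_loss(out, targets, model.head, cfg, imgs.shape[-1])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(comps)
        mean_loss = {k: float(np.mean([c[k] for c in losses])) for k in losses[0]}
        history["loss"].append(mean_loss)
        if log:
            log(f"epoch {epoch + 1}/{cfg.epochs} lr {opt.lr:.4f} " +
                " ".join(f"{k} {v:.3f}" for k, v in mean_loss.items()))
        if val_data and eval_every and (epoch + 1) % eval_every == 0:
            metrics = evaluate_model(model, val_data)
            history["val"].append({"epoch": epoch + 1, **metrics})
            score = 0.5 * (metrics["box"]["map50"] + metrics["mask"]["map50"])
            if log:
                log(f"  val box mAP50 {metrics['box']['map50']:.3f} "
                    f"mask mAP50 {metrics['mask']['map50']:.3f}")
            if score > best[0]:
                best = (score, model.state_dict())
                bad_epochs = 0
            else:
                bad_epochs += eval_every
                if bad_epochs >= cfg.patience:
                    if log:
                        log(f"early stop at epoch {epoch + 1}")
                    break
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------


def _nms(boxes, scores, iou_thres=0.65):
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        iou = _iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[iou <= iou_thres]
    return keep


def _decode_batch(out, head, h_img, conf_thres, iou_thres, mask_thres, max_det):
    """Turn raw head outputs into per-image Detection lists."""
    reg_max, nc, nm = head.reg_max, head.nc, head.nm
    shapes = [s[0].shape[2:] for s in out["scales"]]
    strides = [h_img // h for (h, w) in shapes]
    anchors, strd = _grid_anchors(shapes, strides)
    box_t, cls_t, coef_t = _flatten_scales(out, nc, nm, reg_max)
    n = box_t.shape[0]
    results = []
    for bi in range(n):
        scores = 1.0 / (1.0 + np.exp(-np.clip(cls_t.data[bi, :, 0], -60, 60)))
        boxes = _decode_np(box_t.data[bi].astype(np.float64), anchors, strd, reg_max)
        sel = np.nonzero(scores >= conf_thres)[0]
        dets = []
        if len(sel):
            sel = sel[np.argsort(-scores[sel], kind="stable")[:max_det]]
            keep = _nms(boxes[sel], scores[sel], iou_thres)
            sel = sel[keep]
            protos = out["protos"].data[bi]
            nmch, hp, wp = protos.shape
            up = h_img // hp
            pflat = protos.reshape(nmch, -1)
            for i in sel:
                x1, y1, x2, y2 = np.clip(boxes[i], 0, h_img - 1e-3)
                if x2 - x1 < 1 or y2 - y1 < 1:
                    continue
                mlog = (coef_t.data[bi, i] @ pflat).reshape(hp, wp)
                m = 1.0 / (1.0 + np.exp(-np.clip(mlog, -60, 60))) > mask_thres
                full = m.repeat(up, axis=0).repeat(up, axis=1)
                crop = np.zeros_like(full)
                ix1, iy1 = int(x1), int(y1)
                ix2, iy2 = int(math.ceil(x2)), int(math.ceil(y2))
                crop[iy1:iy2, ix1:ix2] = full[iy1:iy2, ix1:ix2]
                dets.append(Detection((float(x1), float(y1), float(x2), float(y2)),
                                      float(scores[i]), 0, crop))
        results.append(dets)
    return results


def predict(model, image, conf_thres=0.25, iou_thres=0.65, mask_thres=0.5,
            max_det=300):
    """Run one image (CHW float [0,1]) through the model; returns Detections."""
    model.eval()
    h_img = image.shape[-1]
    with nn.no_grad():
        out = model.forward(image[None] if image.ndim == 3 else image)
    return _decode_batch(out, model.head, h_img, conf_thres, iou_thres,
                         mask_thres, max_det)[0]


def evaluate_model(model, data, conf_thres=0.05, batch_size=8):
    """Box and mask precision/recall/mAP50 over (image, records) pairs."""
    model.eval()
    dets_all, gts_all = [], []
    for b0 in range(0, len(data), batch_size):
        chunk = data[b0:b0 + batch_size]
        imgs = np.stack([c[0] for c in chunk])
        with nn.no_grad():
            out = model.forward(imgs)
        dets_all.extend(
            _decode_batch(out, model.head, imgs.shape[-1], conf_thres, 0.65, 0.5, 300)
        )
        gts_all.extend(c[1] for c in chunk)
    pb, rb, apb = evaluate(dets_all, gts_all, mode="box")
    pm, rm, apm = evaluate(dets_all, gts_all, mode="mask")
    return {
        "box": {"precision": pb, "recall": rb, "map50": apb},
        "mask": {"precision": pm, "recall": rm, "map50": apm},
    }


# ---------------------------------------------------------------------------
# EigenCAM
# ---------------------------------------------------------------------------


def eigencam(features: np.ndarray, out_size: tuple[int, int] | None = None):
    """Class-agnostic activation heatmap from the first principal component.

    The (C, H, W) feature map is reshaped to (H*W, C) and projected onto its
    first right-singular vector; the sign is chosen so the projection's mean
    is non-negative, negatives are clamped, and the map is min-max
    normalized and bilinearly resized to ``out_size``.  A (near-)constant
    feature map yields an all-zero heatmap.
    """
    c, h, w = features.shape
    m = features.reshape(c, h * w).T.astype(np.float64)
    _, s, vt = np.linalg.svd(m, full_matrices=False)
    proj = m @ vt[0]
    if proj.mean() < 0:
        proj = -proj
    proj = np.clip(proj, 0, None)
    rng_ = proj.max() - proj.min()
    if s[0] < 1e-12 or rng_ < 1e-12 or (s[1:].sum() < 1e-12 and np.allclose(proj, proj[0])):
        heat = np.zeros((h, w))
    else:
        heat = (proj - proj.min()) / rng_
        heat = heat.reshape(h, w)
    if np.allclose(heat, heat.flat[0]):
        heat = np.zeros((h, w))
    if out_size is not None and (h, w) != tuple(out_size):
        heat = nd_zoom(heat, (out_size[0] / h, out_size[1] / w), order=1)
        heat = np.clip(heat, 0.0, 1.0)
    return heat
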