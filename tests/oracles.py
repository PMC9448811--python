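"""Independent straight-line transcriptions of the attention equations and
other reference computations, written with explicit loops and no shared
code with the package, for use as test oracles."""

import math

import numpy as np


def conv_same_loops(fm, w):
    """Zero-padded stride-1 convolution, explicit loops. fm (H,W,C), w (k,k,C,F)."""
    H, W, C = fm.shape
    k, _, _, F = w.shape
    p = k // 2
    out = np.zeros((H, W, F))
    for y in range(H):
        for x in range(W):
            for f in range(F):
                s = 0.0
                for i in range(k):
                    for j in range(k):
                        yy, xx = y + i - p, x + j - p
                        if 0 <= yy < H and 0 <= xx < W:
                            for c in range(C):
                                s += fm[yy, xx, c] * w[i, j, c, f]
                out[y, x, f] = s
    return out


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def sk_gate_oracle(fm, bw):
    """Gate: sigmoid(FC2(relu(FC1(GAP(U3 + U5))))); returns (ma, u3, u5)."""
    H, W, C = fm.shape
    u3 = conv_same_loops(fm, bw.w3)
    u5 = conv_same_loops(fm, bw.w5)
    gap = np.zeros(C)
    for c in range(C):
        s = 0.0
        for y in range(H):
            for x in range(W):
                s += u3[y, x, c] + u5[y, x, c]
        gap[c] = s / (H * W)
    d = bw.fc1_w.shape[1]
    z = np.zeros(d)
    for j in range(d):
        s = bw.fc1_b[j]
        for c in range(C):
            s += gap[c] * bw.fc1_w[c, j]
        z[j] = max(s, 0.0)
    ma = np.zeros(C)
    for c in range(C):
        s = bw.fc2_b[c]
        for j in range(d):
            s += z[j] * bw.fc2_w[j, c]
        ma[c] = _sigmoid(s)
    return ma, u3, u5


def sk_attention_oracle(fm, bw):
    """Channel-refined map: Ma*U3 + (1-Ma)*U5, channel-wise broadcast."""
    ma, u3, u5 = sk_gate_oracle(fm, bw)
    H, W, C = fm.shape
    out = np.zeros((H, W, C))
    for y in range(H):
        for x in range(W):
            for c in range(C):
                out[y, x, c] = ma[c] * u3[y, x, c] + (1.0 - ma[c]) * u5[y, x, c]
    return out


def spatial_map_oracle(fm, w, b):
    """sigmoid(conv_k([avg-pool; max-pool] over channels)); w (k,k,2,1)."""
    H, W, C = fm.shape
    pooled = np.zeros((H, W, 2))
    for y in range(H):
        for x in range(W):
            s = 0.0
            m = -np.inf
            for c in range(C):
                v = fm[y, x, c]
                s += v
                m = max(m, v)
            pooled[y, x, 0] = s / C
            pooled[y, x, 1] = m
    conv = conv_same_loops(pooled, w)
    out = np.zeros((H, W, 1))
    for y in range(H):
        for x in range(W):
            out[y, x, 0] = _sigmoid(conv[y, x, 0] + b[0])
    return out


def mccbam_oracle(fm, ratios, branches, spatial_w, spatial_b):
    """Full block: concat of refined maps, times FM replicated, times spatial map."""
    H, W, C = fm.shape
    n = len(ratios)
    cat = np.zeros((H, W, n * C))
    for bi, r in enumerate(ratios):
        ref = sk_attention_oracle(fm, branches[r])
        for y in range(H):
            for x in range(W):
                for c in range(C):
                    cat[y, x, bi * C + c] = ref[y, x, c]
    prod = np.zeros_like(cat)
    for y in range(H):
        for x in range(W):
            for bi in range(n):
                for c in range(C):
                    prod[y, x, bi * C + c] = cat[y, x, bi * C + c] * fm[y, x, c]
    smap = spatial_map_oracle(prod, spatial_w, spatial_b)
    out = np.zeros_like(prod)
    for y in range(H):
        for x in range(W):
            for cc in range(n * C):
                out[y, x, cc] = prod[y, x, cc] * smap[y, x, 0]
    return out


# ---------------------------------------------------------------------------
# other reference computations


def dense_conv2d_oracle(img, kernel):
    """Single-channel dense 2-D cross-correlation with edge replication."""
    H, W = img.shape
    k = kernel.shape[0]
    p = k // 2
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            s = 0.0
            for i in range(k):
                for j in range(k):
                    yy = min(max(y + i - p, 0), H - 1)
                    xx = min(max(x + j - p, 0), W - 1)
                    s += img[yy, xx] * kernel[i, j]
            out[y, x] = s
    return out


def bilinear_oracle(img, out_h, out_w):
    """Closed-form bilinear resampling at half-pixel centers, edge clamp."""
    H, W = img.shape[:2]
    chans = 1 if img.ndim == 2 else img.shape[2]
    src = img.reshape(H, W, chans)
    out = np.zeros((out_h, out_w, chans))
    for y in range(out_h):
        fy = (y + 0.5) * H / out_h - 0.5
        y0 = math.floor(fy)
        ty = fy - y0
        ya, yb = min(max(y0, 0), H - 1), min(max(y0 + 1, 0), H - 1)
        for x in range(out_w):
            fx = (x + 0.5) * W / out_w - 0.5
            x0 = math.floor(fx)
            tx = fx - x0
            xa, xb = min(max(x0, 0), W - 1), min(max(x0 + 1, 0), W - 1)
            for c in range(chans):
                top = (1 - tx) * src[ya, xa, c] + tx * src[ya, xb, c]
                bot = (1 - tx) * src[yb, xa, c] + tx * src[yb, xb, c]
                out[y, x, c] = (1 - ty) * top + ty * bot
    return out if img.ndim == 3 else out[..., 0]


def confusion_tally_oracle(y_true, y_pred, labels):
    """Brute-force per-class TP/FP/FN/TN tally and the rate metrics."""
    res = {}
    n = len(y_true)
    correct = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        res[lab] = (prec, rec, f1)
    return res, correct / n if n else 0.0


def pairwise_auc_oracle(y_binary, scores):
    """Mann-Whitney AUC: fraction of positive-negative pairs correctly
    ordered, ties counted half."""
    pos = [s for yb, s in zip(y_binary, scores) if yb]
    neg = [s for yb, s in zip(y_binary, scores) if not yb]
    total = len(pos) * len(neg)
    s = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                s += 1.0
            elif p == q:
                s += 0.5
    return s / total
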