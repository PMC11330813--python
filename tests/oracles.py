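"""Independent reference computations used by the tests.

Everything here is written in the most literal way possible (explicit loops
over pixels and kernel taps, spreadsheet-style parameter arithmetic) so it
shares no code path with the package's GEMM-based implementation.
"""

from __future__ import annotations

import numpy as np


# -- direct convolution arithmetic -------------------------------------------

def direct_conv2d(x, w, b=None, dilation=1):
    """Zero-padded 'same' convolution by explicit per-pixel tap summation.

    x: (H, W, Cin), w: (k, k, Cin, Cout), b: (Cout,) or None.
    """
    h, wid, cin = x.shape
    k = w.shape[0]
    half = k // 2
    out = np.zeros((h, wid, w.shape[3]), dtype=np.float64)
    for i in range(h):
        for j in range(wid):
            acc = np.zeros(w.shape[3])
            for ki in range(k):
                for kj in range(k):
                    ii = i + (ki - half) * dilation
                    jj = j + (kj - half) * dilation
                    if 0 <= ii < h and 0 <= jj < wid:
                        for c in range(cin):
                            acc = acc + x[ii, jj, c] * w[ki, kj, c]
            out[i, j] = acc
    if b is not None:
        out = out + b
    return out


def direct_conv_transpose2x2(x, w, b=None):
    """Stride-2 2x2 transposed convolution by explicit scatter.

    x: (H, W, Cin), w: (2, 2, Cin, Cout).
    """
    h, wid, cin = x.shape
    cout = w.shape[3]
    out = np.zeros((2 * h, 2 * wid, cout), dtype=np.float64)
    for i in range(h):
        for j in range(wid):
            for di in range(2):
                for dj in range(2):
                    for c in range(cin):
                        out[2 * i + di, 2 * j + dj] += x[i, j, c] * w[di, dj, c]
    if b is not None:
        out = out + b
    return out


def batchnorm_train(x, gamma, beta, eps=1e-5):
    """Batch-statistics normalisation over (N, H, W) per channel."""
    mean = x.mean(axis=(0, 1, 2))
    var = x.var(axis=(0, 1, 2))
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def se_gains(xmean, w1, b1, w2, b2):
    """Closed-form squeeze-excitation gains for a pooled descriptor."""
    return sigmoid(relu(xmean @ w1 + b1) @ w2 + b2)


# -- confusion-count loop ------------------------------------------------------

def confusion_loop(pred, truth):
    """Exhaustive per-pixel tally; returns (tp, fp, fn, tn)."""
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


# -- spreadsheet-style parameter tallies --------------------------------------

def _conv(cin, cout, k=3, bias=True):
    return k * k * cin * cout + (cout if bias else 0)


def _bn(c):
    return 2 * c


def _block(cin, cout, residual):
    n = _conv(cin, cout) + _bn(cout) + _conv(cout, cout) + _bn(cout)
    if residual and cin != cout:
        n += _conv(cin, cout, k=1) + _bn(cout)
    return n


def _se(c, reduction=16, floor=4):
    h = max(c // reduction, min(floor, c))
    return c * h + h + h * c + c


def _cbam(c, reduction=16):
    return _se(c, reduction) + _conv(2, 1, k=7)


def _sfem(c):
    branches = 3 * (_conv(c, c) + _bn(c))
    fusions = 2 * (_conv(2 * c, 2 * c) + _bn(2 * c))
    attn = 2 * _cbam(4 * c)
    proj = _conv(9 * c, c, k=1) + _bn(c)
    return branches + fusions + attn + proj


def _mcem(widths):
    total = 0
    for c in widths:
        total += _conv(c, c) + _bn(c) + _se(c) + _conv(c, c, k=1)
    for i in range(len(widths) - 1):
        total += _conv(widths[i + 1], widths[i], k=1)          # lateral projection
        total += _conv(widths[i], widths[i]) + _bn(widths[i])  # merge conv
    return total


def _ag(c):
    inter = max(c // 2, 1)
    return (2 * (_conv(c, inter, k=1) + _bn(inter))
            + _conv(inter, 1, k=1) + _bn(1))


def param_tally(base=16, depth=4, in_channels=1, residual=False, sfem=False,
                mcem=False, ag=False):
    """Layer-by-layer arithmetic parameter count of the encoder-decoder and
    any enabled modules."""
    widths = [base * 2 ** i for i in range(depth)]
    total = 0
    cin = in_channels
    for w in widths:                                  # encoder
        total += _block(cin, w, residual)
        cin = w
    total += _block(widths[-1], 2 * widths[-1], residual)  # bottleneck
    up_in = 2 * widths[-1]
    for w in reversed(widths):                        # decoder
        total += _conv(up_in, w, k=2)                 # 2x2 transposed conv
        total += _block(2 * w, w, residual)
        up_in = w
    total += _conv(widths[0], 1, k=1)                 # output head
    if sfem:
        total += sum(_sfem(w) for w in widths)
    if mcem:
        total += _mcem(widths)
    if ag:
        total += sum(_ag(w) for w in widths)
    return total
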