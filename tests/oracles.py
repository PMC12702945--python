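"""Independent nested-loop reference implementations.

Deliberately written as explicit Python loops over output positions and
kernel taps — slow, but with no shared code or vectorisation tricks in
common with the package's einsum/stride-trick implementations, so they
serve as independent oracles on small inputs.
"""

import numpy as np


def conv2d_oracle(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    xp = np.zeros((B, Cin, H + 2 * padding, W + 2 * padding), dtype=np.float64)
    xp[:, :, padding : padding + H, padding : padding + W] = x
    Ho = (H + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    Wo = (W + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((B, Cout, Ho, Wo), dtype=np.float64)
    cpg_in = Cin // groups
    cpg_out = Cout // groups
    for n in range(B):
        for co in range(Cout):
            g = co // cpg_out
            for oi in range(Ho):
                for oj in range(Wo):
                    acc = 0.0
                    for ci in range(cpg_in):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (
                                    xp[n, g * cpg_in + ci, oi * stride + ki * dilation, oj * stride + kj * dilation]
                                    * w[co, ci, ki, kj]
                                )
                    out[n, co, oi, oj] = acc + (b[co] if b is not None else 0.0)
    return out


def conv1d_oracle(x, w, b=None, padding=0):
    B, Cin, L = x.shape
    Cout, _, k = w.shape
    xp = np.zeros((B, Cin, L + 2 * padding), dtype=np.float64)
    xp[:, :, padding : padding + L] = x
    Lo = L + 2 * padding - k + 1
    out = np.zeros((B, Cout, Lo), dtype=np.float64)
    for n in range(B):
        for co in range(Cout):
            for o in range(Lo):
                acc = 0.0
                for ci in range(Cin):
                    for t in range(k):
                        acc += xp[n, ci, o + t] * w[co, ci, t]
                out[n, co, o] = acc + (b[co] if b is not None else 0.0)
    return out


def pool2d_oracle(x, kernel, stride, mode):
    B, C, H, W = x.shape
    Ho = (H - kernel) // stride + 1
    Wo = (W - kernel) // stride + 1
    out = np.zeros((B, C, Ho, Wo), dtype=np.float64)
    for n in range(B):
        for c in range(C):
            for oi in range(Ho):
                for oj in range(Wo):
                    vals = [
                        x[n, c, oi * stride + ki, oj * stride + kj]
                        for ki in range(kernel)
                        for kj in range(kernel)
                    ]
                    out[n, c, oi, oj] = max(vals) if mode == "max" else sum(vals) / len(vals)
    return out


def mixed_pool_oracle(x, lam, kernel, stride):
    mx = pool2d_oracle(x, kernel, stride, "max")
    av = pool2d_oracle(x, kernel, stride, "avg")
    return lam * mx + (1.0 - lam) * av


def channel_attention_oracle(x, branch_weights, branch_biases):
    """Explicit-sum recomputation of multi-scale channel attention.

    Global average pool each channel, convolve the channel sequence with
    each branch's 1-D kernel (same padding), average the branches, apply
    the logistic function.
    """
    B, C, H, W = x.shape
    pooled = np.zeros((B, C))
    for n in range(B):
        for c in range(C):
            s = 0.0
            for i in range(H):
                for j in range(W):
                    s += x[n, c, i, j]
            pooled[n, c] = s / (H * W)
    acc = np.zeros((B, C))
    for w, b in zip(branch_weights, branch_biases):
        k = len(w)
        pad = (k - 1) // 2
        for n in range(B):
            for c in range(C):
                s = 0.0
                for t in range(k):
                    src = c + t - pad
                    if 0 <= src < C:
                        s += pooled[n, src] * w[t]
                acc[n, c] += s + b
    acc /= len(branch_weights)
    return 1.0 / (1.0 + np.exp(-acc))


def spatial_attention_oracle(x, w7, b7):
    """Channel mean/max maps, explicit 7x7 correlation, logistic."""
    B, C, H, W = x.shape
    avg = x.mean(axis=1)
    mx = x.max(axis=1)
    stacked = np.stack([avg, mx], axis=1)  # B x 2 x H x W
    out = conv2d_oracle(stacked, w7, np.array([b7]), stride=1, padding=3)
    return 1.0 / (1.0 + np.exp(-out))
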