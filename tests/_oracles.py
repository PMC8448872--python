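"""Independent brute-force oracles used by the test suite.

Everything here is loop-based and deliberately ignorant of the package
internals, so agreement is evidence rather than tautology.
"""

import math

import numpy as np


def speeds_by_loop(t, x, y):
    out = []
    for i in range(1, len(t)):
        d = math.hypot(x[i] - x[i - 1], y[i] - y[i - 1])
        out.append(d / (t[i] - t[i - 1]))
    return np.array(out)


def zscore(v):
    v = np.asarray(v, float)
    return (v - v.mean()) / v.std()


def naive_conv1d_same(x, w, b):
    """x: (l, cin), w: (F, cin, cout), b: (cout,); triple loop."""
    length, cin = x.shape
    F, _, cout = w.shape
    pad_l = (F - 1) // 2
    xp = np.zeros((length + F - 1, cin))
    xp[pad_l: pad_l + length] = x
    out = np.zeros((length, cout))
    for t in range(length):
        for f in range(F):
            for o in range(cout):
                out[t, o] += xp[t + f] @ w[f, :, o]
    return out + b


def attention_by_hand(Z, w_a1, w_a2):
    """Two matmuls + softmax over time; Z: (l, C)."""
    scores = (w_a2 @ np.tanh(w_a1 @ Z.T)).ravel()
    e = np.exp(scores - scores.max())
    return e / e.sum()


def bce_elementwise(p, y, eps=1e-7):
    p = min(max(p, eps), 1 - eps)
    return -(y * math.log(p) + (1 - y) * math.log(1 - p))


def mu_closed_form(i, t1, t2, L, alpha, beta):
    if i < t1:
        return 0.0
    if i >= t2:
        return L
    expo = -beta * (i - t1) / (t2 - t1)
    return (L + 1.0) / (L * alpha**expo + 1.0) - 1.0


def rolling_stat(v, w, fn):
    """Centered rolling statistic with truncated edges."""
    n = len(v)
    half = (w - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i - half + w)
        out[i] = fn(v[lo:hi])
    return out


def stochastic_superiority(x, y):
    """P(X < Y) + 0.5 P(X = Y) by exhaustive pairwise comparison."""
    total = 0.0
    for xi in x:
        for yj in y:
            if xi < yj:
                total += 1.0
            elif xi == yj:
                total += 0.5
    return total / (len(x) * len(y))


def finite_difference(f, x, h=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + h
        f1 = f(x)
        flat[i] = old - h
        f2 = f(x)
        flat[i] = old
        gf[i] = (f1 - f2) / (2 * h)
    return g
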