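"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as explicit loops (or direct matrix powers for
the Morgan recursion) with no code shared with the package, so agreement is
evidence and not tautology.
"""

from __future__ import annotations

import math

import numpy as np


# --- statistics ----------------------------------------------------------


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)))
    dy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    return num / (dx * dy)


def r2_oracle(y, yhat):
    return pearson_oracle(y, yhat) ** 2


def ols_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    c1 = sxy / sxx
    c0 = my - c1 * mx
    return c0, c1


def q2_loo_oracle(x, y):
    n = len(x)
    press = 0.0
    for i in range(n):
        xr = [x[j] for j in range(n) if j != i]
        yr = [y[j] for j in range(n) if j != i]
        c0, c1 = ols_oracle(xr, yr)
        press += (y[i] - (c0 + c1 * x[i])) ** 2
    my = sum(y) / n
    tss = sum((yi - my) ** 2 for yi in y)
    return 1.0 - press / tss


def q2_f3_oracle(y_ext, yhat_ext, y_train):
    n_ext = len(y_ext)
    n_tr = len(y_train)
    sse = sum((y_ext[i] - yhat_ext[i]) ** 2 for i in range(n_ext))
    m = sum(y_train) / n_tr
    sst = sum((v - m) ** 2 for v in y_train)
    return 1.0 - (sse / n_ext) / (sst / n_tr)


def ccc_oracle(y, yhat):
    n = len(y)
    my = sum(y) / n
    mp = sum(yhat) / n
    vy = sum((v - my) ** 2 for v in y) / n
    vp = sum((v - mp) ** 2 for v in yhat) / n
    cov = sum((y[i] - my) * (yhat[i] - mp) for i in range(n)) / n
    return 2 * cov / (vy + vp + (my - mp) ** 2)


def iic_oracle(y, yhat):
    resid = [y[i] - yhat[i] for i in range(len(y))]
    neg = [abs(r) for r in resid if r < 0]
    pos = [abs(r) for r in resid if r >= 0]
    if not neg or not pos:
        return 0.0
    mae_neg = sum(neg) / len(neg)
    mae_pos = sum(pos) / len(pos)
    hi = max(mae_neg, mae_pos)
    if hi == 0:
        return 0.0
    return pearson_oracle(y, yhat) * (min(mae_neg, mae_pos) / hi)


def cii_oracle(x, y):
    n = len(x)
    r2_full = pearson_oracle(x, y) ** 2
    protests = 0.0
    for k in range(n):
        xr = [x[j] for j in range(n) if j != k]
        yr = [y[j] for j in range(n) if j != k]
        c0, c1 = ols_oracle(xr, yr)
        yhat = [c0 + c1 * v for v in xr]
        r2_k = pearson_oracle(yr, yhat) ** 2
        if r2_k > r2_full:
            protests += r2_k - r2_full
    return 1.0 - protests


def f_oracle(r2, n):
    return r2 * (n - 2) / (1 - r2)


# --- attributes ----------------------------------------------------------


def sequence_oracle(tokens, order):
    """Direct string windows with mirror normalization."""
    counts = {}
    if order == 1:
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        return counts
    for i in range(len(tokens) - order + 1):
        w = tuple(tokens[i : i + order])
        w = min(w, tuple(reversed(w)))
        key = "~".join(w)
        counts[key] = counts.get(key, 0) + 1
    return counts


def ec_oracle(vertices, edges, order):
    """Morgan values via adjacency-matrix powers applied to the degree vector."""
    n = len(vertices)
    A = np.zeros((n, n))
    for i, j, _ in edges:
        A[i, j] = 1
        A[j, i] = 1
    ec = A.sum(axis=1)  # degrees
    for _ in range(order):
        ec = A @ ec
    counts = {}
    for v in range(n):
        key = f"{vertices[v]}/EC{order}={int(ec[v])}"
        counts[key] = counts.get(key, 0) + 1
    return counts


def nnc_oracle(vertices, edges):
    nbrs = {v: [] for v in range(len(vertices))}
    for i, j, _ in edges:
        nbrs[i].append(vertices[j])
        nbrs[j].append(vertices[i])
    counts = {}
    for v in range(len(vertices)):
        key = f"{vertices[v]}/N[{','.join(sorted(nbrs[v]))}]"
        counts[key] = counts.get(key, 0) + 1
    return counts


def app_oracle(vertices, tokens, pairs):
    """Recount symbols from scratch and emit the joint-count keys."""
    counts = {}
    for sym in ("F", "Cl", "Br", "N", "O", "S", "P"):
        counts[sym] = sum(1 for v in vertices if v.capitalize() == sym)
    for sym in ("=", "#"):
        counts[sym] = sum(1 for t in tokens if t == sym)
    out = {}
    for a, b in pairs:
        if counts[a] >= 1 and counts[b] >= 1:
            out[f"({a}.{b})..{counts[a]}.{counts[b]}"] = 1
    return out
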