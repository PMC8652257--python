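"""Independent reference implementations used to check the package.

Everything here is written with scalar loops and basic math so it shares no
code path with the package's vectorized implementations.
"""

import math


def matmul_oracle(A, x):
    """(n x r) @ (r,) by explicit double loop."""
    n, r = len(A), len(A[0])
    return [sum(A[i][j] * x[j] for j in range(r)) for i in range(n)]


def encode_oracle(W, x):
    return [math.tanh(z) for z in matmul_oracle(W, x)]


def softmax_oracle(b):
    mx = max(b)
    e = [math.exp(z - mx) for z in b]
    s = sum(e)
    return [z / s for z in e]


def squash_oracle(s, const=0.5):
    sq = sum(z * z for z in s)
    if sq == 0.0:
        return [0.0 for _ in s]
    norm = math.sqrt(sq)
    scale = sq / (const + sq) / norm
    return [scale * z for z in s]


def routing_oracle(u_hat, r, const=0.5, normalize_every_iter=False,
                   accumulate_logits=False):
    """Literal scalar-loop transcription of the routing procedure.

    ``u_hat`` is a nested list [l][k][m] for ONE sample. Returns (v, c) with
    v as [k][m] and c as [l][k].

    Steps per iteration: c_i = softmax(b_i) over types; s_j = sum_i c_ij
    u_hat[i][j]; on non-final iterations s_j is L2-normalized and b_ij is set
    to (or, in accumulate mode, incremented by) u_hat[i][j] . s_j. The final
    weighted sum goes through squash (after normalization only when
    ``normalize_every_iter``).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    l = len(u_hat)
    k = len(u_hat[0])
    m = len(u_hat[0][0])
    b = [[0.0] * k for _ in range(l)]
    c = None
    s = None
    for it in range(r):
        c = [softmax_oracle(b[i]) for i in range(l)]
        s = [[sum(c[i][j] * u_hat[i][j][d] for i in range(l)) for d in range(m)]
             for j in range(k)]
        if it < r - 1:
            s_hat = []
            for j in range(k):
                norm = math.sqrt(sum(z * z for z in s[j]))
                s_hat.append([z / norm for z in s[j]] if norm > 0
                             else [0.0] * m)
            for i in range(l):
                for j in range(k):
                    dot = sum(u_hat[i][j][d] * s_hat[j][d] for d in range(m))
                    b[i][j] = b[i][j] + dot if accumulate_logits else dot
    if normalize_every_iter:
        out = []
        for j in range(k):
            norm = math.sqrt(sum(z * z for z in s[j]))
            out.append([z / norm for z in s[j]] if norm > 0 else [0.0] * m)
        s = out
    v = [squash_oracle(s[j], const) for j in range(k)]
    return v, c


def auc_oracle(y, scores):
    """One-vs-rest AUC by O(n^2) pairwise concordance counting."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def pearson_oracle(a, b):
    """Closed-form covariance / (sigma_a sigma_b)."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)
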