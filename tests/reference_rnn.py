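"""Independent reference implementations used only as test oracles.

Everything here is written with pure-Python scalar loops, deliberately
sharing no code path with the package's vectorized numpy implementation.
"""

import math


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def ref_batchnorm(gamma, beta, mean, var, eps, x):
    return [
        gamma[j] * (x[j] - mean[j]) / math.sqrt(var[j] + eps) + beta[j]
        for j in range(len(x))
    ]


def _matvec(W, v):
    return [sum(W[n][m] * v[m] for m in range(len(v))) for n in range(len(W))]


def ref_lstm_sequence(p, X, peepholes: bool):
    """Hidden-state sequence of a peephole LSTM over a list of input vectors."""
    N = len(p["bi"])
    h = [0.0] * N
    c = [0.0] * N
    out = []
    for x in X:
        xi, xf, xc, xo = (_matvec(p[k], x) for k in ("Wxi", "Wxf", "Wxc", "Wxo"))
        hi, hf, hc, ho = (_matvec(p[k], h) for k in ("Whi", "Whf", "Whc", "Who"))
        i = []
        f = []
        for n in range(N):
            ai = xi[n] + hi[n] + p["bi"][n]
            af = xf[n] + hf[n] + p["bf"][n]
            if peepholes:
                ai += p["wci"][n] * c[n]
                af += p["wcf"][n] * c[n]
            i.append(_sigmoid(ai))
            f.append(_sigmoid(af))
        ct = [math.tanh(xc[n] + hc[n] + p["bc"][n]) for n in range(N)]
        c = [f[n] * c[n] + i[n] * ct[n] for n in range(N)]
        o = []
        for n in range(N):
            ao = xo[n] + ho[n] + p["bo"][n]
            if peepholes:
                ao += p["wco"][n] * c[n]
            o.append(_sigmoid(ao))
        h = [o[n] * math.tanh(c[n]) for n in range(N)]
        out.append(list(h))
    return out


def ref_gru_sequence(p, X):
    """Hidden-state sequence of a GRU (reset applied before the recurrent
    matrix multiplication) over a list of input vectors."""
    N = len(p["bz"])
    h = [0.0] * N
    out = []
    for x in X:
        xz, xr, xc = (_matvec(p[k], x) for k in ("Wxz", "Wxr", "Wxc"))
        hz, hr = _matvec(p["Whz"], h), _matvec(p["Whr"], h)
        z = [_sigmoid(xz[n] + hz[n] + p["bz"][n]) for n in range(N)]
        r = [_sigmoid(xr[n] + hr[n] + p["br"][n]) for n in range(N)]
        rh = [r[n] * h[n] for n in range(N)]
        hc = _matvec(p["Whc"], rh)
        ht = [math.tanh(xc[n] + hc[n] + p["bc"][n]) for n in range(N)]
        h = [(1.0 - z[n]) * h[n] + z[n] * ht[n] for n in range(N)]
        out.append(list(h))
    return out


def ref_softmax(logits):
    m = max(logits)
    e = [math.exp(v - m) for v in logits]
    s = sum(e)
    return [v / s for v in e]


def ref_model_forward(model, block_values):
    """End-to-end forward through a package ModelParams, scalar arithmetic."""
    bn = model.batchnorm
    X = [
        ref_batchnorm(
            list(bn.gamma), list(bn.beta), list(bn.running_mean), list(bn.running_var),
            bn.epsilon, list(row),
        )
        for row in block_values
    ]
    for layer in model.recurrent_layers:
        p = {k: getattr(layer, k).tolist() for k in _layer_keys(layer)}
        if hasattr(layer, "peepholes_enabled"):
            X = ref_lstm_sequence(p, X, layer.peepholes_enabled)
        else:
            X = ref_gru_sequence(p, X)
    h = X[-1]
    W, b = model.dense.W.tolist(), model.dense.b.tolist()
    logits = [sum(W[c][n] * h[n] for n in range(len(h))) + b[c] for c in range(len(b))]
    return ref_softmax(logits)


def _layer_keys(layer):
    if hasattr(layer, "peepholes_enabled"):
        return ("Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc", "Who",
                "wci", "wcf", "wco", "bi", "bf", "bc", "bo")
    return ("Wxz", "Wxr", "Wxc", "Whz", "Whr", "Whc", "bz", "br", "bc")


def ref_pairwise_auc(scores, positives):
    """Pairwise-ranking AUC: P(score_pos > score_neg) + 0.5 P(tie), O(n^2)."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
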