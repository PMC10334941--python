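"""Independent brute-force oracles.

Every function here re-derives a quantity from its definition with explicit
loops and unsimplified formulas, deliberately sharing no code with the
package implementation it checks.
"""

import math

import numpy as np


def ranking_loss_bruteforce(f, scores):
    """Mean pairwise cross-entropy, looped over every unordered pair."""
    f = list(map(float, f))
    s = list(map(float, scores))
    n = len(f)
    costs = []
    for i in range(n):
        for j in range(i + 1, n):
            o = f[i] - f[j]
            if s[i] > s[j]:
                pbar = 1.0
            elif s[i] < s[j]:
                pbar = 0.0
            else:
                pbar = 0.5
            p = 1.0 / (1.0 + math.exp(-o))
            # unsimplified cross-entropy, guarded only against log(0)
            eps = 1e-300
            costs.append(-pbar * math.log(max(p, eps))
                         - (1.0 - pbar) * math.log(max(1.0 - p, eps)))
    return sum(costs) / len(costs)


def softmax_ce_bruteforce(logits, labels):
    """Per-sample -log softmax, averaged."""
    total = 0.0
    for z, y in zip(logits, labels):
        exps = [math.exp(v - max(z)) for v in z]
        p = exps[int(y)] / sum(exps)
        total += -math.log(p)
    return total / len(labels)


def bce_bruteforce(logits, labels, weights=(1.0, 1.0, 1.0)):
    """Weighted per-element sigmoid binary cross-entropy, looped."""
    n, k = len(logits), len(logits[0])
    w = [wi * k / sum(weights) for wi in weights]
    total = 0.0
    for row, lab in zip(logits, labels):
        for j in range(k):
            p = 1.0 / (1.0 + math.exp(-row[j]))
            p = min(max(p, 1e-300), 1 - 1e-16)
            total += w[j] * (-lab[j] * math.log(p) - (1 - lab[j]) * math.log(1 - p))
    return total / (n * k)


def consistency_mse_bruteforce(zd_s, zf_s, zd_t, zf_t):
    """Per-head MSE of predicted distributions, summed over heads."""
    def softmax(z):
        exps = [math.exp(v - max(z)) for v in z]
        return [e / sum(exps) for e in exps]

    def sigmoid(v):
        return 1.0 / (1.0 + math.exp(-v))

    n = len(zd_s)
    total_d, cnt_d = 0.0, 0
    for i in range(n):
        ps, pt = softmax(zd_s[i]), softmax(zd_t[i])
        for a, b in zip(ps, pt):
            total_d += (a - b) ** 2
            cnt_d += 1
    total_f, cnt_f = 0.0, 0
    for i in range(n):
        for a, b in zip(zf_s[i], zf_t[i]):
            total_f += (sigmoid(a) - sigmoid(b)) ** 2
            cnt_f += 1
    return total_d / cnt_d + total_f / cnt_f


def auc_bruteforce(scores, truth):
    """O(n^2) Mann-Whitney ROC area with half credit for ties."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def grayworld_gains(pixels):
    """Gray World illuminant: plain channel means mapped to their average."""
    means = pixels.reshape(-1, 3).mean(axis=0)
    return means.mean() / means


def maxrgb_gains(pixels):
    """max-RGB illuminant: per-channel maxima mapped to their average."""
    maxima = pixels.reshape(-1, 3).max(axis=0)
    return maxima.mean() / maxima


def global_hist_eq(channel):
    """Global histogram equalization via the empirical CDF."""
    flat = np.sort(channel.ravel())
    return np.searchsorted(flat, channel, side="right") / flat.size


def kappa_from_table(n11, n10, n01, n00):
    """Cohen's kappa from a hand-filled 2x2 agreement table."""
    n = n11 + n10 + n01 + n00
    po = (n11 + n00) / n
    p_a1 = (n11 + n10) / n
    p_b1 = (n11 + n01) / n
    pe = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    return (po - pe) / (1 - pe)
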