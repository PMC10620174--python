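"""Independent brute-force oracles: explicit double loops, no vectorization,
no reuse of the library's code paths. Used to cross-check the rank-drift
statistics and the location/scale correction."""

import math

import numpy as np


# ---------------------------------------------------------------------------
# Rank-drift statistics (footrule / PSD / PCSD), explicit loops
# ---------------------------------------------------------------------------

def bf_distances(points, ids, anchor_idx):
    out = {}
    for j in range(len(ids)):
        if j == anchor_idx:
            continue
        s = 0.0
        for a, b in zip(points[anchor_idx], points[j]):
            s += (a - b) ** 2
        out[ids[j]] = math.sqrt(s)
    return out


def bf_ranking(points, ids, anchor_idx):
    """(ranked id list, scores dict) with distance ties broken by id order."""
    dists = bf_distances(points, ids, anchor_idx)
    ranked = sorted(dists, key=lambda t: (dists[t], t))
    dmax = max(dists.values())
    scores = {}
    for t in dists:
        scores[t] = 1.0 if dmax == 0 else dists[t] / dmax
    return ranked, scores


def bf_footrule(list_a, list_b, k):
    union = []
    for t in list_a + list_b:
        if t not in union:
            union.append(t)
    total = 0
    for t in union:
        ra = list_a.index(t) + 1 if t in list_a else k + 1
        rb = list_b.index(t) + 1 if t in list_b else k + 1
        total += abs(min(rb, k + 1) - min(ra, k + 1))
    return total


def bf_psd(orig_points, transf_points, ids, anchor_idx, k=None):
    ranked_o, scores_o = bf_ranking(orig_points, ids, anchor_idx)
    ranked_t, scores_t = bf_ranking(transf_points, ids, anchor_idx)
    if k is None:
        k = len(ids) - 1
    total = 0.0
    for t in ranked_o:
        ro = min(ranked_o.index(t) + 1, k + 1)
        rt = min(ranked_t.index(t) + 1, k + 1)
        total += abs(scores_t[t] - scores_o[t]) * abs(rt - ro)
    return total


def bf_pcsd(orig_points, transf_points, ids, k=None):
    vals = []
    for i in range(len(ids)):
        vals.append(bf_psd(orig_points, transf_points, ids, i, k))
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# Location/scale correction, one feature at a time (ls-only mode)
# ---------------------------------------------------------------------------

def bf_ls_correct(y, batches):
    """Per-feature-loop location/scale fit-and-apply with raw per-batch
    moments (no EB): standardize by the weighted grand mean and pooled
    residual sd, remove per-batch mean/sd, restore the grand location."""
    y = np.asarray(y, float)
    n, d = y.shape
    labels = sorted(set(batches))
    out = np.empty_like(y)
    for f in range(d):
        col = y[:, f]
        means = {}
        for b in labels:
            vals = [col[i] for i in range(n) if batches[i] == b]
            means[b] = sum(vals) / len(vals)
        grand = 0.0
        for b in labels:
            n_b = sum(1 for i in range(n) if batches[i] == b)
            grand += means[b] * n_b / n
        sse = 0.0
        for i in range(n):
            sse += (col[i] - means[batches[i]]) ** 2
        pooled_sd = math.sqrt(sse / n)
        z = [(col[i] - grand) / pooled_sd for i in range(n)]
        gamma, delta = {}, {}
        for b in labels:
            zb = [z[i] for i in range(n) if batches[i] == b]
            mu = sum(zb) / len(zb)
            var = sum((v - mu) ** 2 for v in zb) / len(zb)
            gamma[b], delta[b] = mu, math.sqrt(var)
        for i in range(n):
            b = batches[i]
            out[i, f] = ((z[i] - gamma[b]) / delta[b]) * pooled_sd + grand
    return out
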