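"""Independent brute-force oracles used to validate the implementation paths.

These deliberately use the most literal definitions (dynamic programming,
exhaustive graph search, pair counting) and share no code with the package.
"""

from __future__ import annotations

import re

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def density_reachability_components(D, eps: float, min_pts: int = 2) -> list[int]:
    """DBSCAN-style density-reachability partition by exhaustive expansion.

    Core point: >= min_pts points (incl. itself) within eps.  Clusters are the
    sets reachable through core points; non-core, non-reached points are -1.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    core = [(D[i] <= eps).sum() >= min_pts for i in range(n)]
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            u = stack.pop()
            for v in range(n):
                if D[u][v] <= eps and labels[v] == -1:
                    labels[v] = cid
                    if core[v]:
                        stack.append(v)
        cid += 1
    return labels


def canonical_partition(labels) -> list[int]:
    """Relabel cluster ids by first appearance so partitions compare equal."""
    seen: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab == -1:
            out.append(-1)
        else:
            out.append(seen.setdefault(lab, len(seen)))
    return out


def clonotype_components(values, scaffolds, identity: float) -> list[int]:
    """Brute-force pairwise graph + depth-first connected components."""
    n = len(values)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = values[i], values[j]
            if len(a) != len(b) or scaffolds[i] != scaffolds[j]:
                continue
            ident = sum(x == y for x, y in zip(a, b)) / len(a)
            if ident >= identity:
                adj[i].append(j)
                adj[j].append(i)
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if labels[v] == -1:
                    labels[v] = cid
                    stack.append(v)
        cid += 1
    return labels


def liability_scan(aa_seq: str, motifs) -> int:
    """Position-by-position regex scan; counts non-overlapping hits per motif."""
    total = 0
    for _, pattern in motifs:
        pos = 0
        while pos <= len(aa_seq):
            m = re.compile(pattern).search(aa_seq, pos)
            if not m:
                break
            total += 1
            pos = m.end()
    return total


def roc_auc_pairs(y_true, scores) -> float:
    """ROC area by exhaustive positive/negative pair counting (ties = 1/2)."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def average_precision_literal(y_true, scores) -> float:
    """AP = sum over recall steps of precision at each positive, by sorting."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(y_true)
    tp = 0
    ap = 0.0
    for rank, i in enumerate(order, 1):
        if y_true[i] == 1:
            tp += 1
            ap += tp / rank
    return ap / n_pos


def pearson_literal(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def spearman_literal(x, y) -> float:
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        sv = np.asarray(v, dtype=float)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    return pearson_literal(ranks(x), ranks(y))


def confusion_literal(y_true, y_pred) -> list[list[int]]:
    out = [[0, 0], [0, 0]]
    for t, p in zip(y_true, y_pred):
        out[t][p] += 1
    return out


def knee_by_chord(curve) -> int:
    """Max perpendicular distance to the endpoint chord, checked at every index."""
    curve = np.asarray(curve, dtype=float)
    n = len(curve)
    x0, y0, x1, y1 = 0.0, curve[0], float(n - 1), curve[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    best_i, best_d = 0, -1.0
    for i in range(n):
        d = abs(dy * i - dx * curve[i] + x1 * y0 - y1 * x0) / norm
        if d > best_d:
            best_i, best_d = i, d
    return best_i
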