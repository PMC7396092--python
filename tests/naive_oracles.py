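"""From-definition reference implementations used as independent oracles.

Everything here is deliberately written as plain loops over points and
clusters, mirroring the documented definitions, so the vectorized
implementations in the package are checked against an independent route.
"""

import numpy as np


def clusters(lab):
    return sorted(set(int(c) for c in lab))


def wgss(X, lab):
    total = 0.0
    for c in clusters(lab):
        pts = X[lab == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def tss(X):
    return ((X - X.mean(axis=0)) ** 2).sum()


def scatter_within(X, lab):
    p = X.shape[1]
    W = np.zeros((p, p))
    for c in clusters(lab):
        pts = X[lab == c]
        R = pts - pts.mean(axis=0)
        W += R.T @ R
    return W


def pair_distances(X):
    n = len(X)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append((i, j, float(np.linalg.norm(X[i] - X[j]))))
    return out


def calinski_harabasz(X, lab):
    n = len(X)
    k = len(clusters(lab))
    w = wgss(X, lab)
    b = tss(X) - w
    return (b / (k - 1)) / (w / (n - k))


def silhouette(X, lab):
    n = len(X)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if lab[j] == lab[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if lab[j] == c])
            for c in clusters(lab)
            if c != lab[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def c_index(X, lab):
    pairs = pair_distances(X)
    within = [d for i, j, d in pairs if lab[i] == lab[j]]
    nw = len(within)
    all_d = sorted(d for _, _, d in pairs)
    s_w = sum(within)
    s_min = sum(all_d[:nw])
    s_max = sum(all_d[-nw:])
    return (s_w - s_min) / (s_max - s_min)


def dunn(X, lab):
    pairs = pair_distances(X)
    between = [d for i, j, d in pairs if lab[i] != lab[j]]
    within = [d for i, j, d in pairs if lab[i] == lab[j]]
    return min(between) / max(within)


def davies_bouldin(X, lab):
    cs = clusters(lab)
    cents = {c: X[lab == c].mean(axis=0) for c in cs}
    s = {
        c: np.mean([np.linalg.norm(x - cents[c]) for x in X[lab == c]]) for c in cs
    }
    total = 0.0
    for ci in cs:
        total += max(
            (s[ci] + s[cj]) / np.linalg.norm(cents[ci] - cents[cj])
            for cj in cs
            if cj != ci
        )
    return total / len(cs)


def mcclain_rao(X, lab):
    pairs = pair_distances(X)
    within = [d for i, j, d in pairs if lab[i] == lab[j]]
    between = [d for i, j, d in pairs if lab[i] != lab[j]]
    return (np.mean(within)) / (np.mean(between))


def point_biserial(X, lab):
    pairs = pair_distances(X)
    d = np.array([p[2] for p in pairs])
    within = np.array([lab[i] == lab[j] for i, j, _ in pairs])
    nw, nb, nt = within.sum(), (~within).sum(), len(d)
    mw, mb = d[within].mean(), d[~within].mean()
    return (mb - mw) * np.sqrt(nw * nb) / nt / d.std(ddof=1)


def ratkowsky_lance(X, lab):
    k = len(clusters(lab))
    p = X.shape[1]
    vals = []
    for j in range(p):
        col = X[:, j]
        t = ((col - col.mean()) ** 2).sum()
        w = 0.0
        for c in clusters(lab):
            sub = col[lab == c]
            w += ((sub - sub.mean()) ** 2).sum()
        vals.append(np.sqrt((t - w) / t))
    return float(np.mean(vals)) / np.sqrt(k)


def hartigan(X, lab_k, lab_k1):
    n = len(X)
    k = len(clusters(lab_k))
    return (wgss(X, lab_k) / wgss(X, lab_k1) - 1.0) * (n - k - 1)


def ball(X, lab):
    return wgss(X, lab) / len(clusters(lab))


def trace_w(X, lab):
    return wgss(X, lab)


def trcov_w(X, lab):
    W = scatter_within(X, lab)
    return float(np.trace(np.cov(W, rowvar=False, ddof=1)))


def rubin(X, lab):
    T = scatter_within(X, np.zeros(len(X), dtype=int))
    W = scatter_within(X, lab)
    return float(np.linalg.det(T) / np.linalg.det(W))


def krzanowski_lai(X, lab_km1, lab_k, lab_kp1):
    p = X.shape[1]

    def diff(lab_a, lab_b):
        ka = len(clusters(lab_a))
        kb = len(clusters(lab_b))
        return ka ** (2.0 / p) * wgss(X, lab_a) - kb ** (2.0 / p) * wgss(X, lab_b)

    return abs(diff(lab_km1, lab_k)) / abs(diff(lab_k, lab_kp1))


def _split_cluster(lab_k, lab_k1):
    for c in clusters(lab_k):
        members = np.flatnonzero(lab_k == c)
        children = set(int(x) for x in lab_k1[members])
        if len(children) == 2:
            return c
    raise AssertionError("no split found")


def duda_hart(X, lab_k, lab_k1):
    c = _split_cluster(lab_k, lab_k1)
    members = lab_k == c
    je1 = wgss(X[members], np.zeros(members.sum(), dtype=int))
    je2 = wgss(X[members], lab_k1[members])
    return je2 / je1


def pseudo_t2(X, lab_k, lab_k1):
    c = _split_cluster(lab_k, lab_k1)
    members = lab_k == c
    n_m = int(members.sum())
    je1 = wgss(X[members], np.zeros(n_m, dtype=int))
    je2 = wgss(X[members], lab_k1[members])
    return (je1 - je2) / (je2 / (n_m - 2))
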