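"""Cluster-validity index panel with majority-rule best-k voting.

Sixteen classical indices are computed on the hierarchical cut at each
candidate k; each index nominates one best k according to its published
optimality rule, and the k with the most nominations wins (ties break to
the smallest k, the parsimonious choice).  The panel is fixed and versioned
so endorsement counts are interpretable across runs.

Notation: n points, p features, partition into k clusters; W(k) is the
pooled within-cluster scatter matrix, WGSS = trace W, TSS the total sum of
squares, BGSS = TSS - WGSS.  Pair quantities use all n(n-1)/2 pairwise
Euclidean distances; S_w and N_w are the sum and count of within-cluster
pair distances.

Index and rule summary (value -> best-k rule):

==================  =========================================  =============
index               value at k                                 rule
==================  =========================================  =============
calinski_harabasz   (BGSS/(k-1)) / (WGSS/(n-k))                max value
silhouette          mean silhouette width                      max value
c_index             (S_w - S_min) / (S_max - S_min)            min value
dunn                min between-pair dist / max within-pair    max value
davies_bouldin      mean_i max_j (s_i+s_j)/d(c_i,c_j)          min value
hartigan            (W(k)/W(k+1) - 1)(n-k-1)                   max diff
ball                WGSS/k                                     max diff
krzanowski_lai      |DIFF(k)| / |DIFF(k+1)|                    max value
mcclain_rao         (S_w/N_w) / (S_b/N_b)                      min value
point_biserial      (m_b - m_w) sqrt(N_w N_b)/N_t / sd(d)      max value
ratkowsky_lance     mean_j sqrt(BGSS_j/TSS_j) / sqrt(k)        max value
trace_w             WGSS(k)                                    max 2nd diff
trcov_w             trace(cov(W(k)))                           max diff
rubin               det(T)/det(W(k))                           min 2nd diff
duda_hart           Je(2)/Je(1) of the k->k+1 split            crit. value
pseudo_t2           (Je1-Je2) / (Je2/(n_m-2))                  crit. value
==================  =========================================  =============

"max diff" nominates the k maximizing value(k-1) - value(k); "max/min 2nd
diff" uses value(k-1) - 2 value(k) + value(k+1).  DIFF(k) for
Krzanowski-Lai is (k-1)^{2/p} W(k-1) - k^{2/p} W(k).  The Duda-Hart and
pseudo-t2 rules nominate the smallest k whose k->k+1 split is *not*
supported at the standard-normal critical value (z = 1.6449):
crit = 1 - 2/(pi p) - z sqrt(2 (1 - 8/(pi^2 p)) / (n_m p)).

An index abstains (contributes no vote) wherever its value is undefined,
e.g. a degenerate cut; abstentions are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

PANEL_VERSION = "prsubtype-panel-1.0"

INDEX_NAMES = [
    "calinski_harabasz",
    "silhouette",
    "c_index",
    "dunn",
    "davies_bouldin",
    "hartigan",
    "ball",
    "krzanowski_lai",
    "mcclain_rao",
    "point_biserial",
    "ratkowsky_lance",
    "trace_w",
    "trcov_w",
    "rubin",
    "duda_hart",
    "pseudo_t2",
]

_Z_CRIT = 1.6448536269514722  # Phi^{-1}(0.95)


def duda_critical_value(n_m: int, p: int, z: float = _Z_CRIT) -> float:
    """Critical value for the Duda-Hart split test on a cluster of n_m points."""
    return 1.0 - 2.0 / (np.pi * p) - z * np.sqrt(
        2.0 * (1.0 - 8.0 / (np.pi**2 * p)) / (n_m * p)
    )


@dataclass
class _PartitionStats:
    labels: np.ndarray
    counts: np.ndarray
    centroids: np.ndarray  # (k, p)
    W: np.ndarray  # (p, p) pooled within scatter
    wgss: float
    wgss_per_cluster: np.ndarray
    wgss_per_feature: np.ndarray


def _partition_stats(X: np.ndarray, labels: np.ndarray) -> _PartitionStats:
    k = labels.max() + 1
    n, p = X.shape
    counts = np.bincount(labels, minlength=k)
    sums = np.zeros((k, p))
    np.add.at(sums, labels, X)
    centroids = sums / counts[:, None]
    R = X - centroids[labels]
    W = R.T @ R
    wgss_pc = np.bincount(labels, weights=(R**2).sum(axis=1), minlength=k)
    return _PartitionStats(
        labels, counts, centroids, W, float(np.trace(W)), wgss_pc, np.diag(W).copy()
    )


@dataclass
class PanelResult:
    values: dict  # index -> {k: value}
    best_k: dict  # index -> int | None (None = abstained overall)
    abstentions: dict = field(default_factory=dict)  # index -> list of k


class ValidityPanel:
    """Evaluate the full index panel on nested partitions of one dataset.

    ``labels_by_k`` must contain every k in [k_min - 1, k_max + 1] that is
    achievable (k = 1 is the trivial partition), and the partitions must be
    nested (a hierarchy), which the Duda-Hart family requires.
    """

    def __init__(self, X: np.ndarray, labels_by_k: dict[int, np.ndarray]):
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.labels_by_k = {k: np.asarray(v, int).ravel() for k, v in labels_by_k.items()}
        self.stats = {k: _partition_stats(self.X, lab) for k, lab in self.labels_by_k.items()}

        xbar = self.X.mean(axis=0)
        R0 = self.X - xbar
        self.T = R0.T @ R0
        self.tss = float(np.trace(self.T))
        self.tss_per_feature = np.diag(self.T).copy()

        self.d = pdist(self.X)
        self.n_pairs = len(self.d)
        self._d_sorted = np.sort(self.d)
        self._d_cumsum = np.concatenate([[0.0], np.cumsum(self._d_sorted)])
        self._d_sum = float(self._d_cumsum[-1])
        self._d_sd = float(self.d.std(ddof=1)) if self.n_pairs > 1 else np.nan
        ii, jj = np.triu_indices(self.n, 1)
        self._pair_i, self._pair_j = ii, jj
        self._D = None  # full square matrix, built lazily for silhouette

    # -- helpers -----------------------------------------------------------

    def _pair_aggregates(self, k: int):
        lab = self.labels_by_k[k]
        same = lab[self._pair_i] == lab[self._pair_j]
        n_w = int(same.sum())
        s_w = float(self.d[same].sum())
        d_between = self.d[~same]
        min_between = float(d_between.min()) if len(d_between) else np.nan
        d_within = self.d[same]
        max_within = float(d_within.max()) if len(d_within) else 0.0
        return same, n_w, s_w, min_between, max_within

    def _full_matrix(self) -> np.ndarray:
        if self._D is None:
            from scipy.spatial.distance import squareform

            self._D = squareform(self.d)
        return self._D

    def _split_info(self, k: int):
        """Je1, Je2 and parent size for the cluster that splits going k -> k+1."""
        if k + 1 not in self.stats:
            return None
        lab_k = self.labels_by_k[k]
        lab_k1 = self.labels_by_k[k + 1]
        st_k = self.stats[k]
        for parent in range(k):
            members = lab_k == parent
            children = np.unique(lab_k1[members])
            if len(children) == 2:
                je1 = float(st_k.wgss_per_cluster[parent])
                st_k1 = self.stats[k + 1]
                je2 = float(st_k1.wgss_per_cluster[children].sum())
                return je1, je2, int(members.sum())
        return None

    # -- per-k index values ------------------------------------------------

    def calinski_harabasz(self, k):
        st = self.stats[k]
        if k < 2 or st.wgss == 0:
            return np.nan
        return ((self.tss - st.wgss) / (k - 1)) / (st.wgss / (self.n - k))

    def silhouette(self, k):
        lab = self.labels_by_k[k]
        counts = self.stats[k].counts
        if k < 2:
            return np.nan
        D = self._full_matrix()
        onehot = np.zeros((self.n, k))
        onehot[np.arange(self.n), lab] = 1.0
        sums = D @ onehot  # (n, k): total distance to each cluster
        own = counts[lab]
        a = np.where(own > 1, sums[np.arange(self.n), lab] / np.maximum(own - 1, 1), 0.0)
        mean_other = sums / counts[None, :]
        mean_other[np.arange(self.n), lab] = np.inf
        b = mean_other.min(axis=1)
        s = np.where(own > 1, (b - a) / np.maximum(a, b), 0.0)
        return float(s.mean())

    def c_index(self, k):
        _, n_w, s_w, _, _ = self._pair_aggregates(k)
        if n_w == 0 or n_w == self.n_pairs:
            return np.nan
        s_min = float(self._d_cumsum[n_w])
        s_max = float(self._d_sum - self._d_cumsum[self.n_pairs - n_w])
        if s_max == s_min:
            return np.nan
        return (s_w - s_min) / (s_max - s_min)

    def dunn(self, k):
        _, n_w, _, min_between, max_within = self._pair_aggregates(k)
        if np.isnan(min_between) or max_within == 0:
            return np.nan
        return min_between / max_within

    def davies_bouldin(self, k):
        st = self.stats[k]
        if k < 2:
            return np.nan
        # s_i = mean Euclidean distance of members to their centroid
        lab = st.labels
        dist_to_centroid = np.linalg.norm(self.X - st.centroids[lab], axis=1)
        s = np.bincount(lab, weights=dist_to_centroid, minlength=k) / st.counts
        M = np.linalg.norm(st.centroids[:, None, :] - st.centroids[None, :, :], axis=2)
        if np.any(M[~np.eye(k, dtype=bool)] == 0):
            return np.nan
        with np.errstate(divide="ignore"):
            R = (s[:, None] + s[None, :]) / M
        np.fill_diagonal(R, -np.inf)
        return float(R.max(axis=1).mean())

    def hartigan(self, k):
        if k + 1 not in self.stats:
            return np.nan
        w_k = self.stats[k].wgss
        w_k1 = self.stats[k + 1].wgss
        if w_k1 == 0:
            return np.nan
        return (w_k / w_k1 - 1.0) * (self.n - k - 1)

    def ball(self, k):
        return self.stats[k].wgss / k

    def krzanowski_lai(self, k):
        def diff(kk):
            if kk - 1 not in self.stats or kk not in self.stats:
                return np.nan
            e = 2.0 / self.p
            return (kk - 1) ** e * self.stats[kk - 1].wgss - kk**e * self.stats[kk].wgss

        num, den = diff(k), diff(k + 1)
        if np.isnan(num) or np.isnan(den) or den == 0:
            return np.nan
        return abs(num) / abs(den)

    def mcclain_rao(self, k):
        _, n_w, s_w, _, _ = self._pair_aggregates(k)
        n_b = self.n_pairs - n_w
        if n_w == 0 or n_b == 0:
            return np.nan
        s_b = self._d_sum - s_w
        if s_b == 0:
            return np.nan
        return (s_w / n_w) / (s_b / n_b)

    def point_biserial(self, k):
        _, n_w, s_w, _, _ = self._pair_aggregates(k)
        n_b = self.n_pairs - n_w
        if n_w == 0 or n_b == 0 or not np.isfinite(self._d_sd) or self._d_sd == 0:
            return np.nan
        m_w = s_w / n_w
        m_b = (self._d_sum - s_w) / n_b
        return (m_b - m_w) * np.sqrt(n_w * n_b) / self.n_pairs / self._d_sd

    def ratkowsky_lance(self, k):
        st = self.stats[k]
        bg = self.tss_per_feature - st.wgss_per_feature
        ok = self.tss_per_feature > 0
        if not ok.any():
            return np.nan
        c_bar = np.mean(np.sqrt(np.clip(bg[ok] / self.tss_per_feature[ok], 0, None)))
        return c_bar / np.sqrt(k)

    def trace_w(self, k):
        return self.stats[k].wgss

    def trcov_w(self, k):
        W = self.stats[k].W
        return float(np.trace(np.cov(W, rowvar=False, ddof=1)))

    def rubin(self, k):
        sT, ldT = np.linalg.slogdet(self.T)
        sW, ldW = np.linalg.slogdet(self.stats[k].W)
        if sT <= 0 or sW <= 0:
            return np.nan
        return float(np.exp(ldT - ldW))

    def duda_hart(self, k):
        info = self._split_info(k)
        if info is None:
            return np.nan
        je1, je2, n_m = info
        if je1 == 0 or n_m < 3:
            return np.nan
        return je2 / je1

    def pseudo_t2(self, k):
        info = self._split_info(k)
        if info is None:
            return np.nan
        je1, je2, n_m = info
        if je2 == 0 or n_m < 3:
            return np.nan
        return (je1 - je2) / (je2 / (n_m - 2))

    # -- voting ------------------------------------------------------------

    def evaluate(self, k_range: tuple[int, int]) -> PanelResult:
        k_min, k_max = k_range
        ks = [k for k in range(k_min, k_max + 1) if k in self.stats]

        values: dict[str, dict[int, float]] = {}
        for name in INDEX_NAMES:
            fn = getattr(self, name)
            # value grids: diff-based rules need one level below k_min
            lo = k_min - 1 if name in ("hartigan", "ball", "trace_w", "trcov_w", "rubin") else k_min
            hi = k_max + 1 if name in ("trace_w", "rubin") else k_max
            grid = [k for k in range(max(lo, 1), hi + 1) if k in self.stats]
            values[name] = {k: fn(k) for k in grid}

        best: dict[str, int | None] = {}
        abst: dict[str, list[int]] = {}

        def argbest(name, sign):
            vals = {k: v for k, v in values[name].items() if k in ks and np.isfinite(v)}
            abst[name] = [k for k in ks if not np.isfinite(values[name].get(k, np.nan))]
            if not vals:
                return None
            series = [(sign * v, k) for k, v in vals.items()]
            series.sort(key=lambda t: (-t[0], t[1]))
            return series[0][1]

        def argdiff(name, order=1, sign=1):
            out = {}
            for k in ks:
                vm1 = values[name].get(k - 1, np.nan)
                v = values[name].get(k, np.nan)
                if order == 1:
                    d = vm1 - v
                else:
                    vp1 = values[name].get(k + 1, np.nan)
                    d = vm1 - 2 * v + vp1
                out[k] = d
            finite = {k: v for k, v in out.items() if np.isfinite(v)}
            abst[name] = [k for k in ks if k not in finite]
            if not finite:
                return None
            series = [(sign * v, k) for k, v in finite.items()]
            series.sort(key=lambda t: (-t[0], t[1]))
            return series[0][1]

        best["calinski_harabasz"] = argbest("calinski_harabasz", +1)
        best["silhouette"] = argbest("silhouette", +1)
        best["c_index"] = argbest("c_index", -1)
        best["dunn"] = argbest("dunn", +1)
        best["davies_bouldin"] = argbest("davies_bouldin", -1)
        best["krzanowski_lai"] = argbest("krzanowski_lai", +1)
        best["mcclain_rao"] = argbest("mcclain_rao", -1)
        best["point_biserial"] = argbest("point_biserial", +1)
        best["ratkowsky_lance"] = argbest("ratkowsky_lance", +1)
        best["hartigan"] = argdiff("hartigan", order=1, sign=+1)
        best["ball"] = argdiff("ball", order=1, sign=+1)
        best["trcov_w"] = argdiff("trcov_w", order=1, sign=+1)
        best["trace_w"] = argdiff("trace_w", order=2, sign=+1)
        best["rubin"] = argdiff("rubin", order=2, sign=-1)

        # critical-value split rules: smallest unsupported split
        for name, accept in (
            ("duda_hart", lambda v, crit, nm: v >= crit),
            ("pseudo_t2", lambda v, crit, nm: v <= ((1 - crit) / crit) * (nm - 2)),
        ):
            choice = None
            abst[name] = [k for k in ks if not np.isfinite(values[name].get(k, np.nan))]
            for k in ks:
                v = values[name].get(k, np.nan)
                info = self._split_info(k)
                if not np.isfinite(v) or info is None:
                    continue
                crit = duda_critical_value(info[2], self.p)
                if crit <= 0:
                    continue
                if accept(v, crit, info[2]):
                    choice = k
                    break
            best[name] = choice

        return PanelResult(values=values, best_k=best, abstentions=abst)
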