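"""Discrete Bayesian-network classifiers: naive Bayes, Chow-Liu, IAMB.

All three operate on discretized feature columns (integer levels) plus a
binary target, store Laplace-smoothed conditional probability tables, and
return the posterior probability of infestation given possibly partial
evidence (missing values are marginalized out, which is the practical
advantage of these models over the discriminative learners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from beetlecast.mrmr import conditional_mutual_information, mutual_information

LN2 = float(np.log(2.0))


def _level_index(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Map observed values onto indices of the declared level set (NaN -> -1)."""
    idx = np.searchsorted(levels, values)
    idx = np.clip(idx, 0, len(levels) - 1)
    ok = ~np.isnan(values)
    out = np.full(len(values), -1, dtype=int)
    out[ok] = idx[ok]
    return out


# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class DiscreteNaiveBayes:
    """Star-structured network: the target is parent of every covariate.

    With evidence columns missing, the corresponding factors simply drop out
    of the posterior; with *all* evidence missing the prediction is the
    class prior.
    """

    alpha: float = 1.0
    columns: list[str] = field(default_factory=list)
    levels: dict[str, np.ndarray] = field(default_factory=dict)
    log_prior: np.ndarray | None = None          # shape (2,)
    log_cpt: dict[str, np.ndarray] = field(default_factory=dict)  # (2, n_levels)

    def fit(self, X: pd.DataFrame, y: np.ndarray, level_sets: dict) -> "DiscreteNaiveBayes":
        y = np.asarray(y).astype(int)
        if len(X) == 0:
            raise ValueError("empty training data")
        self.columns = list(X.columns)
        self.levels = {c: np.asarray(level_sets[c], dtype=float) for c in self.columns}
        n1 = y.sum()
        n0 = len(y) - n1
        prior = np.array([n0 + self.alpha, n1 + self.alpha], dtype=float)
        self.log_prior = np.log(prior / prior.sum())
        self.log_cpt = {}
        for col in self.columns:
            lv = self.levels[col]
            xi = _level_index(X[col].to_numpy(dtype=float), lv)
            counts = np.full((2, len(lv)), self.alpha, dtype=float)
            ok = xi >= 0
            np.add.at(counts, (y[ok], xi[ok]), 1.0)
            self.log_cpt[col] = np.log(counts / counts.sum(axis=1, keepdims=True))
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        logp = np.tile(self.log_prior, (len(X), 1))
        for col in self.columns:
            if col not in X.columns:
                continue
            xi = _level_index(X[col].to_numpy(dtype=float), self.levels[col])
            ok = xi >= 0
            logp[ok] += self.log_cpt[col][:, xi[ok]].T
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 1] / p.sum(axis=1)


# ---------------------------------------------------------------------------
# Chow-Liu tree
# ---------------------------------------------------------------------------

@dataclass
class ChowLiuTree:
    """Tree-structured network minimizing KL distance to the empirical joint.

    The structure is the maximum-weight spanning tree of the pairwise
    mutual-information graph, directed away from an arbitrary (first-column)
    root; the target node may sit anywhere in the tree.  Inference is exact
    belief propagation, so partial evidence is handled natively.
    """

    alpha: float = 1.0
    columns: list[str] = field(default_factory=list)
    target: str = "target"
    levels: dict[str, np.ndarray] = field(default_factory=dict)
    parent: dict[str, str | None] = field(default_factory=dict)
    log_cpt: dict[str, np.ndarray] = field(default_factory=dict)
    edge_weight: dict[tuple[str, str], float] = field(default_factory=dict)

    def fit(self, X: pd.DataFrame, y: np.ndarray, level_sets: dict,
            target: str = "target") -> "ChowLiuTree":
        if X.shape[1] < 1:
            raise ValueError("Chow-Liu needs at least 2 variables (target + 1)")
        self.target = target
        frame = X.copy()
        frame[target] = np.asarray(y).astype(float)
        self.columns = list(frame.columns)
        self.levels = {c: np.asarray(level_sets[c], dtype=float) for c in X.columns}
        self.levels[target] = np.array([0.0, 1.0])

        g = nx.Graph()
        g.add_nodes_from(self.columns)
        data = {c: frame[c].to_numpy(dtype=float) for c in self.columns}
        for i, a in enumerate(self.columns):
            for b in self.columns[i + 1:]:
                w = mutual_information(data[a], data[b])
                g.add_edge(a, b, weight=w)
                self.edge_weight[(a, b)] = w
        tree = nx.maximum_spanning_tree(g, weight="weight")

        # root at the target: the undirected structure is what matters, and
        # this orientation makes the factorization match naive Bayes exactly
        # whenever the tree happens to be a star centered on the target
        root = target
        self.parent = {root: None}
        for parent, child in nx.bfs_edges(tree, root):
            self.parent[child] = parent

        self.log_cpt = {}
        for node, par in self.parent.items():
            lv = self.levels[node]
            xi = _level_index(data[node], lv)
            if par is None:
                counts = np.full(len(lv), self.alpha, dtype=float)
                np.add.at(counts, xi[xi >= 0], 1.0)
                self.log_cpt[node] = np.log(counts / counts.sum())
            else:
                plv = self.levels[par]
                pi = _level_index(data[par], plv)
                counts = np.full((len(plv), len(lv)), self.alpha, dtype=float)
                ok = (xi >= 0) & (pi >= 0)
                np.add.at(counts, (pi[ok], xi[ok]), 1.0)
                self.log_cpt[node] = np.log(counts / counts.sum(axis=1, keepdims=True))
        return self

    def tree_weight(self) -> float:
        """Total mutual information carried by the fitted tree's edges."""
        total = 0.0
        for child, par in self.parent.items():
            if par is None:
                continue
            key = (par, child) if (par, child) in self.edge_weight else (child, par)
            total += self.edge_weight[key]
        return total

    def edges(self) -> set[frozenset]:
        return {
            frozenset((child, par))
            for child, par in self.parent.items()
            if par is not None
        }

    def _children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {c: [] for c in self.columns}
        for node, par in self.parent.items():
            if par is not None:
                ch[par].append(node)
        return ch

    def posterior_target(self, evidence: dict[str, float]) -> float:
        """P(target = 1 | evidence), exact.

        The target has only two levels, so the posterior is computed by
        clamping the target to each value and normalizing the evidence
        likelihoods; everything unobserved is summed out by the upward
        pass of :meth:`_evidence_likelihood`.
        """
        like = np.empty(2)
        for qi, qval in enumerate((0.0, 1.0)):
            ev = dict(evidence)
            ev[self.target] = qval
            like[qi] = self._evidence_likelihood(ev)
        total = like.sum()
        if total <= 0:
            return 0.5
        return float(like[1] / total)

    def _evidence_likelihood(self, evidence: dict[str, float]) -> float:
        """P(evidence) with all evidenced nodes clamped (others summed out)."""
        children = self._children()
        root = next(c for c, p in self.parent.items() if p is None)

        def clamp_vec(node: str) -> np.ndarray | None:
            val = evidence.get(node)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                return None
            lv = self.levels[node]
            idx = _level_index(np.array([float(val)]), lv)[0]
            v = np.zeros(len(lv))
            v[idx] = 1.0
            return v

        def subtree(node: str) -> np.ndarray:
            """Belief over node's levels from evidence in its subtree."""
            belief = np.ones(len(self.levels[node]))
            cv = clamp_vec(node)
            if cv is not None:
                belief = belief * cv
            for child in children[node]:
                cpt = np.exp(self.log_cpt[child])
                belief = belief * (cpt @ subtree(child))
            return belief

        prior = np.exp(self.log_cpt[root])
        return float(np.sum(prior * subtree(root)))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        cols = [c for c in self.columns if c != self.target and c in X.columns]
        out = np.empty(len(X))
        arr = X[cols].to_numpy(dtype=float)
        cache: dict[tuple, float] = {}
        for i in range(len(X)):
            key = tuple(arr[i])
            if key not in cache:
                evidence = {
                    c: arr[i, j]
                    for j, c in enumerate(cols)
                    if not np.isnan(arr[i, j])
                }
                cache[key] = self.posterior_target(evidence)
            out[i] = cache[key]
        return out


# ---------------------------------------------------------------------------
# IAMB
# ---------------------------------------------------------------------------

def g_squared_test(x, y, z=None) -> tuple[float, float]:
    """G^2 conditional-independence test; returns (statistic, p-value).

    ``G^2 = 2 N ln(2) I(X; Y | Z)`` with chi-square reference on
    ``(|X|-1)(|Y|-1) * prod |Z|`` degrees of freedom.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    if z is None or (hasattr(z, "shape") and np.size(z) == 0):
        mi = mutual_information(x, y)
        dz = 1
    else:
        z = np.asarray(z)
        if z.ndim == 1:
            z = z[:, None]
        mi = conditional_mutual_information(x, y, z)
        dz = int(
            np.prod([max(len(np.unique(z[:, j])), 1) for j in range(z.shape[1])])
        )
    rx = max(len(np.unique(x)), 2)
    ry = max(len(np.unique(y)), 2)
    df = (rx - 1) * (ry - 1) * dz
    stat = 2.0 * n * LN2 * mi
    return stat, float(chi2.sf(stat, df))


@dataclass
class IambModel:
    """Markov-blanket classifier via the incremental-association algorithm.

    Grow phase: repeatedly add the variable with the largest conditional
    mutual information with the target given the current blanket, as long
    as the association is significant at ``alpha``.  Shrink phase: remove
    blanket members that become conditionally independent of the target
    given the rest (the false-positive guard).  Prediction uses the
    smoothed CPT of the target given the blanket configuration, backing
    off to naive Bayes over the blanket for unseen or partial evidence.
    """

    alpha: float = 0.05
    smoothing: float = 1.0
    blanket: list[str] = field(default_factory=list)
    config_counts: dict = field(default_factory=dict)
    prior: float = 0.5
    nb_backoff: DiscreteNaiveBayes | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray, level_sets: dict) -> "IambModel":
        y = np.asarray(y).astype(int)
        if len(X) == 0:
            raise ValueError("empty training data")
        cols = list(X.columns)
        data = {c: X[c].to_numpy(dtype=float) for c in cols}

        blanket: list[str] = []
        # growing phase
        while True:
            candidates = [c for c in cols if c not in blanket]
            if not candidates:
                break
            z = (
                np.column_stack([data[c] for c in blanket]) if blanket else None
            )
            best, best_cmi = None, -1.0
            for c in candidates:
                cmi = (
                    conditional_mutual_information(data[c], y, z)
                    if z is not None
                    else mutual_information(data[c], y)
                )
                if cmi > best_cmi:
                    best, best_cmi = c, cmi
            _, p = g_squared_test(data[best], y, z)
            if p < self.alpha:
                blanket.append(best)
            else:
                break
        # shrinking phase
        for c in list(blanket):
            rest = [b for b in blanket if b != c]
            z = np.column_stack([data[b] for b in rest]) if rest else None
            _, p = g_squared_test(data[c], y, z)
            if p >= self.alpha:
                blanket.remove(c)

        self.blanket = blanket
        n1 = y.sum()
        self.prior = (n1 + self.smoothing) / (len(y) + 2 * self.smoothing)
        self.config_counts = {}
        if blanket:
            arr = np.column_stack([data[c] for c in blanket])
            for i in range(len(y)):
                key = tuple(arr[i])
                n0c, n1c = self.config_counts.get(key, (0, 0))
                if y[i]:
                    self.config_counts[key] = (n0c, n1c + 1)
                else:
                    self.config_counts[key] = (n0c + 1, n1c)
            self.nb_backoff = DiscreteNaiveBayes(alpha=self.smoothing).fit(
                X[blanket], y, {c: level_sets[c] for c in blanket}
            )
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if not self.blanket:
            return np.full(len(X), self.prior)
        arr = X[self.blanket].to_numpy(dtype=float)
        out = np.empty(len(X))
        backoff_rows = []
        for i in range(len(X)):
            row = arr[i]
            if np.isnan(row).any():
                backoff_rows.append(i)
                continue
            counts = self.config_counts.get(tuple(row))
            if counts is None:
                backoff_rows.append(i)
                continue
            n0c, n1c = counts
            out[i] = (n1c + self.smoothing) / (n0c + n1c + 2 * self.smoothing)
        if backoff_rows:
            sub = X.iloc[backoff_rows][self.blanket]
            out[backoff_rows] = self.nb_backoff.predict_proba(sub)
        return out
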