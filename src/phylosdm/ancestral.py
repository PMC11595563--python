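"""Ancestral area reconstruction under the Mk model.

Discrete geographic areas (here NE / NW / SE / SW quadrants) evolve along
the chronogram as a continuous-time Markov chain.  Three standard rate
parameterizations are supported: equal rates (ER, one rate), symmetric
(SYM, one rate per unordered pair) and all-rates-different (ARD, one per
ordered pair).  Likelihoods come from Felsenstein's pruning algorithm with
transition matrices P(t) = exp(Qt); node marginals combine the downward
conditional likelihoods with an upward pass under a uniform root prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo import TimeTree

__all__ = [
    "AREA_LABELS", "MkModel", "AncestralReconstruction", "mk_loglik",
    "fit_mk", "marginal_states", "select_model", "read_tip_states",
]

AREA_LABELS = ("NE", "NW", "SE", "SW")

RATE_MIN = 1e-8
RATE_MAX = 1e3


def _sym_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def _ard_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@dataclass
class MkModel:
    """A k-state Mk rate matrix under one of the ER/SYM/ARD schemes."""
    k: int
    parameterization: str  # "ER" | "SYM" | "ARD"
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.parameterization not in ("ER", "SYM", "ARD"):
            raise ValueError(f"unknown scheme {self.parameterization!r}")
        if len(self.rates) != self.n_params(self.k, self.parameterization):
            raise ValueError(
                f"{self.parameterization} with k={self.k} needs "
                f"{self.n_params(self.k, self.parameterization)} rates, "
                f"got {len(self.rates)}")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    @staticmethod
    def n_params(k: int, scheme: str) -> int:
        return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[scheme]

    @property
    def Q(self) -> np.ndarray:
        """Rate matrix with rows summing to zero."""
        Q = np.zeros((self.k, self.k))
        if self.parameterization == "ER":
            Q[:] = self.rates[0]
        elif self.parameterization == "SYM":
            for r, (i, j) in zip(self.rates, _sym_pairs(self.k)):
                Q[i, j] = Q[j, i] = r
        else:
            for r, (i, j) in zip(self.rates, _ard_pairs(self.k)):
                Q[i, j] = r
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def _tip_partial(state, k: int) -> np.ndarray:
    """One-hot vector, or an indicator over an ambiguity set."""
    v = np.zeros(k)
    if isinstance(state, (set, frozenset, list, tuple)):
        members = list(state)
    else:
        members = [state]
    for s in members:
        s = int(s)
        if not 0 <= s < k:
            raise ValueError(f"state {s} outside 0..{k - 1}")
        v[s] = 1.0
    return v


def _down_pass(tree: TimeTree, tip_states: Mapping, model: MkModel
               ) -> tuple[dict, float]:
    """Postorder conditional likelihoods (scaled); returns (partials,
    accumulated log scaling factor)."""
    k = model.k
    Q = model.Q
    F: dict = {}
    log_scale = 0.0
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_states:
                raise KeyError(f"tip {label!r} has no observed state")
            F[node] = _tip_partial(tip_states[label], k)
        else:
            part = np.ones(k)
            for child in node.child_nodes():
                P = expm(Q * (child.edge.length or 0.0))
                part = part * (P @ F[child])
            top = part.max()
            if top <= 0:
                raise ValueError("zero likelihood: incompatible tip states")
            log_scale += np.log(top)
            F[node] = part / top
    return F, log_scale


def mk_loglik(tree: TimeTree, tip_states: Mapping, model: MkModel) -> float:
    """Log-likelihood of the tip states by pruning, with the root partials
    combined under a uniform prior over the k states."""
    F, log_scale = _down_pass(tree, tip_states, model)
    root = tree.dtree.seed_node
    return float(log_scale + np.log(F[root].mean()))


def fit_mk(tree: TimeTree, tip_states: Mapping, parameterization: str = "ER"
           ) -> tuple[MkModel, float]:
    """Maximum-likelihood rates for one parameterization.

    Rates are optimized on the log scale within [1e-8, 1e3] per Myr from
    fixed starting points (reproducible).  With fewer than two observed
    states the MLE sits at the lower boundary; a boundary fit is returned
    with a warning.
    """
    k = _infer_k(tip_states)
    n_par = MkModel.n_params(k, parameterization)
    observed = set()
    for s in tip_states.values():
        observed |= set(s) if isinstance(s, (set, frozenset, list, tuple)) \
            else {int(s)}
    if len(observed) < 2:
        warnings.warn("fewer than 2 observed states: rate MLE at the "
                      "lower boundary")
        model = MkModel(k, parameterization, np.full(n_par, RATE_MIN))
        return model, mk_loglik(tree, tip_states, model)

    def neg_ll(log_rates: np.ndarray) -> float:
        model = MkModel(k, parameterization, np.exp(log_rates))
        return -mk_loglik(tree, tip_states, model)

    bounds = [(np.log(RATE_MIN), np.log(RATE_MAX))] * n_par
    # fixed multi-start: one around 1 change per root age, one 10x faster
    base = 1.0 / max(tree.root_age, 1e-6)
    best = None
    for start in (base, 10.0 * base):
        x0 = np.full(n_par, np.log(start))
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"Mk optimization failed: {best}")
    model = MkModel(k, parameterization, np.exp(best.x))
    return model, float(-best.fun)


def _infer_k(tip_states: Mapping) -> int:
    mx = 0
    for s in tip_states.values():
        vals = s if isinstance(s, (set, frozenset, list, tuple)) else [s]
        mx = max(mx, max(int(v) for v in vals))
    return max(2, mx + 1)


@dataclass
class AncestralReconstruction:
    """Marginal state probabilities at every node (preorder indexing)."""
    model: MkModel
    loglik: float
    node_probs: list[np.ndarray]                 # preorder over all nodes
    node_is_leaf: list[bool]
    node_labels: list[str]                       # tip label or "node<i>"
    modal_states: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modal_states:
            self.modal_states = [int(np.argmax(p)) for p in self.node_probs]

    def to_frame(self, labels: Sequence[str] = AREA_LABELS) -> pd.DataFrame:
        cols = list(labels[:self.model.k])
        df = pd.DataFrame(np.vstack(self.node_probs), columns=cols)
        df.insert(0, "node", self.node_labels)
        df["modal"] = [cols[m] for m in self.modal_states]
        return df


def marginal_states(tree: TimeTree, tip_states: Mapping,
                    model: MkModel) -> AncestralReconstruction:
    """Marginal posterior state probabilities at every node.

    Downward pruning pass plus an upward pass propagating the likelihood
    of the rest of the tree; uniform root prior.  Tips with an observed
    (unambiguous) state get probability 1 on it.
    """
    k = model.k
    Q = model.Q
    F, log_scale = _down_pass(tree, tip_states, model)
    root = tree.dtree.seed_node
    loglik = float(log_scale + np.log(F[root].mean()))
    G: dict = {root: np.full(k, 1.0 / k)}
    P_edge: dict = {}
    for node in tree.dtree.preorder_node_iter():
        if node is root:
            continue
        P_edge[node] = expm(Q * (node.edge.length or 0.0))
    for node in tree.dtree.preorder_node_iter():
        for child in node.child_nodes():
            m = G[node].copy()
            for sib in node.child_nodes():
                if sib is child:
                    continue
                m = m * (P_edge[sib] @ F[sib])
            g = m @ P_edge[child]
            total = g.sum()
            if total > 0:
                g = g / total
            G[child] = g
    probs, labels, is_leaf = [], [], []
    i_internal = 0
    for node in tree.dtree.preorder_node_iter():
        p = F[node] * G[node]
        p = p / p.sum()
        probs.append(p)
        if node.is_leaf():
            labels.append(node.taxon.label)
            is_leaf.append(True)
        else:
            labels.append(f"node{i_internal}")
            i_internal += 1
            is_leaf.append(False)
    return AncestralReconstruction(model=model, loglik=loglik,
                                   node_probs=probs, node_is_leaf=is_leaf,
                                   node_labels=labels)


def select_model(fits: Sequence[tuple[MkModel, float]],
                 criterion: str = "aic") -> str:
    """Pick a parameterization from (model, log-likelihood) fits.

    ``criterion="loglik"`` takes the raw likelihood arg-max (note ARD
    nests ER, so richer schemes can never lose under this rule);
    ``criterion="aic"`` penalizes parameters, AIC = 2p - 2 logL.
    """
    if not fits:
        raise ValueError("no fits to select from")
    if criterion == "loglik":
        best = max(fits, key=lambda f: f[1])
    elif criterion == "aic":
        best = min(fits, key=lambda f: 2 * len(f[0].rates) - 2 * f[1])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return best[0].parameterization


def read_tip_states(path, labels: Sequence[str] = AREA_LABELS,
                    null_token: str = "Null") -> tuple[dict, list[str]]:
    """Read a 2-column TSV of tip -> area code.

    Codes are single areas (``SE``), ambiguity sets (``SE|SW``), or the
    null token marking tips (e.g. outgroups) to prune before
    reconstruction.  Returns (tip -> state or frozenset, tips_to_prune).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["tip", "area"],
                     dtype=str, comment="#")
    index = {lab: i for i, lab in enumerate(labels)}
    states: dict = {}
    prune: list[str] = []
    for tip, area in zip(df["tip"], df["area"]):
        if area == null_token:
            prune.append(tip)
            continue
        members = area.split("|")
        bad = [m for m in members if m not in index]
        if bad:
            raise ValueError(f"unknown area codes {bad} for tip {tip!r}")
        if len(members) == 1:
            states[tip] = index[members[0]]
        else:
            states[tip] = frozenset(index[m] for m in members)
    return states, prune
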