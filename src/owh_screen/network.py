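"""Gaussian graphical models: MLE precision matrix, partial correlations and
Fisher-Z confidence-interval edge selection, including condition-vs-variable
networks with a binary 0/1 condition node."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PartialCorrelationNetwork:
    pcor: np.ndarray
    edges: pd.DataFrame  # columns i, j, pcor, ci_low, ci_high, significant
    variables: list
    n: int
    level: float

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.variables)
        for _, row in self.edges.iterrows():
            if row["significant"]:
                g.add_edge(row["i"], row["j"], weight=float(row["pcor"]),
                           sign=int(np.sign(row["pcor"])))
        nx.write_graphml(g, path)


def _as_matrix(X, variables=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if variables is None:
        variables = [f"V{i}" for i in range(X.shape[1])]
    return X, list(variables)


def precision_mle(X) -> np.ndarray:
    """Precision matrix as the inverse of the n-denominator sample covariance.

    Raises when there are too few observations or the covariance is singular.
    """
    X, _ = _as_matrix(X)
    n, p = X.shape
    if n <= p:
        raise ValueError("insufficient observations for MLE precision")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant column: covariance singular")
    cov = np.cov(X, rowvar=False, bias=True)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("covariance is singular or near-singular")
    return np.linalg.inv(cov)


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """rho_ij = -theta_ij / sqrt(theta_ii * theta_jj); unit diagonal."""
    precision = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def fisher_z_edges(pcor: np.ndarray, n: int, p: int | None = None,
                   level: float = 0.95,
                   variables=None) -> PartialCorrelationNetwork:
    """Select edges whose Fisher-Z confidence interval excludes zero.

    For partial correlations conditioning on the other k = p - 2 variables,
    SE = 1 / sqrt(n - k - 3); CI = tanh(atanh(rho) +/- z * SE).
    """
    pcor = np.asarray(pcor, dtype=float)
    if p is None:
        p = pcor.shape[0]
    k = p - 2
    dof = n - k - 3
    if dof <= 0:
        raise ValueError(f"need n > p + 1 for Fisher-Z intervals (n={n}, p={p})")
    if variables is None:
        variables = [f"V{i}" for i in range(pcor.shape[0])]
    se = 1.0 / np.sqrt(dof)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for i in range(pcor.shape[0]):
        for j in range(i + 1, pcor.shape[1]):
            r = float(np.clip(pcor[i, j], -1 + 1e-12, 1 - 1e-12))
            z = np.arctanh(r)
            lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
            rows.append({"i": variables[i], "j": variables[j], "pcor": r,
                         "ci_low": float(lo), "ci_high": float(hi),
                         "significant": bool(lo > 0 or hi < 0)})
    edges = pd.DataFrame(rows, columns=["i", "j", "pcor", "ci_low", "ci_high",
                                        "significant"])
    return PartialCorrelationNetwork(pcor=pcor, edges=edges,
                                     variables=list(variables), n=n,
                                     level=level)


def network_from_table(X, level: float = 0.95,
                       variables=None) -> PartialCorrelationNetwork:
    """Full pipeline: observations -> precision -> partial correlations -> edges."""
    mat, names = _as_matrix(X, variables)
    prec = precision_mle(mat)
    pcor = partial_correlations(prec)
    return fisher_z_edges(pcor, n=mat.shape[0], p=mat.shape[1], level=level,
                          variables=names)


def condition_network(table: pd.DataFrame, condition_col: str,
                      levels: tuple | None = None, level: float = 0.95,
                      condition_name: str | None = None):
    """Network over continuous variables plus a binary 0/1 condition node.

    ``levels = (zero_level, one_level)`` fixes the coding; the default uses the
    two observed levels in sorted order.  Returns ``(network,
    condition_effects)`` where the second element is the subset of edges
    incident to the condition node.
    """
    observed = sorted(table[condition_col].unique())
    if levels is None:
        levels = tuple(observed)
    if len(observed) != 2 or set(observed) != set(levels):
        raise ValueError(f"condition must have exactly the two levels {levels}; "
                         f"found {observed}")
    name = condition_name or condition_col
    numeric = table.drop(columns=[condition_col]).astype(float)
    numeric[name] = (table[condition_col] == levels[1]).astype(float)
    net = network_from_table(numeric, level=level)
    mask = (net.edges["i"] == name) | (net.edges["j"] == name)
    return net, net.edges[mask].reset_index(drop=True)
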