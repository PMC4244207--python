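"""Degree-distribution model fitting and degree-correlation statistics.

Degree distributions are summarised as relative frequencies at the raw
observed degrees (no binning) and fitted by nonlinear least squares with
three competing models — lognormal, power law and exponential — compared by
R^2.  Degree correlations come in three levels of compression: the joint
degree distribution (JDD) over edge endpoint degrees, the mean neighbour
degree per degree class (knn), and the Pearson degree correlation (PDC,
standard assortativity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from gofnet.network import WeightedGeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class DegreeDistribution:
    """Observed degrees and the fraction of nodes at each degree."""

    degrees: np.ndarray
    rel_freq: np.ndarray


@dataclass
class ModelFit:
    """One fitted degree-distribution model."""

    model: str
    params: dict[str, float] = field(default_factory=dict)
    r_squared: float = float("-inf")
    converged: bool = False
    message: str = ""


def degree_distribution(net: WeightedGeneNetwork | nx.Graph) -> DegreeDistribution:
    graph = net.graph if isinstance(net, WeightedGeneNetwork) else net
    degs = np.array([d for _, d in graph.degree()], dtype=int)
    if degs.size == 0:
        return DegreeDistribution(np.array([], dtype=int), np.array([]))
    values, counts = np.unique(degs, return_counts=True)
    return DegreeDistribution(values, counts / degs.size)


def _lognormal(x, y0, mu, sigma, amp):
    return y0 + amp / (np.sqrt(2 * np.pi) * sigma * x) * np.exp(
        -((np.log(x) - mu) ** 2) / (2 * sigma ** 2)
    )


def _power_law(x, a, b):
    return a * np.power(x, b)


def _exponential(x, y0, amp, b):
    return y0 + amp * np.exp(b * x)


def _r_squared(y, y_hat) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def _fit_one(name, func, x, y, p0, bounds, param_names) -> ModelFit:
    try:
        popt, _ = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        logger.warning("%s fit did not converge: %s", name, exc)
        return ModelFit(model=name, converged=False, message=str(exc))
    fit = ModelFit(
        model=name,
        params=dict(zip(param_names, (float(p) for p in popt))),
        r_squared=_r_squared(y, func(x, *popt)),
        converged=True,
    )
    return fit


def fit_degree_models(d: DegreeDistribution) -> dict:
    """Fit lognormal, power-law and exponential models; pick the best by R^2.

    Initial parameters come from log-linear pre-fits (log y ~ log x for the
    power law, log y ~ x for the exponential, y-weighted moments of log k for
    the lognormal); sigma and the amplitudes are bounded positive.
    Non-convergence is reported as a flagged fit, never an exception.
    """
    x = np.asarray(d.degrees, dtype=float)
    y = np.asarray(d.rel_freq, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct degrees to fit models")

    pos = y > 0
    log_y = np.log(y[pos])

    # power law: log y = log a + b log x
    b_pl, log_a = np.polyfit(np.log(x[pos]), log_y, 1)
    power = _fit_one(
        "power_law", _power_law, x, y,
        p0=[float(np.exp(log_a)), float(b_pl)],
        bounds=([0.0, -np.inf], [np.inf, np.inf]),
        param_names=("a", "b"),
    )

    # exponential: log y = log A + b x (y0 starts at 0)
    b_exp, log_amp = np.polyfit(x[pos], log_y, 1)
    exponential = _fit_one(
        "exponential", _exponential, x, y,
        p0=[0.0, float(np.exp(log_amp)), float(b_exp)],
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        param_names=("y0", "A", "b"),
    )

    # lognormal: y-weighted moments of log degree
    weights = y / y.sum()
    mu0 = float(np.sum(weights * np.log(x)))
    sigma0 = float(np.sqrt(np.sum(weights * (np.log(x) - mu0) ** 2))) or 1.0
    lognormal = _fit_one(
        "lognormal", _lognormal, x, y,
        p0=[0.0, mu0, sigma0, 1.0],
        bounds=([-np.inf, -np.inf, 1e-9, 0.0], [np.inf, np.inf, np.inf, np.inf]),
        param_names=("y0", "mu", "sigma", "A"),
    )

    fits = {"lognormal": lognormal, "power_law": power, "exponential": exponential}
    converged = {k: f for k, f in fits.items() if f.converged}
    best = max(converged, key=lambda k: converged[k].r_squared) if converged else None
    return {**fits, "best": best}


def joint_degree_distribution(
    net: WeightedGeneNetwork | nx.Graph,
) -> dict[tuple[int, int], int]:
    """Edge counts by unordered endpoint-degree pair; values sum to |E|."""
    graph = net.graph if isinstance(net, WeightedGeneNetwork) else net
    degree = dict(graph.degree())
    jdd: dict[tuple[int, int], int] = {}
    for u, v in graph.edges():
        key = tuple(sorted((degree[u], degree[v])))
        jdd[key] = jdd.get(key, 0) + 1
    return jdd


def knn_curve(net: WeightedGeneNetwork | nx.Graph) -> dict[int, float]:
    """Mean neighbour degree per degree class (absent degrees are skipped)."""
    graph = net.graph if isinstance(net, WeightedGeneNetwork) else net
    degree = dict(graph.degree())
    per_degree: dict[int, list[float]] = {}
    for node, k in degree.items():
        if k == 0:
            continue
        mean_nbr = sum(degree[n] for n in graph.neighbors(node)) / k
        per_degree.setdefault(k, []).append(mean_nbr)
    return {k: sum(v) / len(v) for k, v in sorted(per_degree.items())}


def pearson_degree_correlation(net: WeightedGeneNetwork | nx.Graph) -> float:
    """Pearson correlation of endpoint degrees over all edges (assortativity).

    Each undirected edge contributes both orderings.  A zero-variance degree
    sequence (e.g. a k-regular graph) is degenerate; 0 is returned with a
    warning rather than NaN.
    """
    graph = net.graph if isinstance(net, WeightedGeneNetwork) else net
    if graph.number_of_edges() == 0:
        raise ValueError("Pearson degree correlation undefined on an edgeless network")
    degree = dict(graph.degree())
    x, y = [], []
    for u, v in graph.edges():
        x.extend((degree[u], degree[v]))
        y.extend((degree[v], degree[u]))
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if np.std(x_arr) == 0.0:
        logger.warning("degenerate (regular) degree sequence; PDC reported as 0")
        return 0.0
    return float(np.corrcoef(x_arr, y_arr)[0, 1])
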