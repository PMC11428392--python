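"""External graphical-model refinement: blob candidates, t-distribution
costs, loopy belief propagation.

Landmark candidates are blob peaks (Laplacian of Gaussian) extracted from
each predicted heatmap and ranked by peak intensity; normalized peaks below
a threshold are discarded. Pairwise costs on each topology edge combine a
location-scale t-distribution fitted to training distances with
scale-invariant ratio terms against a fixed set of three reference edges
(the edges with the smallest fitted scale). The resulting pairwise MRF is
approximately solved with synchronous sum-product loopy belief propagation
and each landmark takes the candidate with maximal belief.

This refiner is a separate post-processing step: it is not differentiable
and cannot be trained end-to-end with the localizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.feature import blob_log

from .landmarks import LandmarkSet
from .topology import Topology

SIGMA_FLOOR_PX = 1e-2


@dataclass
class Candidate:
    location: tuple[float, float]  # (u, v)
    peak: float
    norm_peak: float = 0.0


def extract_candidates(
    heatmap: np.ndarray,
    max_n: int = 25,
    min_norm_peak: float = 0.015,
    log_sigmas: tuple[float, ...] = (2.0, 3.0, 4.0),
) -> list[Candidate]:
    """Multiscale LoG blob peaks, top ``max_n`` by peak intensity, with
    normalized peaks below ``min_norm_peak`` discarded. Empty heatmaps (no
    blobs) yield an empty list and the caller falls back to the argmax."""
    h = np.asarray(heatmap, dtype=float)
    peak = h.max()
    if not np.isfinite(peak) or peak <= 0:
        return []
    blobs = blob_log(
        h / peak,
        min_sigma=min(log_sigmas),
        max_sigma=max(log_sigmas),
        num_sigma=len(log_sigmas),
        threshold=0.005,  # detection floor, below the norm-peak threshold
    )
    cands = []
    for v, u, _s in blobs:
        cands.append(Candidate((float(u), float(v)), float(h[int(v), int(u)])))
    cands.sort(key=lambda c: -c.peak)
    cands = cands[:max_n]
    total = sum(c.peak for c in cands)
    if total <= 0:
        return []
    kept = []
    for c in cands:
        c.norm_peak = c.peak / total
        if c.norm_peak >= min_norm_peak:
            kept.append(c)
    return kept


@dataclass(frozen=True)
class EdgeStats:
    edge: tuple[int, int]
    mu: float
    sigma: float
    dof: float

    def logpdf(self, d: np.ndarray) -> np.ndarray:
        return stats.t.logpdf(d, self.dof, loc=self.mu, scale=self.sigma)


def fit_edge_stats(
    landmark_sets: list[LandmarkSet], topology: Topology, n_reference: int = 3
) -> tuple[dict[tuple[int, int], EdgeStats], list[tuple[int, int]]]:
    """Per-edge location-scale t fit to training pixel distances; also
    returns the ``n_reference`` edges with the lowest fitted scale."""
    if len(landmark_sets) < 3:
        raise ValueError("need at least 3 training images")
    out: dict[tuple[int, int], EdgeStats] = {}
    for e in sorted(tuple(sorted(pair)) for pair in topology.edges):
        i, j = e
        d = np.array([
            np.linalg.norm(lms.get(i) - lms.get(j))
            for lms in landmark_sets
            if lms.visible[i - 1] and lms.visible[j - 1]
        ])
        if d.std() < 1e-9:
            mu, sigma, dof = float(d.mean()), SIGMA_FLOOR_PX, 10.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dof, mu, sigma = stats.t.fit(d)
            sigma = max(float(sigma), SIGMA_FLOOR_PX)
            dof = float(np.clip(dof, 1.0, 1e6))
        out[e] = EdgeStats(e, float(mu), sigma, dof)
    reference = sorted(out, key=lambda e: out[e].sigma)[:n_reference]
    return out, reference


def _ratio_cost(
    es: EdgeStats, d_e: float, ref_stats: list[EdgeStats], d_refs: list[float]
) -> float:
    """Scale-invariant term: rescale d_e by mu_f/d_f for each reference edge
    f and score it under edge e's fitted distribution, averaged over the
    references. Multiplying every coordinate by c > 0 leaves d_e/d_f, hence
    the cost, unchanged."""
    vals = [
        es.logpdf(d_e * rs.mu / max(d_f, 1e-9))
        for rs, d_f in zip(ref_stats, d_refs)
    ]
    return float(np.mean(vals))


def solve_mrf(
    candidates: dict[int, list[Candidate]],
    edge_stats: dict[tuple[int, int], EdgeStats],
    topology: Topology,
    reference_edges: list[tuple[int, int]] | None = None,
    scale: float = 1.0,
    damping: float = 0.5,
    max_iters: int = 100,
    tol: float = 1e-6,
) -> tuple[dict[int, np.ndarray], bool]:
    """Sum-product LBP over the candidate MRF; returns per-landmark
    normalized marginal beliefs (exact on trees) and a convergence flag.

    Unary potentials are the normalized blob peaks; pairwise potentials
    combine the t-distribution distance term with the reference-edge ratio
    terms, the two families rescaled once per image so their empirical
    ranges are equally important. ``scale`` converts candidate pixel
    distances to the units the edge statistics were fitted in.
    """
    nodes = sorted(candidates)
    for i in nodes:
        if not candidates[i]:
            raise ValueError(f"landmark {i} has no candidates")
    edges = sorted(
        tuple(sorted(e)) for e in topology.edges
        if all(k in candidates for k in e)
    )

    # current-best distances on the reference edges, for the ratio terms
    ref_stats, d_refs = [], []
    if reference_edges:
        for f in reference_edges:
            a, b = f
            ca = max(candidates[a], key=lambda c: c.peak)
            cb = max(candidates[b], key=lambda c: c.peak)
            ref_stats.append(edge_stats[tuple(sorted(f))])
            d_refs.append(
                scale * float(np.hypot(ca.location[0] - cb.location[0],
                                       ca.location[1] - cb.location[1]))
            )

    # pairwise log-potential tables, built once
    dist_terms: dict[tuple[int, int], np.ndarray] = {}
    ratio_terms: dict[tuple[int, int], np.ndarray] = {}
    for e in edges:
        i, j = e
        es = edge_stats[e]
        pi = np.array([c.location for c in candidates[i]])
        pj = np.array([c.location for c in candidates[j]])
        d = scale * np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
        dist_terms[e] = es.logpdf(d)
        if ref_stats:
            ratio_terms[e] = np.vectorize(
                lambda dd: _ratio_cost(es, dd, ref_stats, d_refs)
            )(d)
        else:
            ratio_terms[e] = np.zeros_like(d)

    # weight the two families to be equally important (matched ranges)
    def _range(tables):
        vals = np.concatenate([t.ravel() for t in tables.values()])
        return float(vals.max() - vals.min())

    r_dist, r_ratio = _range(dist_terms), _range(ratio_terms)
    w_ratio = (r_dist / r_ratio) if (r_ratio > 1e-12 and r_dist > 1e-12) else 1.0
    log_psi = {e: dist_terms[e] + w_ratio * ratio_terms[e] for e in edges}

    log_phi = {
        i: np.log(np.array([max(c.norm_peak, 1e-300) for c in candidates[i]]))
        for i in nodes
    }

    # sum-product messages in the log domain, synchronous with damping
    msgs: dict[tuple[int, int], np.ndarray] = {}
    for i, j in edges:
        msgs[(i, j)] = np.zeros(len(candidates[j]))
        msgs[(j, i)] = np.zeros(len(candidates[i]))
    neigh = {i: [] for i in nodes}
    for i, j in edges:
        neigh[i].append(j)
        neigh[j].append(i)

    def _logsumexp(a, axis):
        m = a.max(axis=axis, keepdims=True)
        return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)

    converged = False
    for _ in range(max_iters):
        new: dict[tuple[int, int], np.ndarray] = {}
        delta = 0.0
        for (i, j), old in msgs.items():
            e = tuple(sorted((i, j)))
            psi = log_psi[e] if e == (i, j) else log_psi[e].T
            incoming = log_phi[i] + sum(
                msgs[(k, i)] for k in neigh[i] if k != j
            )
            m = _logsumexp(psi + incoming[:, None], axis=0)
            m = m - m.max()
            m = damping * old + (1.0 - damping) * m
            delta = max(delta, float(np.abs(m - old).max()))
            new[(i, j)] = m
        msgs = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("loopy belief propagation did not converge; "
                      "returning current beliefs")

    result: dict[int, np.ndarray] = {}
    for i in nodes:
        b = log_phi[i] + sum(msgs[(k, i)] for k in neigh[i])
        b = np.exp(b - b.max())
        result[i] = b / b.sum()
    return result, converged


def save_edge_stats(
    stats_map: dict[tuple[int, int], EdgeStats],
    reference: list[tuple[int, int]],
    path,
) -> None:
    """Persist fitted edge statistics and the reference-edge set as JSON."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps({
        "edges": {f"{i}-{j}": [es.mu, es.sigma, es.dof]
                  for (i, j), es in stats_map.items()},
        "reference": [list(e) for e in reference],
    }))


def load_edge_stats(path):
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    stats_map = {}
    for key, (mu, sigma, dof) in d["edges"].items():
        i, j = (int(x) for x in key.split("-"))
        stats_map[(i, j)] = EdgeStats((i, j), mu, sigma, dof)
    return stats_map, [tuple(e) for e in d["reference"]]


def refine(
    candidates: dict[int, list[Candidate]],
    edge_stats: dict[tuple[int, int], EdgeStats],
    topology: Topology,
    **kwargs,
) -> dict[int, tuple[float, float]]:
    """Max-marginal candidate location per landmark."""
    marg, _ = solve_mrf(candidates, edge_stats, topology, **kwargs)
    return {
        i: candidates[i][int(np.argmax(marg[i]))].location for i in marg
    }
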