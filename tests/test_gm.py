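"""Graphical-model refinement: blob candidates, t-distribution fits, and
loopy belief propagation checked against exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats

from landloc.gm import (
    Candidate, EdgeStats, extract_candidates, fit_edge_stats, refine, solve_mrf,
)
from landloc.heatmaps import BlobConfig, render_target
from landloc.landmarks import LandmarkSet
from landloc.topology import Topology


def _topo(n, edges):
    return Topology(n, frozenset(frozenset(e) for e in edges), frozenset())


class TestExtractCandidates:
    def test_two_rendered_blobs_found(self):
        hm = (render_target((40, 40), (128, 128), BlobConfig(sigma=3))
              + render_target((90, 90), (128, 128), BlobConfig(sigma=3)))
        cands = extract_candidates(hm)
        assert len(cands) == 2
        locs = sorted(c.location for c in cands)
        assert np.allclose(locs, [(40, 40), (90, 90)], atol=1.0)

    def test_normalized_peaks_and_threshold(self):
        hm = (render_target((30, 30), (128, 128), BlobConfig(sigma=3, gamma=0.98))
              + render_target((90, 90), (128, 128), BlobConfig(sigma=3, gamma=0.01)))
        cands = extract_candidates(hm, min_norm_peak=0.0)
        peaks = sorted((c.norm_peak for c in cands), reverse=True)
        assert peaks[0] == pytest.approx(0.98 / 0.99, abs=0.01)
        assert sum(peaks) == pytest.approx(1.0)
        # with the default threshold a 1:100 peak ratio drops the weak blob
        hm2 = (render_target((30, 30), (128, 128), BlobConfig(sigma=3, gamma=1.0))
               + render_target((90, 90), (128, 128), BlobConfig(sigma=3, gamma=0.01)))
        kept = extract_candidates(hm2, min_norm_peak=0.015)
        assert len(kept) == 1

    def test_flat_heatmap_returns_empty(self):
        assert extract_candidates(np.zeros((64, 64))) == []


class TestEdgeStats:
    def test_t_parameter_recovery(self):
        rng = np.random.default_rng(0)
        d = stats.t.rvs(5, loc=40.0, scale=2.0, size=500, random_state=rng)
        # wrap the sample as distances of a 2-landmark dataset
        sets = []
        for dist in d:
            coords = np.array([[0.0, 0.0], [dist, 0.0]])
            sets.append(LandmarkSet(coords))
        es, refs = fit_edge_stats(sets, _topo(2, [(1, 2)]), n_reference=1)
        stat = es[(1, 2)]
        assert stat.mu == pytest.approx(40.0, abs=0.5)
        assert stat.sigma == pytest.approx(2.0, abs=0.5)
        assert refs == [(1, 2)]

    def test_rigid_dataset_floors_sigma(self):
        sets = [LandmarkSet(np.array([[0.0, 0.0], [30.0, 0.0], [30.0, 40.0]]))
                for _ in range(10)]
        es, refs = fit_edge_stats(sets, _topo(3, [(1, 2), (2, 3)]))
        assert all(s.sigma == pytest.approx(1e-2) for s in es.values())
        assert len(refs) == 2  # only two edges exist

    def test_reference_set_size_default_three(self):
        rng = np.random.default_rng(1)
        topo = _topo(5, [(1, 2), (2, 3), (3, 4), (4, 5), (1, 5)])
        sets = [LandmarkSet(rng.normal(scale=30, size=(5, 2)) + 100)
                for _ in range(40)]
        _, refs = fit_edge_stats(sets, topo)
        assert len(refs) == 3


def _enumerate_marginals(candidates, edge_stats, topo, log_psi_fn):
    """Exact marginals by summing the joint over all assignments."""
    nodes = sorted(candidates)
    sizes = [len(candidates[i]) for i in nodes]
    edges = sorted(tuple(sorted(e)) for e in topo.edges)
    marg = {i: np.zeros(s) for i, s in zip(nodes, sizes)}
    for assign in itertools.product(*[range(s) for s in sizes]):
        lp = 0.0
        for i, a in zip(nodes, assign):
            lp += np.log(candidates[i][a].norm_peak)
        for (i, j) in edges:
            ai = assign[nodes.index(i)]
            aj = assign[nodes.index(j)]
            lp += log_psi_fn(i, j, ai, aj)
        p = np.exp(lp)
        for i, a in zip(nodes, assign):
            marg[i][a] += p
    return {i: m / m.sum() for i, m in marg.items()}


def _random_problem(rng, topo, n_cand=3, spread=40.0):
    candidates = {}
    for i in range(1, topo.n_landmarks + 1):
        peaks = rng.uniform(0.2, 1.0, size=n_cand)
        peaks /= peaks.sum()
        candidates[i] = [
            Candidate(tuple(rng.uniform(0, 100, 2)), p, p) for p in peaks
        ]
    edge_stats = {
        tuple(sorted(e)): EdgeStats(tuple(sorted(e)), mu=rng.uniform(20, 60),
                                    sigma=rng.uniform(2, 8), dof=5.0)
        for e in topo.edges
    }
    return candidates, edge_stats


class TestLoopyBeliefPropagation:
    @pytest.mark.parametrize("edges,n", [
        ([(1, 2), (2, 3), (3, 4), (3, 5)], 5),          # tree
        ([(1, 2), (2, 3), (2, 4), (4, 5), (4, 6)], 6),  # tree
    ])
    def test_exact_on_trees(self, edges, n):
        """LBP marginals equal brute-force enumeration on tree graphs."""
        rng = np.random.default_rng(0)
        topo = _topo(n, edges)
        candidates, edge_stats = _random_problem(rng, topo, n_cand=4)
        marg, converged = solve_mrf(candidates, edge_stats, topo,
                                    reference_edges=None)
        assert converged

        def log_psi(i, j, ai, aj):
            es = edge_stats[tuple(sorted((i, j)))]
            pi = np.array(candidates[i][ai].location)
            pj = np.array(candidates[j][aj].location)
            return float(es.logpdf(np.linalg.norm(pi - pj)))

        exact = _enumerate_marginals(candidates, edge_stats, topo, log_psi)
        for i in marg:
            assert np.allclose(marg[i], exact[i], atol=1e-6)

    def test_single_candidate_returned_unchanged(self):
        topo = _topo(3, [(1, 2), (2, 3)])
        candidates = {
            i: [Candidate((float(i), 0.0), 1.0, 1.0)] for i in (1, 2, 3)
        }
        edge_stats = {e: EdgeStats(e, 1.0, 1.0, 5.0)
                      for e in [(1, 2), (2, 3)]}
        out = refine(candidates, edge_stats, topo)
        assert out == {1: (1.0, 0.0), 2: (2.0, 0.0), 3: (3.0, 0.0)}

    def test_planted_outlier_rejected_on_chain(self):
        """A high-peak but anatomically impossible candidate loses to the
        plausible one on a 5-landmark chain."""
        topo = _topo(5, [(1, 2), (2, 3), (3, 4), (4, 5)])
        candidates = {}
        for i in range(1, 6):
            true_loc = (20.0 * i, 0.0)
            candidates[i] = [Candidate(true_loc, 0.6, 0.6)]
            if i == 3:
                # planted outlier: higher peak, 300 px away
                candidates[i] = [Candidate((360.0, 0.0), 0.9, 0.9),
                                 Candidate(true_loc, 0.1, 0.1)]
        edge_stats = {e: EdgeStats(e, mu=20.0, sigma=2.0, dof=5.0)
                      for e in [(1, 2), (2, 3), (3, 4), (4, 5)]}
        out = refine(candidates, edge_stats, topo)
        assert out[3] == (60.0, 0.0)

    def test_missing_candidates_rejected(self):
        topo = _topo(2, [(1, 2)])
        with pytest.raises(ValueError):
            solve_mrf({1: [], 2: [Candidate((0, 0), 1, 1)]},
                      {(1, 2): EdgeStats((1, 2), 1, 1, 5)}, topo)


def test_edge_stats_json_round_trip(tmp_path):
    from landloc.gm import load_edge_stats, save_edge_stats

    stats_map = {(1, 2): EdgeStats((1, 2), 30.0, 3.0, 5.0),
                 (2, 3): EdgeStats((2, 3), 40.0, 2.0, 7.0)}
    save_edge_stats(stats_map, [(2, 3)], tmp_path / "es.json")
    back, refs = load_edge_stats(tmp_path / "es.json")
    assert back == stats_map and refs == [(2, 3)]


def test_ratio_costs_invariant_to_global_rescaling():
    """Multiplying all candidate coordinates by c leaves the refined choice
    unchanged when only ratio terms discriminate."""
    topo = _topo(3, [(1, 2), (2, 3), (1, 3)])
    edge_stats = {e: EdgeStats(e, mu=30.0, sigma=3.0, dof=5.0)
                  for e in [(1, 2), (2, 3), (1, 3)]}
    results = []
    for c in (1.0, 3.5):
        candidates = {
            1: [Candidate((0.0 * c, 0.0), 0.5, 0.5)],
            2: [Candidate((30.0 * c, 0.0), 0.5, 0.5)],
            3: [Candidate((30.0 * c, 30.0 * c), 0.45, 0.45),
                Candidate((90.0 * c, 90.0 * c), 0.55, 0.55)],
        }
        out = refine(candidates, edge_stats, topo,
                     reference_edges=[(1, 2)], scale=1.0)
        results.append(tuple(np.asarray(out[3]) / c))
    assert np.allclose(results[0], results[1])
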