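"""Seeded network construction, soft-power selection, TOM and module detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import neuromark.network as network
from neuromark.errors import ConfigurationError
from neuromark.network import (
    ModulePartition,
    SeededNetwork,
    detect_modules,
    filter_seeded_modules,
    seed_neighborhoods,
    select_soft_power,
    tom_from_adjacency,
    topological_overlap,
)
from neuromark.synthetic import SimConfig, generate_study

from conftest import make_study


def oracle_tom(A):
    """Triple-loop TOM computed from the definition."""
    A = A.copy().astype(float)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=0)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def _noise_net(n_nodes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    study = make_study(rng.normal(size=(n_nodes, n_samples)))
    ids = study.transcript_ids
    return SeededNetwork(ids, ids[:1], study.matrix)


class TestSeedNeighborhoods:
    def test_neighborhood_size_arithmetic(self, rng):
        study = make_study(rng.normal(size=(301, 10)))
        seed = study.transcript_ids[0]
        net = seed_neighborhoods(study, [seed], fraction=0.01)
        assert net.n_nodes == 4  # ceil(0.01 * 300) = 3 neighbours plus the seed

    def test_fraction_one_includes_everything(self, rng):
        study = make_study(rng.normal(size=(40, 8)))
        net = seed_neighborhoods(study, [study.transcript_ids[5]], fraction=1.0)
        assert net.n_nodes == 40

    def test_missing_seed_reported(self, rng):
        study = make_study(rng.normal(size=(20, 6)))
        with pytest.raises(ConfigurationError, match="NOPE"):
            seed_neighborhoods(study, ["NOPE"])

    def test_planted_module_enriched_in_seed_neighborhood(self, small_study):
        study = small_study.cns
        module = small_study.truth["modules"][0]
        net = seed_neighborhoods(study, [module[0]], fraction=0.05)
        neighbours = set(net.node_ids) - {module[0]}
        overlap = len(neighbours & set(module))
        n_total = len(study.transcript_ids) - 1
        p = stats.hypergeom.sf(overlap - 1, n_total, len(module) - 1, len(neighbours))
        assert p < 0.01


class TestSoftPower:
    def test_seeded_modular_network_reaches_scale_free_target(self):
        # hub-bearing module plus background at transcriptome-like width:
        # the composition seeded neighborhoods produce
        from neuromark.screen import screen_pathology_correlates

        study = generate_study(
            SimConfig(n_transcripts=2000, module_sizes=(65, 50, 45), n_samples_cns=12, seed=11)
        )
        res = screen_pathology_correlates(study.cns, alpha=0.01)
        seeds = [r.transcript_id for r in res if r.selected]
        net = seed_neighborhoods(study.cns, seeds)
        scan = select_soft_power(net)
        assert scan.reached_target
        assert scan.chosen_power <= 12
        assert max(scan.scale_free_r2) >= 0.8

    def test_noise_network_exercises_warning_path(self):
        net = _noise_net(60, 30, seed=1)
        with pytest.warns(RuntimeWarning, match="no candidate power"):
            scan = select_soft_power(net, r2_target=0.999)
        assert not scan.reached_target

    def test_tie_broken_toward_smallest_power(self, monkeypatch):
        monkeypatch.setattr(network, "_scale_free_r2", lambda k: 0.5)
        net = _noise_net(40, 10)
        with pytest.warns(RuntimeWarning):
            scan = select_soft_power(net, powers=[2, 3, 4], r2_target=0.8)
        assert scan.chosen_power == 2

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigurationError):
            select_soft_power(_noise_net(10, 8))


class TestTopologicalOverlap:
    def test_three_node_hand_computation(self):
        # correlations 0.9, 0.8, 0.0 at beta = 2 -> adjacency 0.81, 0.64, 0
        A = np.array([[0.0, 0.81, 0.64], [0.81, 0.0, 0.0], [0.64, 0.0, 0.0]])
        tom = tom_from_adjacency(A)
        assert tom[0, 1] == pytest.approx(0.81 / (0.81 + 1 - 0.81))
        assert tom[0, 2] == pytest.approx(0.64 / (0.64 + 1 - 0.64))
        assert tom[1, 2] == pytest.approx((0.81 * 0.64) / (0.64 + 1.0))
        assert np.allclose(np.diag(tom), 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = _noise_net(n_nodes=30, n_samples=12, seed=seed)
        tom = topological_overlap(net, beta=6)
        A = np.abs(net.correlation()) ** 6
        assert np.max(np.abs(tom - oracle_tom(A))) < 1e-10
        assert tom.min() >= 0 and tom.max() <= 1

    def test_identical_profiles_have_unit_overlap(self):
        # duplicated profile among otherwise-orthogonal nodes: by the TOM
        # formula the duplicated pair overlaps maximally (weighted TOM of a
        # duplicated pair reaches 1 exactly when its remaining neighbour
        # weights vanish)
        X = np.array(
            [
                [1.0, -1.0, 1.0, -1.0],
                [1.0, -1.0, 1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [1.0, -1.0, -1.0, 1.0],
            ]
        )
        study = make_study(X)
        net = SeededNetwork(study.transcript_ids, study.transcript_ids[:1], study.matrix)
        tom = topological_overlap(net, beta=2)
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_profiles_have_zero_overlap(self):
        X = np.array(
            [
                [1.0, -1.0, 1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [1.0, -1.0, -1.0, 1.0],
            ]
        )
        study = make_study(X)
        net = SeededNetwork(study.transcript_ids, study.transcript_ids[:1], study.matrix)
        tom = topological_overlap(net, beta=2)
        off = tom[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)


class TestDetectModules:
    def _constructed_network(self, seed=0):
        cfg = SimConfig(
            n_transcripts=300, module_sizes=(55, 45, 40), n_samples_cns=12, seed=seed
        )
        study = generate_study(cfg)
        planted = [t for ts in study.truth["modules"].values() for t in ts]
        rng = np.random.default_rng(seed + 500)
        noise = [t for t in study.cns.transcript_ids if t not in set(planted)]
        ids = planted + list(rng.choice(noise, size=60, replace=False))
        net = SeededNetwork(ids, ids[:1], study.cns.matrix.loc[ids])
        truth = np.array([study.truth["assignment"].get(t, -1) for t in ids])
        return net, truth

    def test_recovers_three_planted_modules(self):
        from sklearn.metrics import adjusted_rand_score

        net, truth = self._constructed_network(seed=1)
        tom = topological_overlap(net, beta=6)
        part = detect_modules(tom, net.node_ids)
        pred = np.array([part.assignment[t] for t in net.node_ids])
        assert len(part.module_numbers) >= 3
        # recovery judged on the planted nodes; background co-clustering at
        # n = 12 samples reflects chance correlation, not detection quality
        planted = truth >= 0
        assert adjusted_rand_score(truth[planted], pred[planted]) >= 0.8

    def test_noise_network_mostly_unassigned(self):
        net = _noise_net(120, 12, seed=4)
        tom = topological_overlap(net, beta=6)
        part = detect_modules(tom, net.node_ids)
        unassigned = sum(1 for m in part.assignment.values() if m == 0)
        assert unassigned >= 0.6 * net.n_nodes

    def test_tiny_network_warns_and_unassigns(self):
        tom = np.eye(2)
        with pytest.warns(RuntimeWarning, match="below min_module_size"):
            part = detect_modules(tom, ["a", "b"], min_module_size=30)
        assert set(part.assignment.values()) == {0}

    def test_partition_invariant_to_node_order(self):
        from sklearn.metrics import adjusted_rand_score

        net, _ = self._constructed_network(seed=2)
        tom = topological_overlap(net, beta=6)
        part1 = detect_modules(tom, net.node_ids)

        rng = np.random.default_rng(0)
        perm = rng.permutation(net.n_nodes)
        ids2 = [net.node_ids[i] for i in perm]
        tom2 = tom[np.ix_(perm, perm)]
        part2 = detect_modules(tom2, ids2)
        a = [part1.assignment[t] for t in net.node_ids]
        b = [part2.assignment[t] for t in net.node_ids]
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_modules_numbered_by_decreasing_size(self):
        net, _ = self._constructed_network(seed=3)
        tom = topological_overlap(net, beta=6)
        part = detect_modules(tom, net.node_ids)
        sizes = [part.module_sizes[m] for m in part.module_numbers]
        assert sizes == sorted(sizes, reverse=True)


class TestFilterSeededModules:
    def test_bookkeeping(self):
        assignment = {f"t{i}": (i % 5) + 1 for i in range(50)}
        part = ModulePartition(assignment)
        seeds = ["t0", "t6"]  # modules 1 and 2
        kept = filter_seeded_modules(part, seeds)
        assert set(kept.module_numbers) == {1, 2}
        assert all(m in (0, 1, 2) for m in kept.assignment.values())
        assert kept.seeded_flags == {1: True, 2: True}

    def test_no_seeded_modules_warns(self):
        part = ModulePartition({"a": 1, "b": 1, "c": 2})
        with pytest.warns(RuntimeWarning, match="no module contains a seed"):
            kept = filter_seeded_modules(part, ["zzz"])
        assert kept.module_numbers == []

    def test_end_to_end_pathology_module_survives(self, small_study):
        from neuromark.screen import screen_pathology_correlates

        res = screen_pathology_correlates(small_study.cns, alpha=0.01)
        seeds = [r.transcript_id for r in res if r.selected]
        net = seed_neighborhoods(small_study.cns, seeds)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scan = select_soft_power(net)
        tom = topological_overlap(net, scan.chosen_power)
        part = filter_seeded_modules(detect_modules(tom, net.node_ids), seeds)
        immune = set(small_study.truth["seed_transcripts"])
        # the planted pathology module survives inside one seeded module
        best = max(
            (len(immune & set(part.members(m))) for m in part.module_numbers), default=0
        )
        assert best >= 0.6 * len(immune & set(net.node_ids))
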