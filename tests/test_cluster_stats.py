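"""Cluster statistics: t maps, pruning, connected components, permutation p."""

import itertools

import numpy as np
import pytest
from scipy import stats

import oddwave as ow
from oddwave.cluster_stats import _masses, _prune_mask, _cluster_labels


# ---------------------------------------------------------------------------
# Brute-force oracle: prune by neighbor count, then flood-fill
# ---------------------------------------------------------------------------


def oracle_masses(tvals, mask, adjacency, minnbchan):
    n_ch, n_s = mask.shape
    pruned = np.zeros_like(mask)
    for c in range(n_ch):
        for s in range(n_s):
            if not mask[c, s]:
                continue
            nb = sum(mask[o, s] for o in range(n_ch) if adjacency[c, o])
            pruned[c, s] = nb >= minnbchan
    seen = np.zeros_like(pruned)
    masses = []
    for c in range(n_ch):
        for s in range(n_s):
            if pruned[c, s] and not seen[c, s]:
                stack, total = [(c, s)], 0.0
                seen[c, s] = True
                while stack:
                    ci, si = stack.pop()
                    total += tvals[ci, si]
                    for cj in range(n_ch):
                        if adjacency[ci, cj] and pruned[cj, si] and not seen[cj, si]:
                            seen[cj, si] = True
                            stack.append((cj, si))
                    for sj in (si - 1, si + 1):
                        if 0 <= sj < n_s and pruned[ci, sj] and not seen[ci, sj]:
                            seen[ci, sj] = True
                            stack.append((ci, sj))
                masses.append(total)
    return sorted(masses)


def tmap_from(tvals, channel_names, tail="negative", df=9):
    return ow.TStatMap(
        tvals=np.asarray(tvals, float), df=df,
        times=np.arange(np.asarray(tvals).shape[1], dtype=float),
        channel_names=channel_names,
        window_ms=(0.0, float(np.asarray(tvals).shape[1] - 1)), tail=tail)


class TestPairedTMap:
    def test_hand_computed_t(self):
        d = np.array([-1.0, -2.0, -3.0]).reshape(3, 1, 1)
        tmap = ow.paired_t_map(d)
        assert tmap.df == 2
        assert np.isclose(tmap.tvals[0, 0], -3.4641016, atol=1e-6)

    def test_all_zero_diffs_give_t_zero_with_warning(self):
        d = np.zeros((4, 2, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            tmap = ow.paired_t_map(d)
        assert np.all(tmap.tvals == 0.0)

    def test_constant_nonzero_diffs_give_infinity_excluded_from_clusters(self, chain4):
        d = np.full((4, 4, 3), -1.0)
        with pytest.warns(UserWarning):
            tmap = ow.paired_t_map(d, channel_names=chain4.channel_names)
        assert np.all(np.isneginf(tmap.tvals))
        assert ow.extract_clusters(tmap, layout=chain4) == []

    def test_shift_moves_t_monotonically(self, rng):
        d = rng.normal(size=(8, 2, 2))
        t0 = ow.paired_t_map(d).tvals
        t1 = ow.paired_t_map(d + 0.5).tvals
        assert (t1 > t0).all()

    def test_window_restriction_sets_nan_outside(self):
        d = np.random.default_rng(0).normal(size=(5, 2, 10))
        tmap = ow.paired_t_map(d, window_ms=(3, 6))
        assert np.isnan(tmap.tvals[:, :3]).all()
        assert np.isfinite(tmap.tvals[:, 3:7]).all()

    def test_fewer_than_two_participants_rejected(self):
        with pytest.raises(ValueError):
            ow.paired_t_map(np.zeros((1, 2, 2)))


class TestExtractClusters:
    def test_chain_prune_leaves_middle_pair(self, chain4):
        # A-B-C-D all suprathreshold at one sample; with minnbchan=2 the
        # endpoints (one masked neighbor each) are pruned -> cluster {B, C}
        tvals = np.full((4, 1), -5.0)
        clusters = ow.extract_clusters(tmap_from(tvals, chain4.channel_names),
                                       cluster_alpha=0.1, minnbchan=2, layout=chain4)
        assert len(clusters) == 1
        assert sorted(ch for ch, _ in clusters[0].members) == ["B", "C"]
        assert np.isclose(clusters[0].mass, -10.0)
        assert clusters[0].sign == -1

    def test_complete_triangle_survives_pruning(self):
        lay = ow.make_layout("complete-3")
        tvals = np.full((3, 1), -5.0)
        clusters = ow.extract_clusters(tmap_from(tvals, lay.channel_names),
                                       minnbchan=2, layout=lay)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_empty_mask_gives_no_clusters(self, chain4):
        clusters = ow.extract_clusters(tmap_from(np.zeros((4, 3)), chain4.channel_names),
                                       layout=chain4)
        assert clusters == []

    def test_minnbchan_zero_prune_is_identity(self, mesh12, rng):
        mask = rng.random((12, 5)) < 0.4
        A = mesh12.adjacency_matrix()
        assert np.array_equal(_prune_mask(mask, A, 0), mask)

    def test_temporal_adjacency_joins_lag1_only(self, chain4):
        tvals = np.zeros((4, 5))
        tvals[1, 0] = tvals[1, 1] = -5.0   # adjacent samples -> one cluster
        tvals[1, 3] = -5.0                 # gap of one sample -> separate
        clusters = ow.extract_clusters(tmap_from(tvals, chain4.channel_names),
                                       minnbchan=0, layout=chain4)
        assert sorted(len(c.members) for c in clusters) == [1, 2]

    @pytest.mark.parametrize("preset,n_s", [("chain-3", 4), ("complete-3", 4),
                                            ("chain-4", 3), ("mesh-2x2", 3)])
    def test_oracle_equivalence_all_masks(self, preset, n_s):
        """Exhaustive: cluster masses match the brute-force oracle for every
        mask of a small grid and every minnbchan."""
        lay = ow.make_layout(preset)
        n_ch = len(lay.channel_names)
        A = lay.adjacency_matrix()
        rng = np.random.default_rng(5)
        tvals = -np.abs(rng.normal(2, 1, size=(n_ch, n_s)))
        cells = n_ch * n_s
        for bits in range(2 ** cells):
            mask = np.array([(bits >> k) & 1 for k in range(cells)],
                            dtype=bool).reshape(n_ch, n_s)
            for minnb in (0, 1, 2):
                got = sorted(_masses(tvals, mask, A, minnb).tolist())
                assert np.allclose(got, oracle_masses(tvals, mask, A, minnb))


class TestPermutationTest:
    def make_effect_stack(self, n=12, seed=0, mean=-1.2, noise=0.8):
        rng = np.random.default_rng(seed)
        mesh = ow.make_layout("mesh-3x4")
        K = np.zeros((12, 30))
        K[[1, 4, 5, 6, 9], 8:20] = 1.0
        eff = rng.normal(mean, 1.0, size=n)
        data = eff[:, None, None] * K + rng.normal(0, noise, size=(n, 12, 30))
        return data, mesh

    def test_p_convention_and_floor(self):
        """Monte-Carlo p follows (r+1)/(n_perm+1); an observed mass more
        extreme than every permutation maximum gets the floor 1/(n_perm+1)."""
        data, mesh = self.make_effect_stack(n=20, seed=3, mean=-3.0, noise=0.4)
        res = ow.permutation_test(data, n_perm=999, seed=1, layout=mesh,
                                  channel_names=mesh.channel_names)
        for c in res.clusters:
            r = int(np.sum(res.null_max_mass <= c.mass))
            assert c.monte_carlo_p == pytest.approx((r + 1) / 1000)
        top = res.clusters[0]
        assert top.mass < res.null_max_mass.min()
        assert top.monte_carlo_p == pytest.approx(1 / 1000)

    def test_p_values_bounded_and_distribution_length(self):
        data, mesh = self.make_effect_stack()
        res = ow.permutation_test(data, n_perm=150, seed=2, layout=mesh,
                                  channel_names=mesh.channel_names)
        assert len(res.null_max_mass) == 150
        for c in res.clusters:
            assert 1 / 151 <= c.monte_carlo_p <= 1.0

    def test_same_seed_identical_result(self):
        data, mesh = self.make_effect_stack()
        a = ow.permutation_test(data, n_perm=100, seed=9, layout=mesh,
                                channel_names=mesh.channel_names)
        b = ow.permutation_test(data, n_perm=100, seed=9, layout=mesh,
                                channel_names=mesh.channel_names)
        assert a.to_json() == b.to_json()
        c = ow.permutation_test(data, n_perm=100, seed=10, layout=mesh,
                                channel_names=mesh.channel_names)
        assert not np.array_equal(a.null_max_mass, c.null_max_mass)

    def test_detects_planted_negative_effect(self):
        data, mesh = self.make_effect_stack(n=20, seed=7)
        res = ow.permutation_test(data, n_perm=300, seed=0, layout=mesh,
                                  channel_names=mesh.channel_names)
        assert res.min_p < 0.01
        # the winning cluster overlaps the planted channels/samples
        top = res.clusters[0]
        chans = {ch for ch, _ in top.members}
        assert chans & {"E01", "E11", "E12", "E13", "E21"}

    def test_two_sided_mode_finds_positive_effect(self):
        data, mesh = self.make_effect_stack(n=20, seed=7)
        res = ow.permutation_test(-data, n_perm=300, seed=0, layout=mesh,
                                  channel_names=mesh.channel_names, tail="two_sided")
        assert res.clusters[0].sign == 1
        assert res.min_p < 0.05

    def test_result_json_roundtrip(self, tmp_path):
        data, mesh = self.make_effect_stack()
        res = ow.permutation_test(data, n_perm=50, seed=4, layout=mesh,
                                  channel_names=mesh.channel_names)
        path = tmp_path / "clusters.json"
        res.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert payload["n_permutations"] == 50
        assert payload["config"]["minnbchan"] == 2
        assert len(payload["null_max_mass"]) == 50
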