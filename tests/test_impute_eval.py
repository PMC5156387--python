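import numpy as np
import pytest

from tagarray.impute_eval import (
    LSParams,
    ScaffoldSpec,
    _forward_backward,
    compare_scaffolds,
    impute_dosage,
    loo_accuracy,
)
from tagarray.panel_io import DataError

from conftest import make_panel
from oracles import hmm_path_posterior


class TestForwardBackward:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        s = int(rng.integers(2, 6))
        ref = rng.integers(0, 2, size=(n, s))
        obs = rng.integers(0, 2, size=s)
        p_switch = rng.uniform(0, 0.8, size=s - 1)
        eps = float(rng.uniform(0.005, 0.2))
        post = _forward_backward(ref, obs, p_switch, eps)
        oracle = hmm_path_posterior(ref, obs, p_switch, eps)
        np.testing.assert_allclose(post, oracle, atol=1e-8)

    def test_posteriors_normalized_everywhere(self):
        rng = np.random.default_rng(11)
        ref = rng.integers(0, 2, size=(50, 40))
        obs = rng.integers(0, 2, size=40)
        p_switch = rng.uniform(0, 1, size=39)
        post = _forward_backward(ref, obs, p_switch, 0.01)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_single_reference_haplotype_dominates(self):
        ref = np.array([[0, 1, 0, 1]])
        post = _forward_backward(ref, np.array([1, 0, 1, 0]), np.full(3, 0.5), 0.01)
        np.testing.assert_allclose(post, 1.0)


class TestImputeDosage:
    def test_perfect_proxy_limit_recovers_truth(self):
        # eval site duplicates a scaffold site; tiny emission error
        rng = np.random.default_rng(0)
        pattern = rng.integers(0, 2, 20)
        other = rng.integers(0, 2, 20)
        alleles = np.stack([pattern, other, pattern], axis=1)
        panel = make_panel(alleles, positions=[100, 200, 300])
        scaffold = [panel.vids[0], panel.vids[1]]
        ls = LSParams(emission_error=1e-4)
        for i in range(panel.n_samples):
            rows = np.delete(np.arange(20), [2 * i, 2 * i + 1])
            ref = make_panel(alleles[rows], positions=[100, 200, 300],
                             pops=["EUR"] * 9)
            obs = alleles[[2 * i, 2 * i + 1]][:, :2]
            dosages, flagged = impute_dosage(ref, obs, scaffold, [panel.vids[2]], ls)
            truth = alleles[2 * i, 2] + alleles[2 * i + 1, 2]
            assert dosages[panel.vids[2]] == pytest.approx(truth, abs=0.05)
            assert not flagged

    def test_eval_site_on_scaffold_returned_observed_and_flagged(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(10, 3))
        ref = make_panel(alleles, positions=[100, 200, 300], pops=["EUR"] * 5)
        obs = np.array([[0, 1, 1], [1, 0, 0]])
        dosages, flagged = impute_dosage(
            ref, obs, ref.vids, [ref.vids[1]], LSParams()
        )
        assert flagged == {ref.vids[1]}
        assert dosages[ref.vids[1]] == 1.0

    def test_no_scaffold_on_chromosome_rejected(self):
        rng = np.random.default_rng(2)
        alleles = rng.integers(0, 2, size=(10, 2))
        ref = make_panel(alleles, positions=[100, 200], pops=["EUR"] * 5)
        with pytest.raises(DataError, match="chromosome"):
            impute_dosage(ref, np.zeros((2, 0)), [], [ref.vids[0]], LSParams())

    def test_dosages_bounded(self):
        rng = np.random.default_rng(3)
        alleles = rng.integers(0, 2, size=(30, 12))
        ref = make_panel(alleles, pops=["EUR"] * 15)
        obs = rng.integers(0, 2, size=(2, 6))
        dosages, _ = impute_dosage(
            ref, obs, ref.vids[:6], ref.vids[6:], LSParams()
        )
        assert all(0.0 <= d <= 2.0 for d in dosages.values())


class TestLooAccuracy:
    def _panel(self, seed=0, n_samples=30, n_sites=24):
        rng = np.random.default_rng(seed)
        # blocky LD: duplicated columns with small noise
        base = rng.integers(0, 2, size=(2 * n_samples, n_sites // 2))
        noisy = base ^ (rng.random(base.shape) < 0.05)
        alleles = np.empty((2 * n_samples, n_sites), dtype=np.int8)
        alleles[:, 0::2] = base
        alleles[:, 1::2] = noisy
        return make_panel(alleles, positions=[200 * (j + 1) for j in range(n_sites)],
                          pops=["EUR"] * n_samples)

    def test_scaffold_eval_sites_score_perfect(self):
        panel = self._panel()
        scaffold = ScaffoldSpec("all", set(panel.vids))
        report = loo_accuracy(panel, scaffold, panel.vids[:6])
        vals = report.accuracy.loc["EUR"].dropna()
        np.testing.assert_allclose(vals, 100.0, atol=1e-9)

    def test_small_population_reported_na(self):
        rng = np.random.default_rng(4)
        alleles = rng.integers(0, 2, size=(8, 6))
        panel = make_panel(alleles, pops=["EUR", "EUR", "AFR", "AFR"])
        report = loo_accuracy(
            panel, ScaffoldSpec("s", set(panel.vids[:3])), panel.vids[3:]
        )
        assert report.accuracy.loc["AFR"].isna().all()

    def test_deterministic(self):
        panel = self._panel(seed=5)
        scaffold = ScaffoldSpec("s", set(panel.vids[::2]))
        evs = panel.vids[1::2]
        r1 = loo_accuracy(panel, scaffold, evs)
        r2 = loo_accuracy(panel, scaffold, evs)
        assert r1.accuracy.equals(r2.accuracy)

    def test_informative_scaffold_beats_null(self):
        panel = self._panel(seed=6)
        evs = panel.vids[1::2]
        informative = loo_accuracy(
            panel, ScaffoldSpec("s", set(panel.vids[0::2])), evs,
            LSParams(switch_rate=1e-5),
        )
        vals = informative.accuracy.loc["EUR"].dropna()
        assert vals.mean() > 50


class TestCompareScaffolds:
    def test_identical_scaffolds_zero_delta(self):
        panel = TestLooAccuracy()._panel(seed=7)
        sc = ScaffoldSpec("a", set(panel.vids[::2]))
        comp = compare_scaffolds(panel, sc, sc, panel.vids[1::2])
        deltas = comp.delta.values
        assert np.nanmax(np.abs(deltas)) == 0.0

    def test_subset_violation_rejected(self):
        panel = TestLooAccuracy()._panel(seed=8)
        a = ScaffoldSpec("a", set(panel.vids[:4]))
        b = ScaffoldSpec("b", set(panel.vids[4:8]))
        with pytest.raises(DataError, match="subset"):
            compare_scaffolds(panel, a, b, panel.vids[8:])

    def test_eval_overlap_rejected(self):
        panel = TestLooAccuracy()._panel(seed=9)
        a = ScaffoldSpec("a", set(panel.vids[:6]))
        b = ScaffoldSpec("b", set(panel.vids[:4]))
        with pytest.raises(DataError, match="overlap"):
            compare_scaffolds(panel, a, b, panel.vids[5:10])

    def test_perfect_proxies_drive_accuracy_to_ceiling(self):
        # adding a duplicate of every eval site pushes with-custom accuracy
        # to ~100 while the sparse scaffold stays below it
        rng = np.random.default_rng(10)
        n_eval = 8
        base = rng.integers(0, 2, size=(60, n_eval))
        far = rng.integers(0, 2, size=(60, 2))
        alleles = np.concatenate([far, base, base], axis=1)
        positions = (
            [10, 20]
            + [1_000 + 50 * j for j in range(n_eval)]       # proxies
            + [1_001 + 50 * j for j in range(n_eval)]       # adjacent eval sites
        )
        order = np.argsort(positions)
        panel = make_panel(alleles[:, order],
                           positions=sorted(positions), pops=["EUR"] * 30)
        pos_to_vid = dict(zip(sorted(positions), panel.vids))
        proxies = {pos_to_vid[1_000 + 50 * j] for j in range(n_eval)}
        evs = [pos_to_vid[1_001 + 50 * j] for j in range(n_eval)]
        sparse = {pos_to_vid[10], pos_to_vid[20]}
        comp = compare_scaffolds(
            panel,
            ScaffoldSpec("with", sparse | proxies),
            ScaffoldSpec("without", sparse),
            evs,
            LSParams(emission_error=1e-3, switch_rate=1e-3),
        )
        with_vals = comp.with_report.accuracy.loc["EUR"].dropna()
        assert with_vals.mean() > 95
        assert np.nanmean(comp.delta.values) > 0
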