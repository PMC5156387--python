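import numpy as np
import pytest

from tagarray.ld_engine import r2_matrix
from tagarray.regions import Region, merge_regions
from tagarray.tag_select import DesignParams, coverage_report, select_tags

from conftest import make_panel
from oracles import min_set_cover_size, r2_from_table

WHOLE = merge_regions([Region("1", 0, 10**6)])


def block_panel(n_blocks, sites_per_block, n_hap=100, seed=0, spacing=1_000):
    """k perfect-LD blocks: identical columns within a block, ~independent across."""
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(n_blocks):
        pattern = rng.integers(0, 2, n_hap)
        while not 0.05 < pattern.mean() < 0.95:
            pattern = rng.integers(0, 2, n_hap)
        cols.extend([pattern] * sites_per_block)
    alleles = np.stack(cols, axis=1)
    positions = [spacing * (j + 1) for j in range(alleles.shape[1])]
    panel = make_panel(alleles, positions=positions)
    # construction sanity: cross-block LD must sit below the tag threshold
    r2 = r2_matrix(alleles)
    for i in range(alleles.shape[1]):
        for j in range(alleles.shape[1]):
            if i // sites_per_block != j // sites_per_block:
                assert r2[i, j] < 0.2
    return panel


class TestSelectTags:
    def test_nothing_to_add_when_fixed_covers_all(self):
        panel = block_panel(3, 2, seed=1)
        fixed = {panel.vids[0], panel.vids[2], panel.vids[4]}  # one per block
        result = select_tags(panel, WHOLE, fixed, DesignParams())
        assert result.selected == []
        assert (result.summary["frac_ge_min_r2"] == 1.0).all()

    def test_one_tag_per_perfect_ld_block(self):
        panel = block_panel(2, 3, seed=2)
        result = select_tags(panel, WHOLE, set(), DesignParams())
        assert len(result.selected) == 2
        blocks = {panel.vid_index[v] // 3 for v in result.selected}
        assert blocks == {0, 1}

    def test_matches_exhaustive_minimum_set_cover(self):
        panel = block_panel(4, 3, seed=3)  # 12 candidate sites
        params = DesignParams()
        result = select_tags(panel, WHOLE, set(), params)
        # independent oracle: cover sets from brute-force r2
        rows = panel.pop_rows("EUR")
        n = panel.n_sites
        universe = set()
        cover_sets = []
        cols = [panel.alleles[rows, j] for j in range(n)]
        mafs = [min(c.mean(), 1 - c.mean()) for c in cols]
        targets = [t for t in range(n) if mafs[t] >= params.tag_min_maf]
        universe = set(targets)
        for c in range(n):
            covered = set()
            for t in targets:
                r2 = r2_from_table(cols[c], cols[t])
                if r2 is not None and r2 >= params.tag_min_r2:
                    covered.add(t)
            cover_sets.append(covered)
        assert len(result.selected) == min_set_cover_size(cover_sets, universe)

    def test_every_covered_pair_verified_by_ld_oracle(self):
        panel = block_panel(3, 2, n_hap=60, seed=4)
        params = DesignParams()
        result = select_tags(panel, WHOLE, {panel.vids[0]}, params)
        onarray = set(result.selected) | {panel.vids[0]}
        rows = panel.pop_rows("EUR")
        for pop, cov in result.coverage.items():
            for target, best in cov.items():
                if best < params.tag_min_r2:
                    continue
                oracle_best = max(
                    (
                        r2_from_table(
                            panel.column(target)[rows], panel.column(s)[rows]
                        )
                        or 0.0
                    )
                    for s in onarray
                )
                assert best == pytest.approx(oracle_best, abs=1e-10)
                assert oracle_best >= params.tag_min_r2

    def test_selected_bounded_by_targets_and_disjoint_from_fixed(self, two_pop_panel):
        fixed = set(two_pop_panel.vids[::7])
        result = select_tags(
            two_pop_panel, merge_regions([Region("1", 0, 10**6)]), fixed,
            DesignParams(),
        )
        assert not (set(result.selected) & fixed)
        assert len(result.selected) <= int(result.summary["n_targets"].max())

    def test_enlarging_fixed_never_increases_selection(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            params = DesignParams()
            alleles = rng.integers(0, 2, size=(40, 25))
            # add some LD structure by duplicating random columns
            for _ in range(8):
                i, j = rng.integers(0, 25, 2)
                alleles[:, j] = alleles[:, i]
            panel = make_panel(alleles, positions=[50 * (k + 1) for k in range(25)])
            small = set(rng.choice(panel.vids, size=3, replace=False))
            large = small | set(rng.choice(panel.vids, size=5, replace=False))
            n_small = len(select_tags(panel, WHOLE, small, params).selected)
            n_large = len(select_tags(panel, WHOLE, large, params).selected)
            assert n_large <= n_small

    def test_threshold_one_makes_every_target_its_own_tag(self):
        rng = np.random.default_rng(6)
        # distinct columns, all pairwise r2 < 1
        alleles = rng.integers(0, 2, size=(60, 10))
        r2 = r2_matrix(alleles)
        iu = np.triu_indices(10, 1)
        assert np.nanmax(r2[iu]) < 1.0
        panel = make_panel(alleles, positions=[100 * (k + 1) for k in range(10)])
        params = DesignParams(tag_min_r2=1.0)
        result = select_tags(panel, WHOLE, set(), params)
        rows = panel.pop_rows("EUR")
        targets = [
            v for v in panel.vids
            if min(panel.column(v)[rows].mean(), 1 - panel.column(v)[rows].mean())
            >= params.tag_min_maf
        ]
        assert sorted(result.selected) == sorted(targets)

    def test_design_score_filter_excludes_candidates(self):
        panel = block_panel(2, 2, seed=7)
        # fail the whole first block's scores: selection must still cover it
        # if possible, but cannot pick those sites
        panel.sites[0].design_score = 0.3
        panel.sites[1].design_score = 0.3
        result = select_tags(panel, WHOLE, set(), DesignParams())
        assert not {panel.vids[0], panel.vids[1]} & set(result.selected)


class TestCoverageReport:
    def test_self_coverage_is_perfect(self):
        panel = block_panel(2, 2, seed=8)
        report = coverage_report(panel, WHOLE, set(panel.vids), DesignParams())
        assert report.loc["EUR", "mean_best_r2"] == pytest.approx(1.0)
        assert report.loc["EUR", "frac_ge_enhanced_r2"] == 1.0

    def test_empty_sites_give_zero_coverage(self):
        panel = block_panel(2, 2, seed=9)
        report = coverage_report(panel, WHOLE, set(), DesignParams())
        assert report.loc["EUR", "mean_best_r2"] == 0.0
        assert report.loc["EUR", "frac_ge_min_r2"] == 0.0
        assert report.loc["EUR", "n_uncoverable"] == report.loc["EUR", "n_targets"]

    def test_agrees_with_brute_force_best_r2(self, two_pop_panel):
        panel = two_pop_panel.subset_sites(range(40))
        params = DesignParams()
        sites = set(panel.vids[::4])
        report = coverage_report(
            panel, merge_regions([Region("1", 0, 10**6)]), sites, params
        )
        for pop in ("AFR", "EUR"):
            rows = panel.pop_rows(pop)
            bests = []
            for t in panel.vids:
                col_t = panel.column(t)[rows]
                f = col_t.mean()
                if min(f, 1 - f) < params.tag_min_maf:
                    continue
                best = 0.0
                for s in sites:
                    r2 = r2_from_table(col_t, panel.column(s)[rows])
                    if r2 is not None:
                        best = max(best, r2)
                bests.append(best)
            assert report.loc[pop, "n_targets"] == len(bests)
            assert report.loc[pop, "mean_best_r2"] == pytest.approx(
                np.mean(bests), abs=1e-10
            )
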