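import math

import numpy as np
import pytest

from dmrkit import DmrCallParams, InputError, call_dmrs, call_dmrs_full
from dmrkit.caller import (Window, _Region, build_regions, call_dmcs,
                           enumerate_windows, pool_window_counts,
                           retain_and_merge, trim_to_dmcs)
from dmrkit.caller import test_windows as screen_windows

from .conftest import build_methylome, uniform_cg_pair

DEFAULTS = DmrCallParams()


class TestEnumerateWindows:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (200, [(0, 200), (50, 200), (100, 200), (150, 200)]),
            (300, [(0, 200), (50, 250), (100, 300), (150, 300), (200, 300),
                   (250, 300)]),
            (100, [(0, 100), (50, 100)]),
        ],
    )
    def test_frame_construction(self, length, expected):
        frames = list(enumerate_windows({"Chr1": length}, DEFAULTS))
        assert [(s, e) for _, s, e in frames] == expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_windows({"Chr1": 0}, DEFAULTS))


class TestPoolWindowCounts:
    def test_pooled_counts_and_level(self):
        rows_a = [("Chr1", 10, "+", "CG", 7, 3), ("Chr1", 20, "+", "CG", 3, 7)]
        rows_b = [("Chr1", 10, "+", "CG", 9, 1), ("Chr1", 20, "+", "CG", 9, 1)]
        a = build_methylome(rows_a, chrom_lengths={"Chr1": 200})
        b = build_methylome(rows_b, chrom_lengths={"Chr1": 200})
        w = pool_window_counts(a, b, ("Chr1", 0, 200), DEFAULTS)
        assert (w.meth_a, w.unmeth_a) == (10, 10)
        assert w.level_a == pytest.approx(0.5)
        assert w.level_b == pytest.approx(0.9)
        assert w.direction == "hyper" and w.n_sites == 2

    def test_low_coverage_site_excluded_from_both_pools(self):
        # covered 3x in A and 20x in B: below the per-library floor in A
        a = build_methylome([("Chr1", 10, "+", "CG", 2, 1)],
                            chrom_lengths={"Chr1": 200})
        b = build_methylome([("Chr1", 10, "+", "CG", 20, 0)],
                            chrom_lengths={"Chr1": 200})
        w = pool_window_counts(a, b, ("Chr1", 0, 200), DEFAULTS)
        assert w.n_sites == 0 and not w.testable

    def test_context_mode_filters_sites(self):
        rows = [("Chr1", 10, "+", "CG", 5, 5), ("Chr1", 20, "+", "CHH", 5, 5)]
        a = build_methylome(rows, chrom_lengths={"Chr1": 200})
        params = DmrCallParams(context_mode="CHH")
        w = pool_window_counts(a, a, ("Chr1", 0, 200), params)
        assert w.n_sites == 1


class TestTestWindows:
    def _window(self, meth_a, unmeth_a, meth_b, unmeth_b, start=0):
        w = Window("Chr1", start, start + 200, meth_a, unmeth_a, meth_b,
                   unmeth_b, n_sites=5)
        if w.level_b > w.level_a:
            w.direction = "hyper"
        elif w.level_b < w.level_a:
            w.direction = "hypo"
        return w

    def test_retains_large_significant_fold(self):
        strong = self._window(20, 180, 100, 100)  # 0.1 vs 0.5
        kept = screen_windows([strong], DEFAULTS)
        assert len(kept) == 1 and kept[0].direction == "hyper"

    def test_rejects_small_fold_despite_significance(self):
        # 0.30 vs 0.45 at heavy coverage: tiny p but fold only 1.5
        modest = self._window(300, 700, 450, 550)
        assert screen_windows([modest], DEFAULTS) == []

    def test_zero_baseline_gives_infinite_fold(self):
        zero_base = self._window(0, 200, 80, 120)
        kept = screen_windows([zero_base], DEFAULTS)
        assert len(kept) == 1

    def test_untestable_windows_excluded_from_family(self):
        empty = Window("Chr1", 0, 200)
        strong = self._window(0, 200, 80, 120, start=200)
        kept = screen_windows([empty, strong], DEFAULTS)
        assert [w.start for w in kept] == [200]


class TestRegions:
    def test_overlapping_same_direction_windows_union(self):
        rows = [("Chr1", 0, 200, "hyper", 1e-4), ("Chr1", 50, 250, "hyper", 1e-5)]
        regions = build_regions(_as_windows(rows))
        assert [(r.start, r.end) for r in regions] == [(0, 250)]
        assert regions[0].best_q == 1e-5

    def test_direction_barrier(self):
        rows = [("Chr1", 0, 200, "hyper", 1e-4), ("Chr1", 200, 400, "hypo", 1e-4)]
        regions = build_regions(_as_windows(rows))
        assert len(regions) == 2

    def test_single_window_is_its_own_region(self):
        regions = build_regions(_as_windows([("Chr1", 0, 200, "hypo", 1e-3)]))
        assert [(r.start, r.end, r.direction)
                for r in regions] == [(0, 200, "hypo")]


def _as_windows(rows):
    out = []
    for chrom, start, end, direction, q in rows:
        w = Window(chrom, start, end, 1, 1, 1, 1, n_sites=1)
        w.direction = direction
        w.q = q
        out.append(w)
    return out


class TestCallDmcs:
    def test_extreme_site_is_dmc(self):
        a = build_methylome([("Chr1", 10, "+", "CG", 0, 10)],
                            chrom_lengths={"Chr1": 200})
        b = build_methylome([("Chr1", 10, "+", "CG", 10, 0)],
                            chrom_lengths={"Chr1": 200})
        dmcs = call_dmcs(a, b, ("Chr1", 0, 200), "hyper", DEFAULTS)
        assert len(dmcs) == 1
        assert dmcs[0].p_raw == pytest.approx(2 / 184756, abs=1e-14)

    def test_balanced_site_is_not_dmc(self):
        a = build_methylome([("Chr1", 10, "+", "CG", 5, 5)],
                            chrom_lengths={"Chr1": 200})
        assert call_dmcs(a, a, ("Chr1", 0, 200), "hyper", DEFAULTS) == []

    def test_minimal_coverage_cannot_reach_significance(self):
        a = build_methylome([("Chr1", 10, "+", "CG", 3, 1)],
                            chrom_lengths={"Chr1": 200})
        b = build_methylome([("Chr1", 10, "+", "CG", 1, 3)],
                            chrom_lengths={"Chr1": 200})
        assert call_dmcs(a, b, ("Chr1", 0, 200), "hypo", DEFAULTS) == []

    def test_direction_mismatch_excluded(self):
        a = build_methylome([("Chr1", 10, "+", "CG", 0, 10)],
                            chrom_lengths={"Chr1": 200})
        b = build_methylome([("Chr1", 10, "+", "CG", 10, 0)],
                            chrom_lengths={"Chr1": 200})
        assert call_dmcs(a, b, ("Chr1", 0, 200), "hypo", DEFAULTS) == []


def _region(start, end, direction="hyper", n_dmcs=8, chrom="Chr1"):
    from dmrkit.caller import Dmc

    positions = np.linspace(start + 1, end, n_dmcs).astype(int) if n_dmcs else []
    dmcs = [Dmc(chrom, int(p), "+", "CG", 1e-4, direction)
            for p in sorted(set(positions))]
    return _Region(chrom, start, end, direction, 1e-5, dmcs)


class TestRetainAndMerge:
    def test_region_below_min_dmcs_dropped(self):
        assert retain_and_merge([_region(0, 300, n_dmcs=6)], DEFAULTS) == []

    def test_gap_99_merges_gap_100_does_not(self):
        merged = retain_and_merge(
            [_region(0, 300), _region(399, 500)], DEFAULTS
        )
        assert [(r.start, r.end) for r in merged] == [(0, 500)]
        kept = retain_and_merge([_region(0, 300), _region(400, 500)], DEFAULTS)
        assert [(r.start, r.end) for r in kept] == [(0, 300), (400, 500)]

    def test_opposite_directions_never_merge(self):
        kept = retain_and_merge(
            [_region(0, 300), _region(350, 500, direction="hypo")], DEFAULTS
        )
        assert len(kept) == 2

    def test_merge_is_order_independent(self):
        regions = [_region(0, 300), _region(350, 600), _region(1000, 1200)]
        forward = retain_and_merge(regions, DEFAULTS)
        backward = retain_and_merge(list(reversed(regions)), DEFAULTS)
        assert [(r.start, r.end, len(r.dmcs)) for r in forward] == \
               [(r.start, r.end, len(r.dmcs)) for r in backward]

    def test_merged_dmc_sets_union(self):
        merged = retain_and_merge([_region(0, 300), _region(399, 500)],
                                  DEFAULTS)
        assert len(merged[0].dmcs) == 16


class TestTrim:
    def test_trim_to_first_and_last_dmc(self, toy_pair):
        from dmrkit.caller import Dmc, _paired_sites, _qualifying

        a, b = toy_pair
        dmcs = [Dmc("Chr1", pos, "+", "CG", 1e-4, "hyper")
                for pos in range(120, 181, 10)]
        region = _Region("Chr1", 0, 500, "hyper", 1e-6, dmcs)
        qualifying = _qualifying(_paired_sites(a, b), DEFAULTS)
        dmr = trim_to_dmcs(region, qualifying, DEFAULTS)
        assert (dmr.start, dmr.end) == (119, 180)
        assert dmr.n_dmcs == 7

    def test_zero_dmcs_is_an_internal_error(self, toy_pair):
        from dmrkit.caller import _paired_sites, _qualifying

        a, b = toy_pair
        qualifying = _qualifying(_paired_sites(a, b), DEFAULTS)
        with pytest.raises(RuntimeError):
            trim_to_dmcs(_Region("Chr1", 0, 500, "hyper", 1e-6, []),
                         qualifying, DEFAULTS)


class TestCallDmrs:
    def test_self_comparison_yields_nothing(self, small_simulation):
        a = small_simulation["meth_a"]
        assert call_dmrs(a, a) == []

    def test_toy_pair_one_hyper_dmr(self, toy_pair):
        a, b = toy_pair
        dmrs = call_dmrs(a, b)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert 200 <= d.start < d.end <= 400
        assert d.n_dmcs >= 7
        assert d.start in d.dmc_positions and d.end - 1 in d.dmc_positions

    def test_swapped_samples_mirror_to_hypo(self, toy_pair):
        a, b = toy_pair
        forward = call_dmrs(a, b)
        swapped = call_dmrs(b, a)
        assert [(d.chrom, d.start, d.end, d.n_dmcs) for d in forward] == \
               [(d.chrom, d.start, d.end, d.n_dmcs) for d in swapped]
        assert {d.direction for d in swapped} == {"hypo"}

    def test_no_shared_chromosomes_is_input_error(self, make_methylome):
        a = make_methylome([("Chr1", 10, "+", "CG", 5, 5)])
        b = make_methylome([("Chr2", 10, "+", "CG", 5, 5)])
        with pytest.raises(InputError):
            call_dmrs(a, b)

    def test_deterministic_rerun(self, small_simulation):
        a, b = small_simulation["meth_a"], small_simulation["meth_b"]
        assert call_dmrs(a, b) == call_dmrs(a, b)

    def test_funnel_counts_are_consistent(self, small_simulation):
        a, b = small_simulation["meth_a"], small_simulation["meth_b"]
        res = call_dmrs_full(a, b)
        f = res.funnel
        assert f["sites_qualifying"] <= f["sites_paired"]
        assert f["windows_retained"] <= f["windows_tested"]
        assert f["regions_min_dmcs"] <= f["regions_candidate"]
        assert f["dmrs"] <= f["regions_min_dmcs"]
        assert f["dmrs"] == len(res.dmrs)

    def test_recovers_implants(self, small_simulation):
        from dmrkit import evaluate_recovery

        res = call_dmrs(small_simulation["meth_a"], small_simulation["meth_b"])
        rep = evaluate_recovery(res, small_simulation["truth"])
        assert rep.recall == 1.0 and rep.precision == 1.0


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_bp": 0},
            {"step_bp": 300},
            {"min_fold": 1.0},
            {"window_q_max": 0.0},
            {"min_cov": 0},
            {"context_mode": "CNN"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DmrCallParams(**kwargs)
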