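"""Unit and property tests for the single-cell SIP calculations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from darksip.sip import (
    ControlBaseline,
    LabelingContext,
    assign_region,
    atom_fraction_to_ratio_13C,
    atom_fraction_to_ratio_15N,
    call_enrichment,
    compare_substrates,
    compute_assimilation_rate,
    compute_baseline,
    compute_ka,
    integrate_region,
    process_roi_table,
    ratio_to_atom_fraction_13C,
    ratio_to_atom_fraction_15N,
    substrate_label_fraction,
    summarize_depth,
)


class TestAtomFractionConversions:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(0.0, 0.0), (1.0, 0.5), (0.0036765, 0.0036765 / 1.0036765)],
    )
    def test_cn_ion_ratio(self, ratio, expected):
        assert ratio_to_atom_fraction_15N(ratio) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "ratio, expected",
        [(0.0, 0.0), (2.0, 0.5), (0.0224, 0.0224 / 2.0224)],
    )
    def test_c2_dimer_ratio(self, ratio, expected):
        assert ratio_to_atom_fraction_13C(ratio) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("fn", [ratio_to_atom_fraction_15N, ratio_to_atom_fraction_13C])
    def test_negative_ratio_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-0.01)

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_cn_round_trip(self, r):
        assert atom_fraction_to_ratio_15N(ratio_to_atom_fraction_15N(r)) == pytest.approx(
            r, rel=1e-12, abs=1e-12
        )

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_c2_round_trip(self, r):
        assert atom_fraction_to_ratio_13C(ratio_to_atom_fraction_13C(r)) == pytest.approx(
            r, rel=1e-12, abs=1e-12
        )

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert ratio_to_atom_fraction_15N(lo) <= ratio_to_atom_fraction_15N(hi)


class TestBaselineAndEnrichment:
    def _rois(self, ratios, timepoint=0.0):
        return pd.DataFrame(
            {
                "roi_id": [f"c{i}" for i in range(len(ratios))],
                "site": "OO",
                "depth_m": 500.0,
                "substrate": "urea",
                "timepoint_h": timepoint,
                "ratio_15N": ratios,
            }
        )

    def test_constant_controls(self):
        b = compute_baseline(self._rois([0.003, 0.003, 0.003]), "OO", "urea")
        assert b.mean_ratio == pytest.approx(0.003)
        assert b.sd_ratio == pytest.approx(0.0, abs=1e-15)

    def test_two_cell_baseline(self):
        b = compute_baseline(self._rois([0.002, 0.004]), "OO", "urea")
        assert b.mean_ratio == pytest.approx(0.003)
        assert b.sd_ratio == pytest.approx(0.0014142, rel=1e-4)
        assert b.n_cells == 2

    def test_insufficient_controls(self):
        with pytest.raises(ValueError, match="insufficient"):
            compute_baseline(self._rois([0.003]), "OO", "urea")
        with pytest.raises(ValueError, match="insufficient"):
            compute_baseline(self._rois([0.003, 0.003], timepoint=72.0), "OO", "urea")

    def test_strict_two_sd_rule(self):
        b = ControlBaseline("OO", "urea", "15N", mean_ratio=0.003, sd_ratio=0.0005, n_cells=10)
        assert not call_enrichment(0.003 + 2.0 * 0.0005, b)  # boundary is not enriched
        assert call_enrichment(0.003 + 2.01 * 0.0005, b)
        assert not call_enrichment(0.002, b)


class TestLabelFraction:
    def test_undiluted_label(self):
        ctx = LabelingContext(amendment_nM=50, label_purity=0.98, ambient_nM=0)
        assert substrate_label_fraction(ctx) == pytest.approx(0.98)

    def test_equal_pool_dilution(self):
        ctx = LabelingContext(
            amendment_nM=50, label_purity=0.98, ambient_nM=50, n_per_molecule=1
        )
        assert substrate_label_fraction(ctx) == pytest.approx(0.4918315, rel=1e-6)

    def test_unlabeled_amendment_is_inert(self):
        for ambient in (0.0, 25.0, 400.0):
            ctx = LabelingContext(
                amendment_nM=50, label_purity=0.003663, ambient_nM=ambient
            )
            assert substrate_label_fraction(ctx) == pytest.approx(0.003663)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            substrate_label_fraction(LabelingContext(amendment_nM=0, ambient_nM=0))


class TestKaAndRate:
    def test_no_excess_is_zero(self):
        assert compute_ka(0.0037, 0.0037, 0.49, 72.0) == 0.0

    def test_full_turnover_in_one_day(self):
        assert compute_ka(0.49, 0.0037, 0.49, 24.0) == pytest.approx(1.0)

    def test_worked_example(self):
        assert compute_ka(0.0525, 0.0037, 0.49183, 72.0) == pytest.approx(0.03332, rel=1e-3)

    def test_negative_excess_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_ka(0.0030, 0.0037, 0.49, 72.0) == 0.0

    def test_no_label_contrast(self):
        with pytest.raises(ValueError, match="label contrast"):
            compute_ka(0.01, 0.5, 0.4, 72.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_homogeneity_in_label_contrast(self, scale):
        """Scaling all excesses above x0 by one factor leaves Ka unchanged."""
        x0, dx_cell, dx_sub, t = 0.0037, 0.02, 0.49, 72.0
        base = compute_ka(x0 + dx_cell, x0, x0 + dx_sub, t)
        scaled = compute_ka(x0 + scale * dx_cell, x0, x0 + scale * dx_sub, t)
        assert scaled == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize(
        "ka, content, expected",
        [(0.0, 10.0, 0.0), (1.0, 24.0, 1.0), (0.03333, 10.0, 0.0138875)],
    )
    def test_assimilation_rate(self, ka, content, expected):
        assert compute_assimilation_rate(ka, content) == pytest.approx(expected, rel=1e-4)


def _cell_results(enriched_flags, rates):
    n = len(enriched_flags)
    return pd.DataFrame(
        {
            "roi_id": [f"c{i}" for i in range(n)],
            "site": "OO",
            "depth_m": 50.0,
            "substrate": "urea",
            "timepoint_h": 72.0,
            "enriched": enriched_flags,
            "atom_fraction": 0.01,
            "atom_fraction_excess": 0.006,
            "ka_per_day": np.asarray(rates) * 24.0 / 10.0,
            "rate_fg_per_cell_h": rates,
        }
    )


class TestDepthSummary:
    def test_nine_of_ten_enriched(self):
        res = _cell_results([True] * 9 + [False], [0.01] * 10)
        s = summarize_depth(res)
        assert s.loc[0, "pct_enriched"] == pytest.approx(90.0)

    def test_no_enrichment_means_missing_rate(self):
        s = summarize_depth(_cell_results([False] * 5, [0.0] * 5))
        assert s.loc[0, "pct_enriched"] == 0.0
        assert np.isnan(s.loc[0, "mean_rate_enriched"])

    def test_equal_rates_mean(self):
        s = summarize_depth(_cell_results([True] * 4, [0.02] * 4))
        assert s.loc[0, "mean_rate_enriched"] == pytest.approx(0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_depth(_cell_results([], []))


class TestRegionIntegration:
    def test_region_assignment_half_open(self):
        assert assign_region(0.0) == "epipelagic"
        assert assign_region(200.0) == "mesopelagic"
        assert assign_region(1000.0) == "bathypelagic"
        with pytest.raises(ValueError):
            assign_region(4500.0)
        with pytest.raises(ValueError):
            assign_region(-1.0)

    def _summary(self, depth=50.0, pct=50.0, rate=0.01):
        return pd.DataFrame(
            [{"site": "OO", "depth_m": depth, "substrate": "urea", "n_cells": 10,
              "pct_enriched": pct, "mean_rate_enriched": rate, "mean_ka_enriched": 0.02}]
        )

    def test_single_depth_product(self, no_warnings):
        out = integrate_region(
            self._summary(), {50.0: 1e5}, {"epipelagic": 1e3, "mesopelagic": 1, "bathypelagic": 1}
        )
        epi = out[out["region"] == "epipelagic"].iloc[0]
        # volumetric rate 1e5 * 0.5 * 0.01 = 500 fg/L/h, times 1e3 L of region
        assert epi["total_rate_fg_h"] == pytest.approx(500.0 * 1e3)

    def test_zero_enrichment_gives_zero_total(self, no_warnings):
        out = integrate_region(
            self._summary(pct=0.0, rate=np.nan), {50.0: 1e5},
            {"epipelagic": 1e3, "mesopelagic": 1, "bathypelagic": 1},
        )
        assert out[out["region"] == "epipelagic"]["total_rate_fg_h"].iloc[0] == 0.0

    def test_volume_linearity(self, no_warnings):
        vols = {"epipelagic": 1e3, "mesopelagic": 1, "bathypelagic": 1}
        out1 = integrate_region(self._summary(), {50.0: 1e5}, vols)
        vols2 = {k: 2 * v for k, v in vols.items()}
        out2 = integrate_region(self._summary(), {50.0: 1e5}, vols2)
        assert out2["total_rate_fg_h"].iloc[0] == pytest.approx(
            2 * out1["total_rate_fg_h"].iloc[0]
        )

    def test_unsampled_region_warns(self):
        with pytest.warns(UserWarning, match="no sampled depth"):
            out = integrate_region(
                self._summary(), {50.0: 1e5},
                {"epipelagic": 1e3, "mesopelagic": 1, "bathypelagic": 1},
            )
        assert np.isnan(out[out["region"] == "bathypelagic"]["total_rate_fg_h"].iloc[0])


def exact_ranksum_two_sided_p(a, b):
    """Brute-force two-sided rank-sum p by enumerating rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestSubstrateComparison:
    def test_fully_separated_samples(self):
        res = compare_substrates([1, 2, 3], [101, 102, 103])
        assert res.statistic == 0.0  # extreme U for the first sample
        assert res.pvalue == pytest.approx(0.1, rel=1e-12)
        assert res.pvalue == pytest.approx(
            exact_ranksum_two_sided_p(np.array([1.0, 2, 3]), np.array([101.0, 102, 103]))
        )

    def test_symmetry(self):
        p1 = compare_substrates([1, 5, 9, 11], [2, 3, 4, 8]).pvalue
        p2 = compare_substrates([2, 3, 4, 8], [1, 5, 9, 11]).pvalue
        assert p1 == pytest.approx(p2)

    def test_identical_samples_degenerate(self):
        with pytest.warns(UserWarning, match="tied"):
            res = compare_substrates([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.pvalue == 1.0
        assert not res.significant

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_substrates([1, 2], [3, 4, 5])


class TestProcessRoiTable:
    def test_per_cell_results_shape_and_flags(self):
        rois = pd.DataFrame(
            {
                "roi_id": ["a", "b", "c", "d", "e"],
                "site": "OO",
                "depth_m": 500.0,
                "substrate": "urea",
                "timepoint_h": [0.0, 0.0, 0.0, 72.0, 72.0],
                "ratio_15N": [0.0036, 0.0037, 0.0038, 0.0500, 0.0037],
            }
        )
        ctx = LabelingContext(amendment_nM=50, label_purity=0.98, ambient_nM=50)
        cells = process_roi_table(rois, {"urea": ctx}, cell_content_fg=10.0)
        assert len(cells) == 2
        assert cells.set_index("roi_id").loc["d", "enriched"]
        assert not cells.set_index("roi_id").loc["e", "enriched"]
        assert (cells["ka_per_day"] >= 0).all()
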