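"""Efficiency fitting, Pfaffl ratios, reference-gene stability, tests."""

import numpy as np
import pytest

from mirserca.model_io import CqRecord, ModelIOError
from mirserca.qpcr import (
    DilutionSeries,
    compare_groups,
    fit_efficiency,
    pfaffl_ratio,
    rg_stability,
    sample_ratios,
)
from mirserca.synthetic import gen_qpcr


def _series(slope, intercept=30.0, assay="a", noise=None, rng=None):
    points = []
    for step in range(1, 6):
        amount = 3.0**-step
        for _ in range(3):
            cq = intercept + slope * np.log10(amount)
            if noise:
                cq += rng.normal(0, noise)
            points.append((amount, float(cq)))
    return DilutionSeries(assay=assay, points=tuple(points))


class TestFitEfficiency:
    def test_perfect_doubling_closed_form(self):
        fit = fit_efficiency(_series(slope=-3.3219))
        assert fit.efficiency == pytest.approx(2.0, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_planted_efficiency_with_noise(self):
        # planted E = 1.90, Cq noise SD 0.1: median recovery within +-0.05
        target_slope = -1.0 / np.log10(1.90)
        recovered = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_efficiency(_series(target_slope, noise=0.1, rng=rng))
            recovered.append(fit.efficiency)
        assert abs(float(np.median(recovered)) - 1.90) <= 0.05

    def test_two_point_series_rejected(self):
        with pytest.raises(ModelIOError):
            DilutionSeries("a", ((1.0, 20.0), (0.1, 23.3)))

    def test_positive_slope_rejected(self):
        with pytest.raises(ModelIOError):
            fit_efficiency(_series(slope=+3.3))

    def test_invariant_to_input_rescaling(self):
        s1 = _series(slope=-3.3219)
        s2 = DilutionSeries("a", tuple((a * 7.5, c) for a, c in s1.points))
        assert fit_efficiency(s1).efficiency == pytest.approx(
            fit_efficiency(s2).efficiency
        )


class TestPfafflRatio:
    def test_one_cycle_later_halves_expression(self):
        assert pfaffl_ratio(2.0, 20.0, 21.0, 2.0, 20.0, 20.0) == pytest.approx(0.5)

    def test_equal_cqs_give_unity(self):
        assert pfaffl_ratio(2.0, 20.0, 20.0, 2.0, 25.0, 25.0) == pytest.approx(1.0)

    def test_reduces_to_ddcq_at_e2(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            ct_c, ct_i, cr_c, cr_i = rng.uniform(15, 35, 4)
            ddcq = (ct_i - ct_c) - (cr_i - cr_c)
            assert pfaffl_ratio(2.0, ct_c, ct_i, 2.0, cr_c, cr_i) == pytest.approx(
                2.0**-ddcq
            )

    def test_self_comparison_identity(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            e = rng.uniform(1.5, 2.1)
            a, b_ = rng.uniform(15, 35, 2)
            assert pfaffl_ratio(e, a, b_, e, a, b_) == pytest.approx(1.0)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ModelIOError):
            pfaffl_ratio(0.9, 20, 21, 2.0, 20, 20)


def _cq(sample, tissue, preservation, assay, cq, chemistry="dye_based"):
    return CqRecord(
        sample_id=sample,
        tissue=tissue,
        preservation=preservation,
        chemistry=chemistry,
        assay=assay,
        Cq=cq,
    )


class TestRGStability:
    def test_constant_cq(self):
        recs = [_cq(f"S{i}", "remote", "FFPE", "RNU6B", 20.0) for i in range(4)]
        t = rg_stability(recs)
        assert t.loc[0, "mean_cq"] == 20.0
        assert t.loc[0, "sd_cq"] == 0.0

    def test_two_value_closed_form(self):
        recs = [
            _cq("S1", "remote", "FFPE", "RNU6B", 20.0),
            _cq("S2", "remote", "FFPE", "RNU6B", 22.0),
        ]
        t = rg_stability(recs)
        assert t.loc[0, "mean_cq"] == pytest.approx(21.0)
        assert t.loc[0, "sd_cq"] == pytest.approx(np.sqrt(2.0), abs=1e-3)

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(23)
        recs = [
            _cq(f"S{i}", "remote", p, "RNU6B", float(rng.uniform(18, 30)))
            for i in range(8)
            for p in ("FFPE", "RNAlater")
        ]
        t1 = rg_stability(recs)
        t2 = rg_stability(list(reversed(recs)))
        assert t1.equals(t2)

    def test_recovers_preservation_shift_and_sd_inflation(self):
        shifts, sd_ratios = [], []
        for seed in range(60):
            recs, _, _ = gen_qpcr(assays={"RNU6B": 2.0}, seed=seed)
            t = rg_stability(recs).set_index("preservation")
            shifts.append(t.loc["FFPE", "mean_cq"] - t.loc["RNAlater", "mean_cq"])
            sd_ratios.append(t.loc["FFPE", "sd_cq"] / t.loc["RNAlater", "sd_cq"])
        assert abs(float(np.median(shifts)) - 3.0) <= 0.2
        assert abs(float(np.median(sd_ratios)) - 2.0) <= 0.3

    def test_empty_group_rejected(self):
        with pytest.raises(ModelIOError):
            rg_stability([])


class TestCompareGroups:
    def test_identical_vectors_flagged_degenerate(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(x, x)
        assert res.degenerate and res.wilcoxon_p is None

    def test_monotone_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        up = compare_groups(x, [2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        down = compare_groups(x, [13.0, 11.0, 7.0, 5.0, 3.0, 2.0])
        assert up.spearman_rho == pytest.approx(1.0)
        assert down.spearman_rho == pytest.approx(-1.0)

    def test_shifted_pairs_significant(self):
        rng = np.random.default_rng(24)
        x = rng.normal(10, 1, 12)
        res = compare_groups(x, x - 2.0)
        assert res.significant

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ModelIOError):
            compare_groups([1, 2], [2, 3])


class TestPlantedRatioRecovery:
    def test_two_fold_downregulation_recovered(self):
        medians = []
        for seed in range(40):
            recs, series, _ = gen_qpcr(
                assays={"RNU6B": 2.0, "t1": 2.0},
                group_shifts={"t1": -1.0},
                seed=seed,
            )
            fits = {k: fit_efficiency(s) for k, s in series.items()}
            sr = sample_ratios(
                recs, "t1", "RNU6B", fits["t1"].efficiency, fits["RNU6B"].efficiency
            )
            medians.append(float(sr["ratio"].median()))
        assert abs(float(np.median(medians)) - 0.5) <= 0.1
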