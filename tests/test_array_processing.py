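"""Background correction, lowess normalization and replicate aggregation."""

import numpy as np
import pytest
from scipy import stats

from rhizoclass.arrays import (
    Contrast,
    aggregate_contrast,
    background_correct,
    derive_indirect_ratio,
    lowess_normalize,
    ma_transform,
    normalize_slide,
)
from rhizoclass.errors import DesignError, NormalizationError, StatisticsError
from rhizoclass.simulate import (
    RHIZOSPHERES,
    SimulationConfig,
    SyntheticTruth,
    generate_slides,
    generate_truth,
)


class TestBackgroundCorrection:
    def test_subtracts_local_background(self, raw_slide):
        slide = background_correct(raw_slide([("g1", 1000, 100, 600, 50)]))
        assert slide.spots["ch1_fg"].iloc[0] == 900
        assert slide.spots["ch2_fg"].iloc[0] == 550
        assert not slide.spots["flagged"].iloc[0]

    def test_floors_and_flags_negative_spots(self, raw_slide):
        slide = background_correct(raw_slide([("g1", 50, 100, 600, 50)]))
        assert slide.spots["ch1_fg"].iloc[0] == 0.5
        assert bool(slide.spots["flagged"].iloc[0])

    def test_zero_background_is_identity(self, raw_slide):
        raw = raw_slide([("g1", 1000, 0, 600, 0), ("g2", 5, 0, 7, 0)])
        out = background_correct(raw)
        assert (out.spots["ch1_fg"] == raw.spots["ch1_fg"]).all()
        assert (out.spots["ch2_fg"] == raw.spots["ch2_fg"]).all()
        assert not out.spots["flagged"].any()


def _null_slide(n_genes, amplitude, noise, seed=0):
    cfg = SimulationConfig(
        n_genes=n_genes,
        noise_sd_log2=noise,
        dye_bias_amplitude=amplitude,
        category_proportions={"NONE": 1.0},
        seed=seed,
    )
    truths = generate_truth(cfg)
    (slide,) = generate_slides(truths, [Contrast("pea", "glucose", 1)], cfg)
    return ma_transform(background_correct(slide)), cfg


class TestLowessNormalization:
    def test_constant_offset_fully_absorbed(self, make_normalized_slide):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 14, 200)
        slide = make_normalized_slide(np.full(200, 1.7), a_values=a)
        out = lowess_normalize(slide)
        assert np.abs(out.data["M"]).max() < 1e-6

    def test_additive_offset_invariance(self, make_normalized_slide):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 300)
        m = rng.normal(0, 0.3, 300)
        base = lowess_normalize(make_normalized_slide(m, a_values=a))
        shifted = lowess_normalize(make_normalized_slide(m + 2.5, a_values=a))
        np.testing.assert_allclose(
            base.data["M"], shifted.data["M"], atol=1e-6
        )

    def test_removes_planted_cubic_bias(self):
        nslide, cfg = _null_slide(3000, amplitude=0.4, noise=0.0)
        out = lowess_normalize(nslide)
        a = out.data["A"].to_numpy()
        resid = out.data["M"].to_numpy()  # true log-ratio is 0 for null genes
        lo, hi = np.quantile(a, [0.05, 0.95])
        assert np.abs(resid[(a >= lo) & (a <= hi)]).max() < 0.05

    def test_bias_free_slide_left_nearly_untouched(self):
        nslide, _ = _null_slide(2000, amplitude=0.0, noise=0.25)
        before = nslide.data["M"].to_numpy().copy()
        after = lowess_normalize(nslide).data["M"].to_numpy()
        assert np.mean(np.abs(after - before)) < 0.02

    def test_flagged_genes_normalized_but_not_fitted(self, make_normalized_slide):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, 100)
        flagged = np.zeros(100, bool)
        flagged[:3] = True
        out = lowess_normalize(
            make_normalized_slide(np.full(100, 0.8), a_values=a, flagged=flagged)
        )
        assert np.abs(out.data["M"]).max() < 1e-6
        assert out.data["flagged"].sum() == 3

    def test_too_few_spots_raises(self, make_normalized_slide):
        with pytest.raises(NormalizationError):
            lowess_normalize(make_normalized_slide(np.zeros(10)))


class TestAggregation:
    def test_matches_textbook_t_test(self, make_normalized_slide):
        values = np.log2(3.0) + np.array([0.01, -0.02, 0.005])
        slides = [
            make_normalized_slide([v], slide_id=f"s{i}", gene_ids=["g1"])
            for i, v in enumerate(values)
        ]
        result = aggregate_contrast(slides, Contrast("pea", "glucose"))
        row = result.iloc[0]
        # independent oracle: the t statistic computed from first principles
        t = values.mean() / (values.std(ddof=1) / np.sqrt(len(values)))
        p_expected = 2 * stats.t.sf(abs(t), df=len(values) - 1)
        assert row["fold_change"] == pytest.approx(3.0, rel=0.02)
        assert row["p_value"] == pytest.approx(p_expected, rel=1e-9)
        assert row["p_value"] < 0.05
        assert row["n_replicates"] == 3

    def test_zero_variance_null_gene_reports_p_one(self, make_normalized_slide):
        slides = [
            make_normalized_slide([0.0], slide_id=f"s{i}", gene_ids=["g1"])
            for i in range(4)
        ]
        row = aggregate_contrast(slides, Contrast("pea", "glucose")).iloc[0]
        assert row["fold_change"] == 1.0
        assert row["p_value"] == 1.0

    def test_zero_variance_shifted_gene_flagged_degenerate(self, make_normalized_slide):
        slides = [
            make_normalized_slide([1.0], slide_id=f"s{i}", gene_ids=["g1"])
            for i in range(3)
        ]
        row = aggregate_contrast(slides, Contrast("pea", "glucose")).iloc[0]
        assert row["p_value"] == 0.0
        assert row["flags"] == "degenerate"

    def test_dye_swap_orientation_correction(self, make_normalized_slide):
        fwd = make_normalized_slide([1.0], slide_id="f", gene_ids=["g1"])
        swp = make_normalized_slide(
            [-1.0],
            slide_id="r",
            condition_ch1="glucose",
            condition_ch2="pea",
            dye_swap=True,
            gene_ids=["g1"],
        )
        row = aggregate_contrast([fwd, swp], Contrast("pea", "glucose")).iloc[0]
        assert row["mean_log2_ratio"] == pytest.approx(1.0, abs=1e-12)

    def test_fold_inverts_when_contrast_is_reversed(self, make_normalized_slide):
        rng = np.random.default_rng(3)
        slides = [
            make_normalized_slide(
                rng.normal(0.5, 0.2, 20),
                slide_id=f"s{i}",
                gene_ids=[f"g{j}" for j in range(20)],
            )
            for i in range(3)
        ]
        fwd = aggregate_contrast(slides, Contrast("pea", "glucose"))
        rev = aggregate_contrast(slides, Contrast("glucose", "pea"))
        np.testing.assert_allclose(
            fwd["fold_change"], 1.0 / rev["fold_change"], rtol=1e-9
        )

    def test_gene_flagged_everywhere_reported_not_dropped(self, make_normalized_slide):
        slides = [
            make_normalized_slide(
                [0.4, 2.0],
                slide_id=f"s{i}",
                gene_ids=["g1", "g2"],
                flagged=np.array([False, True]),
            )
            for i in range(3)
        ]
        result = aggregate_contrast(slides, Contrast("pea", "glucose"))
        row = result.set_index("gene_id").loc["g2"]
        assert row["p_value"] == 1.0
        assert row["flags"] == "all_flagged"

    def test_single_replicate_raises(self, make_normalized_slide):
        with pytest.raises(StatisticsError):
            aggregate_contrast(
                [make_normalized_slide([0.1])], Contrast("pea", "glucose")
            )


class TestIndirectRatio:
    def _contrast(self, make_slide, condition, values_by_gene, seed):
        rng = np.random.default_rng(seed)
        genes = list(values_by_gene)
        slides = [
            make_slide(
                [values_by_gene[g] + rng.normal(0, 0.02) for g in genes],
                slide_id=f"{condition}{i}",
                condition_ch1=condition,
                gene_ids=genes,
            )
            for i in range(4)
        ]
        return aggregate_contrast(slides, Contrast(condition, "glucose"))

    def test_fold_ratio_arithmetic(self, make_normalized_slide):
        a = self._contrast(make_normalized_slide, "pea", {"g1": np.log2(6.0)}, 1)
        b = self._contrast(make_normalized_slide, "alfalfa", {"g1": np.log2(2.0)}, 2)
        derived = derive_indirect_ratio(a, b)
        assert derived["fold_change"].iloc[0] == pytest.approx(3.0, rel=0.05)
        assert derived["numerator"].iloc[0] == "pea"
        assert derived["denominator"].iloc[0] == "alfalfa"

    def test_identical_contrasts_give_unit_fold(self, make_normalized_slide):
        a = self._contrast(make_normalized_slide, "pea", {"g1": 0.7}, 3)
        b = a.copy()
        b["numerator"] = "alfalfa"
        derived = derive_indirect_ratio(a, b)
        assert derived["fold_change"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert derived["p_value"].iloc[0] == pytest.approx(1.0)

    def test_mismatched_baselines_rejected(self, make_normalized_slide):
        a = self._contrast(make_normalized_slide, "pea", {"g1": 0.5}, 4)
        b = a.copy()
        b["denominator"] = "pyruvate"
        with pytest.raises(DesignError):
            derive_indirect_ratio(a, b)

    def test_indirect_agrees_with_direct_design_at_zero_noise(self):
        # one gene planted pea=9x / alfalfa=3x plus null filler; the derived
        # pea-vs-alfalfa fold and the directly hybridized fold both equal 3
        cfg = SimulationConfig(
            n_genes=201, noise_sd_log2=0.0, dye_bias_amplitude=0.3, seed=6,
            category_proportions={"NONE": 1.0},
        )
        truths = generate_truth(cfg)[:-1]
        truths.append(
            SyntheticTruth(
                gene_id="gFOCUS",
                category="LEGUME",
                planted_fold={"pea": 9.0, "alfalfa": 3.0, "sugarbeet": 1.0},
                replicon="chromosome",
            )
        )
        design = [
            Contrast("pea", "glucose", 3),
            Contrast("alfalfa", "glucose", 3),
            Contrast("pea", "alfalfa", 3),
        ]
        slides = generate_slides(truths, design, cfg)
        normalized = [normalize_slide(s) for s in slides]
        tables = {c: aggregate_contrast(normalized, c) for c in design}
        derived = derive_indirect_ratio(
            tables[design[0]], tables[design[1]]
        ).set_index("gene_id")
        direct = tables[design[2]].set_index("gene_id")
        assert derived.at["gFOCUS", "fold_change"] == pytest.approx(3.0, rel=0.03)
        assert direct.at["gFOCUS", "fold_change"] == pytest.approx(3.0, rel=0.03)


def test_type_i_error_calibrated_on_null_cohort():
    """On pure-noise data the t-test rejects at its nominal 5% rate."""
    cfg = SimulationConfig(
        n_genes=5000,
        noise_sd_log2=0.25,
        dye_bias_amplitude=0.4,
        n_replicates_per_contrast=4,
        category_proportions={"NONE": 1.0},
        seed=12,
    )
    truths = generate_truth(cfg)
    contrast = Contrast("pea", "glucose")
    slides = generate_slides(truths, [contrast], cfg)
    normalized = [normalize_slide(s) for s in slides]
    p = aggregate_contrast(normalized, contrast)["p_value"].to_numpy()
    assert (p <= 0.05).mean() == pytest.approx(0.05, abs=0.01)
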