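"""Probe-element outlier masking, summarisation, flags and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootplast import expression as ex
from rootplast import synthetic
from rootplast.expression import SignalCube


def _uniform_cube(n_probes=5, k=4, n_acc=3, value=None, seed=0):
    """Cube with fixed element affinities and negligible noise."""
    rng = np.random.default_rng(seed)
    accs = [f"acc{i + 1:03d}" for i in range(n_acc)]
    cols = pd.MultiIndex.from_product(
        [accs, ["control", "treated"], [1, 2, 3]],
        names=["accession", "treatment", "replicate"],
    )
    idx = pd.MultiIndex.from_product(
        [[f"PS{i:03d}" for i in range(n_probes)], range(k)],
        names=["probe_set", "element"],
    )
    if value is not None:
        data = np.full((n_probes * k, len(cols)), float(value))
    else:
        aff = rng.normal(8, 1, size=(n_probes, k)).reshape(-1, 1)
        data = 2.0 ** (aff + rng.normal(0, 1e-9, size=(n_probes * k, len(cols))))
    return SignalCube(
        data=pd.DataFrame(data, index=idx, columns=cols), reference_accession=accs[0]
    )


class TestRankNull:
    def test_noise_free_reference_gives_zero_deviations(self):
        cube = _uniform_cube()
        null = ex.build_rank_null(cube, seed=0)
        for pool in null.pooled_deviations.values():
            assert np.abs(pool).max() == 0.0

    def test_permuted_reference_array_inflates_deviations(self):
        cube = _uniform_cube(n_probes=40, k=6)
        data = cube.data.copy()
        ref_cols = [c for c in data.columns if c[0] == cube.reference_accession]
        # scramble the element order of one reference array
        col = ref_cols[0]
        rng = np.random.default_rng(1)
        for ps in data.index.get_level_values("probe_set").unique():
            vals = data.loc[ps, col].to_numpy()
            data.loc[ps, col] = rng.permutation(vals)
        scrambled = SignalCube(data=data, reference_accession=cube.reference_accession)
        null_clean = ex.build_rank_null(cube, seed=0)
        null_scr = ex.build_rank_null(scrambled, seed=0)
        q95_clean = np.quantile(np.abs(null_clean.pooled_deviations[6]), 0.95)
        assert np.abs(null_scr.pooled_deviations[6]).max() > q95_clean

    def test_quantiles_match_sort_and_index_oracle(self, expression_cube):
        cube, _, _ = expression_cube
        null = ex.build_rank_null(cube, seed=2)
        draws = np.sort(null.null_stats[11])
        alpha = 0.05
        oracle = np.quantile(draws, 1 - alpha)
        assert null.threshold(11, alpha) == pytest.approx(oracle, abs=1e-12)

    def test_single_element_probe_sets_excluded(self):
        cube = _uniform_cube(k=1)
        with pytest.raises(ValueError, match="multi-element"):
            ex.build_rank_null(cube)


class TestDetectOutliers:
    def test_planted_attenuation_detected_with_calibrated_errors(self):
        cube, _, truth = synthetic.simulate_expression_study(
            800, attenuation_spec={"n_outliers": 120, "fraction": 0.4}, seed=31
        )
        null = ex.build_rank_null(cube, seed=3)
        mask = ex.detect_outlier_elements(cube, null, alpha=0.01)
        att = {(p, e, a) for p, e, a, _ in truth.attenuated_elements}
        sens = len(att & mask.flagged) / len(att)
        n_clean = 800 * 11 * 6 - len(att)
        fpr = len(mask.flagged - att) / n_clean
        assert sens >= 0.9
        assert fpr <= 0.01 + 2 * np.sqrt(0.01 * 0.99 / n_clean)

    def test_mask_monotone_in_alpha(self, expression_cube):
        cube, _, _ = expression_cube
        null = ex.build_rank_null(cube, seed=4)
        m_tight = ex.detect_outlier_elements(cube, null, alpha=0.005)
        m_loose = ex.detect_outlier_elements(cube, null, alpha=0.05)
        assert m_tight.flagged <= m_loose.flagged

    def test_reference_accession_never_flagged(self, expression_cube):
        cube, _, _ = expression_cube
        null = ex.build_rank_null(cube, seed=5)
        mask = ex.detect_outlier_elements(cube, null, alpha=0.05)
        assert all(acc != cube.reference_accession for _, _, acc in mask.flagged)


class TestSummarize:
    def test_constant_elements_summarise_to_constant(self):
        cube = _uniform_cube(value=250.0)
        em = ex.summarize_probesets(cube, scale=False)
        np.testing.assert_allclose(em.values.to_numpy(), 250.0, rtol=1e-12)

    def test_masking_attenuated_element_improves_accuracy(self):
        # each estimator is judged against its own noise-free expectation
        # (the generator's clean log2 signals summarised over the same
        # element subset), so the comparison isolates attenuation leakage
        cube, _, truth = synthetic.simulate_expression_study(
            400, attenuation_spec={"n_outliers": 80, "fraction": 0.4}, seed=32
        )
        truth_mask = ex.OutlierMask(
            flagged={(p, e, a) for p, e, a, _ in truth.attenuated_elements},
            table=pd.DataFrame(),
        )
        em_masked = ex.summarize_probesets(cube, truth_mask, scale=False)
        em_raw = ex.summarize_probesets(cube, None, scale=False)
        clean = truth.noise_free_log2.copy()
        for probe, e, acc, frac in truth.attenuated_elements:
            cols = [c for c in clean.columns if c[0] == acc]
            clean.loc[(probe, e), cols] -= np.log2(frac)
        errs_m, errs_r = [], []
        for probe, e, acc, _ in truth.attenuated_elements:
            cols = [c for c in cube.data.columns if c[0] == acc]
            block = clean.loc[probe, cols].to_numpy()
            keep = np.ones(block.shape[0], dtype=bool)
            keep[e] = False
            target_m = ex._tukey_biweight(block[keep].T).mean()
            target_r = ex._tukey_biweight(block.T).mean()
            errs_m.append(abs(np.log2(em_masked.values.loc[probe, cols]).mean() - target_m))
            errs_r.append(abs(np.log2(em_raw.values.loc[probe, cols]).mean() - target_r))
        errs_m, errs_r = np.array(errs_m), np.array(errs_r)
        # masking wins in a clear majority of probe sets (in the rest the
        # biweight has already zero-weighted the outlier, so the two tie)
        assert (errs_m < errs_r).mean() >= 0.7
        assert errs_m.mean() < 0.5 * errs_r.mean()

    def test_masking_unused_elements_is_noop(self, expression_cube):
        cube, _, _ = expression_cube
        phantom = ex.OutlierMask(
            flagged={("PS_DOES_NOT_EXIST", 0, cube.accessions[1])},
            table=pd.DataFrame(),
        )
        a = ex.summarize_probesets(cube, None)
        b = ex.summarize_probesets(cube, phantom)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_invariant_to_common_array_rescaling(self, expression_cube):
        cube, _, _ = expression_cube
        a = ex.summarize_probesets(cube)
        data = cube.data.copy()
        data.iloc[:, 0] *= 8.0  # rescale one array by a common factor
        b = ex.summarize_probesets(
            SignalCube(data=data, reference_accession=cube.reference_accession)
        )
        pd.testing.assert_frame_equal(a.values, b.values, rtol=1e-9)

    def test_below_min_elements_marks_accession_missing(self):
        cube = _uniform_cube(n_probes=2, k=4)
        acc = cube.accessions[1]
        mask = ex.OutlierMask(
            flagged={("PS000", e, acc) for e in range(2)}, table=pd.DataFrame()
        )
        em = ex.summarize_probesets(cube, mask, min_elements=3)
        cols = [c for c in cube.data.columns if c[0] == acc]
        assert em.values.loc["PS000", cols].isna().all()
        assert em.values.loc["PS001", cols].notna().all()


class TestFlagProbes:
    @staticmethod
    def _em(values):
        cols = pd.MultiIndex.from_product(
            [["acc001", "acc002"], ["control", "treated"], [1]],
            names=["accession", "treatment", "replicate"],
        )
        vals = pd.DataFrame(np.asarray(values, dtype=float),
                            index=values.index, columns=cols)
        vals.index.name = "probe_set"
        return ex.ExpressionMatrix(values=vals, elements_used=pd.DataFrame(),
                                   scale_factors=pd.Series(1.0, index=cols))

    def test_flag_assignment(self):
        em = self._em(
            pd.DataFrame(
                [[500.0] * 4, [99.9] * 4, [500.0] * 4, [500.0] * 4, [500.0] * 4],
                index=["p_ok", "p_dim", "p_multi", "p_nomatch", "p_organelle"],
            )
        )
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3,g4", "", "g5"],
                "nuclear": [True, True, True, True, False],
            },
            index=["p_ok", "p_dim", "p_multi", "p_nomatch", "p_organelle"],
        )
        flags = ex.flag_probes(ann, em, detection_cutoff=100.0)
        assert flags.loc["p_dim", "flag4"]
        assert flags.loc["p_multi", "flag2"]
        assert flags.loc["p_nomatch", "flag1"]
        assert flags.loc["p_organelle", "flag1"]
        assert flags.loc["p_ok", "analysis_set"]
        assert not flags.loc["p_dim", "analysis_set"]

    def test_probe_absent_from_annotation_gets_flag1(self):
        em = self._em(pd.DataFrame([[500.0] * 4], index=["p_unknown"]))
        ann = pd.DataFrame({"gene_id": ["g1"]}, index=["p_other"])
        flags = ex.flag_probes(ann, em)
        assert flags.loc["p_unknown", "flag1"]

    def test_flag_counts_match_filter_oracle(self, expression_cube):
        cube, probe_map, _ = expression_cube
        em = ex.summarize_probesets(cube)
        ann = probe_map.copy()
        flags = ex.flag_probes(ann, em, detection_cutoff=100.0)
        oracle4 = (em.values.mean(axis=1) < 100.0).sum()
        assert flags["flag4"].sum() == oracle4
        assert flags["flag2"].sum() == 0  # 1:1 mapping


class TestAnovaClassify:
    def test_constant_gene_is_class_none_with_p_one(self):
        cols = pd.MultiIndex.from_product(
            [[f"a{i}" for i in range(3)], ["control", "treated"], [1, 2, 3]],
            names=["accession", "treatment", "replicate"],
        )
        values = pd.DataFrame([[128.0] * len(cols)], index=["g_const"], columns=cols)
        out = ex.anova_classify(values)
        assert out.classes.loc["g_const", "class"] == "none"
        assert out.classes.loc["g_const", "p_model"] == 1.0

    def test_global_null_rarely_passes_stage_one(self):
        rng = np.random.default_rng(33)
        cols = pd.MultiIndex.from_product(
            [[f"a{i}" for i in range(7)], ["control", "treated"], [1, 2, 3]],
            names=["accession", "treatment", "replicate"],
        )
        values = pd.DataFrame(
            2.0 ** rng.normal(8, 0.5, size=(2000, len(cols))), columns=cols
        )
        out = ex.anova_classify(values)
        assert (out.classes["class"] != "none").mean() <= 0.01

    def test_planted_classes_recovered(self):
        cube, pm, truth = synthetic.simulate_expression_study(1000, seed=34)
        em = ex.summarize_probesets(cube)
        out = ex.anova_classify(em.values)
        pred = out.classes["class"]
        pred.index = pm["gene_id"].reindex(out.classes.index).to_numpy()
        truth_cls = pd.Series(truth.gene_classes)
        assert (pred.reindex(truth_cls.index) == truth_cls).mean() >= 0.8

    def test_nonly_pipeline_recovers_consistent_sign(self):
        # full cube -> mask -> summarise -> classify keeps NOnly genes
        # nitrogen-responsive with one sign across accessions
        cube, pm, truth = synthetic.simulate_expression_study(
            400, class_proportions=(0.7, 0.0, 0.3, 0.0, 0.0), seed=35
        )
        null = ex.build_rank_null(cube, seed=6)
        mask = ex.detect_outlier_elements(cube, null)
        em = ex.summarize_probesets(cube, mask)
        out = ex.anova_classify(em.values)
        truth_cls = pd.Series(truth.gene_classes)
        gene_of = pm["gene_id"].reindex(out.classes.index)
        nonly = out.classes.index[(truth_cls.reindex(gene_of).to_numpy() == "NOnly")]
        called = out.classes.loc[nonly, "class"].isin(["NOnly", "NAccession"])
        assert called.mean() >= 0.8
        resp = out.responses.loc[nonly[called]]
        signs = np.sign(resp.to_numpy())
        assert (np.abs(signs.sum(axis=1)) == signs.shape[1]).mean() >= 0.95


class TestClusterEffectGenes:
    def test_anticorrelated_shapes_form_two_clusters(self):
        rng = np.random.default_rng(36)
        cols = pd.MultiIndex.from_product(
            [[f"a{i}" for i in range(5)], ["control", "treated"], [1, 2]],
            names=["accession", "treatment", "replicate"],
        )
        shape = rng.normal(0, 1, len(cols) // 2)
        base = np.repeat(shape, 2)
        up = 2.0 ** (8 + base + rng.normal(0, 0.05, (6, len(cols))))
        down = 2.0 ** (8 - base + rng.normal(0, 0.05, (6, len(cols))))
        values = pd.DataFrame(np.vstack([up, down]), columns=cols,
                              index=[f"g{i}" for i in range(12)])
        classes = pd.Series("NOnly", index=values.index)
        out = ex.cluster_effect_genes(values, classes)
        mat, part = out["NOnly"]
        assert part.n_clusters == 2
        assert np.allclose(mat.mean(axis=1), 0.0, atol=1e-12)

    def test_small_class_single_cluster(self):
        cols = pd.MultiIndex.from_product(
            [["a1", "a2"], ["control", "treated"], [1, 2]],
            names=["accession", "treatment", "replicate"],
        )
        values = pd.DataFrame([[100.0 + i] * len(cols) for i in range(2)],
                              columns=cols, index=["g1", "g2"])
        out = ex.cluster_effect_genes(values, pd.Series("NOnly", index=values.index))
        _, part = out["NOnly"]
        assert part is None
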