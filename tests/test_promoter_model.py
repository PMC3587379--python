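"""Training-set construction, feature fusion, SVM training and CV metrics."""

import numpy as np
import pytest

from promin.kmer_features import BackgroundModel
from promin.promoter_model import (
    ALL_FEATURE_SETS,
    CANDIDATE_WINDOWS,
    CVReport,
    DEFAULT_WINDOW,
    ModelBundle,
    assemble_features,
    build_training_set,
    cross_validate,
    feature_matrix,
    predict_promoters,
    train,
    train_bundle,
)
from promin.seqio import CpGClass, GenomicSequence, RelativeWindow, rel_to_index
from promin.stability import load_nn_table
from promin.synthetic import GeneratorConfig, gen_background, gen_promoters


@pytest.fixture(scope="module")
def small_records():
    return gen_promoters(GeneratorConfig(seed=5, n_records=30, flank=1000))


class TestTrainingSet:
    def test_equal_sizes(self, small_records):
        pos, neg, kept = build_training_set(small_records, seed=0)
        assert len(pos) == len(neg) == len(kept) == len(small_records)
        assert all(len(p) == DEFAULT_WINDOW.length for p in pos + neg)

    def test_negatives_do_not_overlap_positive(self, small_records):
        rng = np.random.default_rng(1)
        window = DEFAULT_WINDOW
        for rec in small_records[:5]:
            pos, neg, kept = build_training_set([rec], window, seed=rng)
            ps, pe = rel_to_index(window, rec.tss_index)
            # the negative must be findable outside [ps, pe)
            idx = rec.seq.find(neg[0])
            assert idx >= 0
            found_outside = False
            while idx >= 0:
                if idx + window.length <= ps or idx >= pe:
                    found_outside = True
                    break
                idx = rec.seq.find(neg[0], idx + 1)
            assert found_outside

    def test_seed_determinism(self, small_records):
        a = build_training_set(small_records, seed=42)
        b = build_training_set(small_records, seed=42)
        assert a[1] == b[1]

    def test_short_record_dropped(self):
        cfg = GeneratorConfig(seed=1, n_records=2, flank=400)
        recs = gen_promoters(cfg)
        # window (-400, 200) leaves no room for a negative in an 801-bp record
        with pytest.warns(UserWarning):
            pos, neg, kept = build_training_set(recs, RelativeWindow(-400, 200))
        assert kept == []


class TestFeatures:
    def test_poly_a_blocks(self):
        t = load_nn_table()
        hexamers = ["AAAAAA"] + ["ACGTAC"] * 99
        fv = assemble_features("A" * 300, hexamers)
        assert len(fv) == 204 and len(fv.schema) == 204
        # OR: (L-5)/L overlapping AAAAAA occurrences, 0 for the absent hexamer
        assert fv.values[0] == pytest.approx(295 / 300)
        assert fv.values[1] == 0.0
        # NC: rate 1 for A, AA, AAA
        names = dict(zip(fv.schema, fv.values))
        assert names["nc_A"] == 1.0 and names["nc_AA"] == 1.0 and names["nc_AAA"] == 1.0
        assert names["nc_C"] == 0.0
        # DS: 20 identical bins of 14 * dG(AA)
        ds = [v for n, v in names.items() if n.startswith("ds_")]
        assert np.allclose(ds, 14 * t["AA"])

    def test_nc_block_sums_to_three(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        fv = assemble_features(seq, ["AAAAAA"] * 100)
        nc = [v for n, v in zip(fv.schema, fv.values) if n.startswith("nc_")]
        assert np.isclose(sum(nc), 3.0)

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            assemble_features("AN" + "A" * 298, ["AAAAAA"])

    @pytest.mark.parametrize("window", CANDIDATE_WINDOWS, ids=str)
    def test_dimension_window_invariant(self, window, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, window.length)])
        fv = assemble_features(seq, ["ACGTAC"] * 100)
        assert len(fv) == 204

    @pytest.mark.parametrize(
        "sets,dim", [(("OR",), 100), (("NC",), 84), (("DS",), 20),
                     (("OR", "NC"), 184), (("NC", "DS"), 104)]
    )
    def test_ablation_dimensions(self, sets, dim):
        fv = assemble_features("ACGT" * 75, ["ACGTAC"] * 100, feature_sets=sets)
        assert len(fv) == dim


class TestTrain:
    def test_separable_toy_data(self, rng):
        X = np.r_[rng.normal(-3, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))]
        y = np.r_[np.zeros(40), np.ones(40)]
        scaler, svc = train(X, y, C=1.0, gamma=0.5)
        assert (svc.predict(scaler.transform(X)) == y).all()

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            train(X, np.ones(10))

    def test_shuffled_labels_near_chance(self):
        """Random labels on structureless features give ~50% CV accuracy."""
        recs = gen_promoters(
            GeneratorConfig(
                seed=13, n_records=100, flank=800, embedding_rate=0.0,
                tata_strength=0.0, stability_dip=False,
            )
        )
        report = cross_validate(recs, RelativeWindow(-100, 50), k=5, seed=3)
        assert 0.35 <= report.accuracy <= 0.65


class TestCVReport:
    def test_printed_formulas(self):
        r = CVReport([], tp=80, fp=20, tn=80, fn=20)
        assert r.precision == pytest.approx(0.80)
        assert r.sensitivity == pytest.approx(0.80)
        assert r.specificity == pytest.approx(0.80)
        assert r.accuracy == pytest.approx(0.80)

    def test_metric_identities_on_real_report(self):
        recs = gen_promoters(GeneratorConfig(seed=8, n_records=25, flank=800))
        report = cross_validate(recs, RelativeWindow(-100, 50), k=5, seed=0)
        tp = sum(f["tp"] for f in report.folds)
        fp = sum(f["fp"] for f in report.folds)
        tn = sum(f["tn"] for f in report.folds)
        fn = sum(f["fn"] for f in report.folds)
        assert (tp, fp, tn, fn) == (report.tp, report.fp, report.tn, report.fn)
        assert report.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        # one positive and one negative per record
        assert tp + fp + tn + fn == 2 * len(recs)

    def test_fold_sizes_balanced(self):
        recs = gen_promoters(GeneratorConfig(seed=9, n_records=23, flank=800))
        report = cross_validate(recs, RelativeWindow(-100, 50), k=5, seed=0)
        sizes = [(f["tp"] + f["fn"]) for f in report.folds]  # positives per fold
        assert max(sizes) - min(sizes) <= 1

    def test_k_validation(self):
        recs = gen_promoters(GeneratorConfig(seed=9, n_records=6, flank=800))
        with pytest.raises(ValueError):
            cross_validate(recs, k=1)

    def test_determinism(self):
        recs = gen_promoters(GeneratorConfig(seed=10, n_records=20, flank=800))
        a = cross_validate(recs, RelativeWindow(-100, 50), k=4, seed=7)
        b = cross_validate(recs, RelativeWindow(-100, 50), k=4, seed=7)
        assert a.folds == b.folds


@pytest.fixture(scope="module")
def bundle():
    recs = gen_promoters(
        GeneratorConfig(seed=21, n_records=40, cpg_class=CpGClass.WITH_CPG)
    ) + gen_promoters(
        GeneratorConfig(seed=22, n_records=40, cpg_class=CpGClass.WITHOUT_CPG)
    )
    return train_bundle(recs, seed=2)


class TestBundlePrediction:
    def test_both_branches_trained(self, bundle):
        assert set(bundle.branches) == {"with_cpg", "without_cpg"}

    def test_predicts_region_at_tss(self, bundle):
        rec = gen_promoters(
            GeneratorConfig(seed=99, n_records=1, cpg_class=CpGClass.WITH_CPG)
        )[0]
        regions = predict_promoters(GenomicSequence(rec.gene_id, rec.seq), bundle)
        ps, pe = rel_to_index(DEFAULT_WINDOW, rec.tss_index)
        assert any(r.start < pe and r.end > ps for r in regions)

    def test_low_false_positive_rate_on_background(self, bundle):
        bg = gen_background(1, 6001, seed=123)[0]
        wlen = bundle.window.length
        n_windows = (bg.length - wlen) // 10 + 1
        regions = predict_promoters(bg, bundle, stride=10)
        covered = sum(r.end - r.start for r in regions)
        assert covered / bg.length <= 0.05 * (wlen / 10)  # generous bound
        assert len(regions) <= 0.05 * n_windows

    def test_stride_larger_than_sequence(self, bundle):
        rec = gen_promoters(
            GeneratorConfig(seed=98, n_records=1, cpg_class=CpGClass.WITH_CPG)
        )[0]
        sub = GenomicSequence("w", rec.window_seq(DEFAULT_WINDOW))
        regions = predict_promoters(sub, bundle, stride=10 ** 6)
        assert all(r.start == 0 for r in regions)

    def test_save_load_round_trip(self, bundle, tmp_path):
        path = tmp_path / "bundle.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        assert set(loaded.branches) == set(bundle.branches)
        assert loaded.window == bundle.window

    def test_untrained_bundle_raises(self):
        empty = ModelBundle(DEFAULT_WINDOW, {})
        with pytest.raises(ValueError):
            predict_promoters(GenomicSequence("s", "ACGT" * 100), empty)
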