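"""Performance indices, agreement, stratification, bootstrap analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn import metrics as skm

import repliclass as rc
from repliclass.errors import ValidationError


def counts(tp, fp, tn, fn):
    return rc.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestConfusion:
    def test_perfect_and_inverted(self):
        truth = {f"p{i}": rc.PLASMID for i in range(50)}
        truth.update({f"c{i}": rc.CHROMOSOME for i in range(50)})
        perfect = rc.confusion(truth, truth)
        assert (perfect.tp, perfect.fp, perfect.tn, perfect.fn) == (50, 0, 50, 0)
        inverted = {
            k: rc.CHROMOSOME if v == rc.PLASMID else rc.PLASMID
            for k, v in truth.items()
        }
        worst = rc.confusion(inverted, truth)
        assert (worst.tp, worst.fp, worst.tn, worst.fn) == (0, 50, 0, 50)

    def test_id_mismatch_rejected(self):
        truth = {"a": rc.PLASMID}
        with pytest.raises(ValidationError, match="mismatch"):
            rc.confusion({"a": rc.PLASMID, "b": rc.CHROMOSOME}, truth)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValidationError):
            rc.confusion({"a": "unknown"}, {"a": rc.PLASMID})


class TestMetrics:
    def test_perfect_classifier(self):
        r = rc.metrics(counts(50, 0, 50, 0))
        assert (r.sensitivity, r.precision, r.f1, r.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_mcc_hand_value(self):
        r = rc.metrics(counts(40, 10, 35, 15))
        assert r.mcc == pytest.approx(0.5025, abs=5e-5)

    def test_zero_marginal_mcc_convention(self):
        r = rc.metrics(counts(0, 0, 50, 50))  # nothing predicted plasmid
        assert r.mcc == 0.0
        assert r.mcc_zero_marginal
        assert r.precision is None and "precision" in r.undefined

    def test_oracle_equivalence_on_random_instances(self):
        # brute-force recomputation from raw label pairs via scikit-learn
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            truth = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            ids = [f"x{i}" for i in range(n)]
            ours = rc.metrics(rc.confusion(
                dict(zip(ids, np.where(pred, rc.PLASMID, rc.CHROMOSOME))),
                dict(zip(ids, np.where(truth, rc.PLASMID, rc.CHROMOSOME))),
            ))
            assert ours.mcc == pytest.approx(
                skm.matthews_corrcoef(truth, pred), abs=1e-12
            )
            if ours.sensitivity is not None:
                assert ours.sensitivity == pytest.approx(
                    skm.recall_score(truth, pred, zero_division=np.nan)
                )
            if ours.precision is not None:
                assert ours.precision == pytest.approx(
                    skm.precision_score(truth, pred, zero_division=np.nan)
                )
            if ours.f1 is not None and ours.sensitivity and ours.precision:
                assert ours.f1 == pytest.approx(skm.f1_score(truth, pred))

    def test_mcc_symmetric_under_class_swap_f1_not(self):
        c = counts(40, 10, 35, 15)
        swapped = counts(35, 15, 40, 10)  # positive/negative designation swapped
        assert rc.metrics(c).mcc == pytest.approx(rc.metrics(swapped).mcc)
        assert rc.metrics(c).f1 != pytest.approx(rc.metrics(swapped).f1)


class TestF1FromRates:
    def test_equal_rates(self):
        assert rc.f1_from_rates(0.5, 0.5) == 0.5

    def test_closed_form_grid(self):
        for x in np.linspace(0.05, 1.0, 20):
            assert rc.f1_from_rates(1.0, x) == pytest.approx(2 * x / (1 + x))

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            rc.f1_from_rates(0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            rc.f1_from_rates(1.2, 0.5)


class TestStratifiedMetrics:
    def _data(self):
        rng = np.random.default_rng(7)
        ids = [f"x{i}" for i in range(400)]
        sizes = {i: int(s) for i, s in zip(
            ids, rng.integers(50, 100_000, size=400)
        )}
        truth = {i: rc.PLASMID if rng.random() < 0.3 else rc.CHROMOSOME
                 for i in ids}
        pred = {
            i: truth[i] if rng.random() < 0.8 else (
                rc.CHROMOSOME if truth[i] == rc.PLASMID else rc.PLASMID
            )
            for i in ids
        }
        return pred, truth, sizes

    def test_default_bins_are_the_five_strata_plus_overall(self):
        pred, truth, sizes = self._data()
        reports = rc.stratified_metrics(pred, truth, sizes)
        assert [r.stratum for r in reports] == [
            "[50,1000)", "[1000,2000)", "[2000,5000)", "[5000,50000)",
            "[50000,inf)", "Overall",
        ]

    def test_pooled_counts_are_additive(self):
        pred, truth, sizes = self._data()
        reports = rc.stratified_metrics(pred, truth, sizes)
        overall = reports[-1].counts
        summed = np.sum(
            [[r.counts.tp, r.counts.fp, r.counts.tn, r.counts.fn]
             for r in reports[:-1]],
            axis=0,
        )
        assert list(summed) == [overall.tp, overall.fp, overall.tn, overall.fn]

    def test_overall_is_pooled_not_averaged(self):
        pred, truth, sizes = self._data()
        reports = rc.stratified_metrics(pred, truth, sizes)
        mean_of_bins = np.mean([r.mcc for r in reports[:-1]])
        assert reports[-1].mcc != pytest.approx(mean_of_bins, abs=1e-6)

    def test_single_stratum_equals_overall(self):
        pred, truth, _ = self._data()
        sizes = {k: 500 for k in pred}
        reports = rc.stratified_metrics(pred, truth, sizes)
        assert len(reports) == 2
        assert reports[0].counts == reports[1].counts

    def test_contig_below_lowest_bound_rejected(self):
        with pytest.raises(ValidationError):
            rc.stratified_metrics(
                {"a": rc.PLASMID}, {"a": rc.PLASMID}, {"a": 20}
            )


class TestCohensKappa:
    def test_perfect_agreement(self):
        k = rc.cohens_kappa(rc.AgreementCounts(40, 0, 0, 60))
        assert k == pytest.approx(1.0)

    def test_hand_value(self):
        k = rc.cohens_kappa(rc.AgreementCounts(40, 10, 10, 40))
        assert k == pytest.approx(0.6)

    def test_symmetry_and_sklearn_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            table = rc.AgreementCounts(
                both_plasmid=int(np.sum((a == 1) & (b == 1))),
                a_only=int(np.sum((a == 1) & (b == 0))),
                b_only=int(np.sum((a == 0) & (b == 1))),
                both_chromosome=int(np.sum((a == 0) & (b == 0))),
            )
            swapped = rc.AgreementCounts(
                table.both_plasmid, table.b_only, table.a_only,
                table.both_chromosome,
            )
            ours = rc.cohens_kappa(table)
            assert ours == rc.cohens_kappa(swapped)
            oracle = skm.cohen_kappa_score(a, b)
            if ours is None:
                assert math.isnan(oracle) or oracle == pytest.approx(1.0)
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_undefined_when_chance_agreement_is_one(self):
        assert rc.cohens_kappa(rc.AgreementCounts(10, 0, 0, 0)) is None


class TestResampleDatabase:
    def test_preserves_cardinality_and_draws_with_replacement(self):
        db = [rc.Contig(id=f"s{i}", sequence="ACGT" * 25) for i in range(30)]
        resampled = rc.resample_database(db, seed=3)
        assert len(resampled) == len(db)
        originals = {c.id.split("__")[0] for c in resampled}
        assert len(originals) < len(db)  # some duplicates, some dropped
        assert len({c.id for c in resampled}) == len(db)  # ids stay unique


class TestBootstraps:
    N_REPS = 6  # scaled-down replicate count for the miniature system

    def test_database_bootstrap_deterministic(self, small_split):
        database, train, test = small_split
        kw = dict(n_reps=2, seeds=[101, 202], n_trees=50)
        a = rc.bootstrap_database(database, train, test, **kw)
        b = rc.bootstrap_database(database, train, test, **kw)
        assert [r.counts for r in a] == [r.counts for r in b]
        assert len(a) == 2

    def test_training_bootstrap_deterministic_and_test_fixed(self, small_split):
        database, train, test = small_split
        hits_tr = rc.run_homology_search(train, database)
        hits_te = rc.run_homology_search(test, database)
        Xtr = rc.features_table(train, hits_tr)
        Xte = rc.features_table(test, hits_te)
        ytr = [c.truth_label for c in train]
        yte = [c.truth_label for c in test]
        before = Xte.copy()
        a = rc.bootstrap_training(Xtr, ytr, Xte, yte, n_reps=1, seeds=[7],
                                  n_trees=50)
        b = rc.bootstrap_training(Xtr, ytr, Xte, yte, n_reps=1, seeds=[7],
                                  n_trees=50)
        assert a[0].counts == b[0].counts
        pd.testing.assert_frame_equal(Xte, before)  # test set untouched

    def test_database_resampling_hurts_more_than_training_resampling(
        self, small_split
    ):
        # resampling the reference database drops the only homolog of some
        # plasmids, so performance degrades and spreads; resampling the
        # training rows leaves the features intact
        database, train, test = small_split
        hits_tr = rc.run_homology_search(train, database)
        hits_te = rc.run_homology_search(test, database)
        Xtr = rc.features_table(train, hits_tr)
        Xte = rc.features_table(test, hits_te)
        ytr = [c.truth_label for c in train]
        yte = [c.truth_label for c in test]
        model = rc.train(Xtr, ytr, n_trees=100, seed=0)
        pred = rc.predict(model, Xte)["prediction"]
        truth = pd.Series(yte, index=Xte.index)
        full_mcc = rc.metrics(rc.confusion(pred, truth)).mcc

        seeds = list(range(301, 301 + self.N_REPS))
        db_reports = rc.bootstrap_database(
            database, train, test, n_reps=self.N_REPS, seeds=seeds, n_trees=100
        )
        tr_reports = rc.bootstrap_training(
            Xtr, ytr, Xte, yte, n_reps=self.N_REPS, seeds=seeds, n_trees=100
        )
        db_mcc = np.array([r.mcc for r in db_reports])
        tr_mcc = np.array([r.mcc for r in tr_reports])
        assert np.median(db_mcc) <= full_mcc + 0.02
        iqr = lambda x: np.subtract(*np.percentile(x, [75, 25]))
        assert iqr(tr_mcc) <= iqr(db_mcc)

    def test_empty_database_rejected(self, small_split):
        _, train, test = small_split
        with pytest.raises(ValidationError):
            rc.bootstrap_database([], train, test, n_reps=1, seeds=[1])
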