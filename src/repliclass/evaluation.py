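"""Binary-classification performance indices and sensitivity analyses.

The positive class is plasmid throughout. From the confusion matrix we
report sensitivity (recall), precision, their harmonic mean F1, and the
Matthews correlation coefficient

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),

a correlation between predicted and observed classes that stays meaningful
under heavy class imbalance. Degenerate 0/0 rates are reported as
undefined with a reason rather than raising; when any MCC marginal is
zero the coefficient is reported as 0 (the convention of standard
implementations) and flagged.

Two bootstrap analyses probe the stability of a trained classifier: one
resamples the plasmid reference database (features are recomputed and a
fresh model trained per replicate), the other resamples the balanced
training rows while the test set stays fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as _classifier
from . import features as _features
from .errors import ValidationError
from .homology import HomologyConfig, run_homology_search
from .sequence_io import CHROMOSOME, PLASMID, Contig

#: The five evaluation strata used for size-stratified reports (bp).
EVAL_SIZE_BINS: tuple[float, ...] = (50, 1e3, 2e3, 5e3, 5e4, math.inf)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the four indices.

    An index that is 0/0 is ``None`` with the reason recorded in
    ``undefined``; ``mcc_zero_marginal`` flags the MCC = 0 convention.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    precision: float | None
    f1: float | None
    mcc: float
    stratum: str | None = None
    undefined: dict = field(default_factory=dict)
    mcc_zero_marginal: bool = False


@dataclass(frozen=True)
class AgreementCounts:
    """2x2 contingency table of two classifiers' plasmid calls."""

    both_plasmid: int
    a_only: int
    b_only: int
    both_chromosome: int

    def __post_init__(self) -> None:
        values = (self.both_plasmid, self.a_only, self.b_only, self.both_chromosome)
        if min(values) < 0:
            raise ValidationError("agreement counts must be non-negative")
        if sum(values) < 1:
            raise ValidationError("agreement table is empty")

    @property
    def total(self) -> int:
        return self.both_plasmid + self.a_only + self.b_only + self.both_chromosome


def _as_mapping(labels) -> dict[str, str]:
    if isinstance(labels, pd.Series):
        return {str(k): str(v) for k, v in labels.items()}
    return {str(k): str(v) for k, v in dict(labels).items()}


def confusion(predictions, truth) -> ConfusionCounts:
    """Confusion counts with plasmid as the positive class.

    Both arguments are id -> label mappings (dict or pandas Series) over
    identical id sets.
    """
    pred = _as_mapping(predictions)
    true = _as_mapping(truth)
    missing_in_pred = sorted(set(true) - set(pred))
    extra_in_pred = sorted(set(pred) - set(true))
    if missing_in_pred or extra_in_pred:
        raise ValidationError(
            f"prediction/truth id mismatch: missing from predictions "
            f"{missing_in_pred[:5]}, unexpected in predictions {extra_in_pred[:5]}"
        )
    for mapping, side in ((pred, "prediction"), (true, "truth")):
        bad = sorted({v for v in mapping.values() if v not in (PLASMID, CHROMOSOME)})
        if bad:
            raise ValidationError(f"non-binary {side} labels: {bad}")
    tp = fp = tn = fn = 0
    for cid, t in true.items():
        p = pred[cid]
        if t == PLASMID:
            if p == PLASMID:
                tp += 1
            else:
                fn += 1
        else:
            if p == PLASMID:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts, stratum: str | None = None) -> MetricsReport:
    """Sensitivity, precision, F1 and MCC from confusion counts."""
    undefined: dict[str, str] = {}
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity, undefined["sensitivity"] = None, "no positive truth labels"
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined["precision"] = None, "no positive predictions"
    if sensitivity is None or precision is None:
        f1, undefined["f1"] = None, "sensitivity or precision undefined"
    elif sensitivity + precision == 0:
        f1, undefined["f1"] = None, "sensitivity and precision both zero"
    else:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    marginals = (tp + fp, tp + fn, tn + fp, tn + fn)
    zero_marginal = any(m == 0 for m in marginals)
    if zero_marginal:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(float(math.prod(marginals)))
    return MetricsReport(
        counts=counts,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        mcc=mcc,
        stratum=stratum,
        undefined=undefined,
        mcc_zero_marginal=zero_marginal,
    )


def f1_from_rates(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision."""
    for name, value in (("sensitivity", sensitivity), ("precision", precision)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {value}")
    if sensitivity + precision == 0:
        raise ValidationError("F1 undefined: sensitivity and precision both zero")
    return 2 * sensitivity * precision / (sensitivity + precision)


def stratified_metrics(
    predictions,
    truth,
    sizes: Mapping[str, int],
    bins: Sequence[float] = EVAL_SIZE_BINS,
) -> list[MetricsReport]:
    """Per-size-bin reports plus an Overall row on pooled counts.

    The Overall row pools the confusion counts before computing indices;
    it is not an average of per-bin rates.
    """
    if list(bins) != sorted(bins):
        raise ValidationError("size bins must be ascending")
    pred = _as_mapping(predictions)
    true = _as_mapping(truth)
    sizes = {str(k): int(v) for k, v in dict(sizes).items()}
    below = sorted(k for k, v in sizes.items() if v < bins[0])
    if below:
        raise ValidationError(
            f"contigs below the lowest size boundary {bins[0]}: {below[:5]}"
        )
    reports: list[MetricsReport] = []
    for i in range(len(bins) - 1):
        ids = [k for k, v in sizes.items() if bins[i] <= v < bins[i + 1]]
        if not ids:
            continue
        counts = confusion(
            {k: pred[k] for k in ids}, {k: true[k] for k in ids}
        )
        upper = "inf" if math.isinf(bins[i + 1]) else f"{int(bins[i + 1])}"
        reports.append(
            metrics(counts, stratum=f"[{int(bins[i])},{upper})")
        )
    reports.append(metrics(confusion(pred, true), stratum="Overall"))
    return reports


def reports_to_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Tabulate reports in a Table-1-like layout (one row per stratum)."""
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "tn": r.counts.tn,
                "fn": r.counts.fn,
                "sensitivity": r.sensitivity,
                "precision": r.precision,
                "f1": r.f1,
                "mcc": r.mcc,
            }
            for r in reports
        ]
    )


def cohens_kappa(counts: AgreementCounts) -> float | None:
    """Chance-corrected agreement between two classifiers' plasmid calls.

    Returns ``None`` (undefined) when chance agreement is exactly 1,
    i.e. both classifiers are the same constant.
    """
    n = counts.total
    po = (counts.both_plasmid + counts.both_chromosome) / n
    a_plasmid = (counts.both_plasmid + counts.a_only) / n
    b_plasmid = (counts.both_plasmid + counts.b_only) / n
    pe = a_plasmid * b_plasmid + (1 - a_plasmid) * (1 - b_plasmid)
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


def _replicate_seeds(n_reps: int, seeds, seed: int | None) -> list[int]:
    if seeds is not None:
        seeds = [int(s) for s in seeds]
        if len(seeds) != n_reps:
            raise ValidationError(f"need {n_reps} seeds, got {len(seeds)}")
        return seeds
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps)]


def _labels_of(contigs: Sequence[Contig]) -> list[str]:
    labels = [c.truth_label for c in contigs]
    if any(l not in (PLASMID, CHROMOSOME) for l in labels):
        raise ValidationError("all contigs must carry a truth label")
    return labels


def resample_database(database: Sequence[Contig], seed: int) -> list[Contig]:
    """Bootstrap resample of the database: with replacement, original size.

    Resampled copies get unique ids (``<id>__b<i>``) so duplicated
    sequences remain distinct database entries.
    """
    if len(database) == 0:
        raise ValidationError("database is empty")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(database), size=len(database))
    return [
        Contig(
            id=f"{database[j].id}__b{i}",
            sequence=database[j].sequence,
            truth_label=database[j].truth_label,
        )
        for i, j in enumerate(picks.tolist())
    ]


def bootstrap_database(
    database: Sequence[Contig],
    train_contigs: Sequence[Contig],
    test_contigs: Sequence[Contig],
    n_reps: int = 50,
    seeds: Sequence[int] | None = None,
    seed: int | None = None,
    homology_config: HomologyConfig | None = None,
    n_trees: int = _classifier.N_TREES_DEFAULT,
) -> list[MetricsReport]:
    """Stability of the classifier under resampling of the reference database.

    Per replicate, the database is resampled with replacement to its
    original size, features are recomputed for train and test contigs
    against the resampled database, a fresh forest is trained, and test
    metrics are reported.
    """
    if len(database) == 0:
        raise ValidationError("database is empty")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rep_seeds = _replicate_seeds(n_reps, seeds, seed)
    train_labels = _labels_of(train_contigs)
    test_labels = _labels_of(test_contigs)
    reports = []
    for r, rep_seed in enumerate(rep_seeds):
        resampled = resample_database(database, rep_seed)
        train_X = _features.features_table(
            train_contigs, run_homology_search(train_contigs, resampled, homology_config)
        )
        test_X = _features.features_table(
            test_contigs, run_homology_search(test_contigs, resampled, homology_config)
        )
        model = _classifier.train(train_X, train_labels, n_trees=n_trees, seed=rep_seed)
        pred = _classifier.predict(model, test_X)["prediction"]
        truth = pd.Series(test_labels, index=test_X.index)
        reports.append(metrics(confusion(pred, truth), stratum=f"replicate_{r}"))
    return reports


def bootstrap_training(
    train_features: pd.DataFrame,
    train_labels: Sequence[str],
    test_features: pd.DataFrame,
    test_labels: Sequence[str],
    n_reps: int = 50,
    seeds: Sequence[int] | None = None,
    seed: int | None = None,
    n_trees: int = _classifier.N_TREES_DEFAULT,
) -> list[MetricsReport]:
    """Stability under resampling of the balanced training rows.

    Training rows are resampled with replacement to their original count
    (features unchanged); the test set is identical across replicates.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    train_labels = list(train_labels)
    if len(train_labels) != len(train_features):
        raise ValidationError("training labels do not match feature rows")
    rep_seeds = _replicate_seeds(n_reps, seeds, seed)
    truth = pd.Series(list(test_labels), index=test_features.index)
    reports = []
    for r, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        picks = rng.integers(0, len(train_features), size=len(train_features))
        X = train_features.iloc[picks]
        y = [train_labels[i] for i in picks.tolist()]
        model = _classifier.train(X, y, n_trees=n_trees, seed=rep_seed)
        pred = _classifier.predict(model, test_features)["prediction"]
        reports.append(metrics(confusion(pred, truth), stratum=f"replicate_{r}"))
    return reports
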