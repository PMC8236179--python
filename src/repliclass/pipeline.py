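"""End-to-end pipelines: classify query contigs, and train from genomes.

Classification runs the three-step method: (1) contigs whose FASTA
annotation already names a plasmid or chromosome are passed through with
that label (unless ``reassign`` is set); (2) the remaining contigs are
searched against the plasmid database and summarised into the seven
features; (3) the forest assigns a label from the tree votes. The result
table has exactly one row per input contig, in input order, whatever the
thread count or batch size — work partitioning never reorders or re-seeds
anything.

Training runs shred -> balance -> genome-level 70/30 split -> featurize ->
fit 500 trees -> evaluate on the held-out genomes, all governed by a
single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import classifier as _classifier
from . import evaluation as _evaluation
from . import features as _features
from . import shredder as _shredder
from .errors import ValidationError
from .homology import HomologyConfig, compute_overlap, run_homology_search
from .sequence_io import UNKNOWN, Contig, annotation_label, read_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_fasta: str
    database: str
    model: str
    output: str
    reassign: bool = False
    show_best_hits: bool = False
    show_features: bool = False
    verbose: bool = False
    threads: int = 1
    size_of_batch: int | None = None  # None = one batch with all contigs
    seed: int = 0
    homology: HomologyConfig | None = None

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValidationError("threads must be >= 1")
        if self.size_of_batch is not None and self.size_of_batch < 1:
            raise ValidationError("size_of_batch must be >= 1")


def _batches(items: Sequence, size: int | None) -> list[Sequence]:
    if size is None or size >= len(items):
        return [items]
    return [items[i : i + size] for i in range(0, len(items), size)]


def _atomic_write_text(path: Path, text: str) -> None:
    # write-then-rename: a failed run never leaves a partial output behind
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def classify_contigs(
    contigs: Sequence[Contig],
    database: Sequence[Contig],
    model: _classifier.ForestModel,
    reassign: bool = False,
    show_best_hits: bool = False,
    show_features: bool = False,
    threads: int = 1,
    size_of_batch: int | None = None,
    homology_config: HomologyConfig | None = None,
) -> pd.DataFrame:
    """In-memory classification; one output row per input contig."""
    homology_config = homology_config or HomologyConfig()
    by_annotation: dict[str, str] = {}
    to_classify: list[Contig] = []
    for c in contigs:
        label = UNKNOWN if reassign else annotation_label(c.description)
        if label != UNKNOWN:
            by_annotation[c.id] = label
        else:
            to_classify.append(c)

    hits_by_query: dict[str, list] = {}
    feature_frames: list[pd.DataFrame] = []
    if to_classify:
        batches = _batches(to_classify, size_of_batch)

        def process(batch):
            hits = run_homology_search(batch, database, homology_config)
            return hits, _features.features_table(batch, hits)

        if threads > 1 and len(batches) > 1:
            with ThreadPoolExecutor(max_workers=threads) as pool:
                results = list(pool.map(process, batches))
        else:
            results = [process(b) for b in batches]
        for hits, table in results:
            feature_frames.append(table)
            for h in hits:
                hits_by_query.setdefault(h.query_id, []).append(h)

    predictions = pd.DataFrame(columns=["prediction", "vote_fraction"])
    features_all = pd.DataFrame(columns=list(_features.FEATURE_NAMES))
    if feature_frames:
        features_all = pd.concat(feature_frames)
        predictions = _classifier.predict(model, features_all)

    lengths = {c.id: c.length for c in contigs}
    rows = []
    for c in contigs:
        if c.id in by_annotation:
            row = {
                "contig_id": c.id,
                "prediction": by_annotation[c.id],
                "provenance": "annotation",
                "vote_fraction": "",
            }
        else:
            row = {
                "contig_id": c.id,
                "prediction": predictions.loc[c.id, "prediction"],
                "provenance": "classifier",
                "vote_fraction": float(predictions.loc[c.id, "vote_fraction"]),
            }
        if show_best_hits:
            hits = hits_by_query.get(c.id, [])
            if hits:
                best = max(
                    hits,
                    key=lambda h: (compute_overlap(h, lengths[h.query_id]), -h.evalue),
                )
                row["best_hit_subject"] = best.subject_id
                row["best_hit_evalue"] = best.evalue
            else:
                row["best_hit_subject"] = ""
                row["best_hit_evalue"] = ""
        if show_features:
            if c.id in features_all.index:
                for name in _features.FEATURE_NAMES:
                    row[name] = features_all.loc[c.id, name]
            else:
                for name in _features.FEATURE_NAMES:
                    row[name] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """File-level classify pipeline: FASTA in, CSV out, manifest alongside."""
    contigs = read_fasta(config.input_fasta)
    database = read_fasta(config.database)
    model = _classifier.load_model(config.model)
    if config.verbose:
        logger.info(
            "classifying %d contigs against %d database sequences",
            len(contigs), len(database),
        )
    table = classify_contigs(
        contigs,
        database,
        model,
        reassign=config.reassign,
        show_best_hits=config.show_best_hits,
        show_features=config.show_features,
        threads=config.threads,
        size_of_batch=config.size_of_batch,
        homology_config=config.homology,
    )
    out = Path(config.output)
    _atomic_write_text(out, table.to_csv(index=False))
    manifest = {
        "tool": "repliclass",
        "version": __version__,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "homology"
        },
        "homology": dataclasses.asdict(config.homology or HomologyConfig()),
        "n_contigs": len(contigs),
    }
    _atomic_write_text(
        out.with_suffix(out.suffix + ".manifest.json"),
        json.dumps(manifest, indent=2, default=str) + "\n",
    )
    return table


@dataclass
class TrainResult:
    model: _classifier.ForestModel
    reports: list
    train_contigs: list[Contig]
    test_contigs: list[Contig]
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    balance_report: pd.DataFrame
    train_genomes: list[str]
    test_genomes: list[str]


def run_train(
    genomes: Mapping[str, Sequence[Contig]],
    database: Sequence[Contig],
    size_distribution: _shredder.SizeDistribution = _shredder.DEFAULT_SIZE_DISTRIBUTION,
    balance_spec: _shredder.BalanceSpec | None = None,
    train_fraction: float = 0.7,
    homology_config: HomologyConfig | None = None,
    n_trees: int = _classifier.N_TREES_DEFAULT,
    seed: int = 0,
) -> TrainResult:
    """Shred labelled genomes, balance, split 70/30, featurize, train, test.

    ``genomes`` maps genome id to its labelled replicons. All randomness
    (per-replicon shredding seeds, the balance down-sampling, the genome
    split, the forest) derives from the single ``seed``.
    """
    if len(genomes) < 2:
        raise ValidationError("need at least 2 genomes")
    master = np.random.default_rng(seed)
    contigs_by_genome: dict[str, list[Contig]] = {}
    for genome_id in sorted(genomes):
        shredded: list[Contig] = []
        for replicon in genomes[genome_id]:
            rep_seed = int(master.integers(0, 2**31 - 1))
            shredded.extend(
                _shredder.shred_replicon(replicon, size_distribution, seed=rep_seed)
            )
        contigs_by_genome[genome_id] = shredded
    split_seed = int(master.integers(0, 2**31 - 1))
    balance_seed = int(master.integers(0, 2**31 - 1))
    forest_seed = int(master.integers(0, 2**31 - 1))
    train_ids, test_ids = _shredder.split_genomes(
        sorted(genomes), train_fraction=train_fraction, seed=split_seed
    )
    train_raw = [c for g in train_ids for c in contigs_by_genome[g]]
    test_contigs = [c for g in test_ids for c in contigs_by_genome[g]]
    spec = balance_spec or _shredder.BalanceSpec(seed=balance_seed)
    train_contigs, balance_report = _shredder.balance_training_set(train_raw, spec)

    train_hits = run_homology_search(train_contigs, database, homology_config)
    test_hits = run_homology_search(test_contigs, database, homology_config)
    train_X = _features.features_table(train_contigs, train_hits)
    test_X = _features.features_table(test_contigs, test_hits)
    model = _classifier.train(
        train_X, [c.truth_label for c in train_contigs],
        n_trees=n_trees, seed=forest_seed,
    )
    pred = _classifier.predict(model, test_X)["prediction"]
    truth = pd.Series([c.truth_label for c in test_contigs], index=test_X.index)
    sizes = {c.id: c.length for c in test_contigs}
    reports = _evaluation.stratified_metrics(pred, truth, sizes)
    return TrainResult(
        model=model,
        reports=reports,
        train_contigs=train_contigs,
        test_contigs=test_contigs,
        train_features=train_X,
        test_features=test_X,
        balance_report=balance_report,
        train_genomes=train_ids,
        test_genomes=test_ids,
    )
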