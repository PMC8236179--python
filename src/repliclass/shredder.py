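"""Draft-genome simulation: replicon shredding, balancing, splits, fixtures.

Complete replicons are cut left-to-right into artificial contigs whose
target sizes follow a configurable empirical size distribution, mimicking
the contig sizes of real unassembled genomes. Training contigs are then
down-sampled per size bin so roughly 10% are plasmid-derived, and genomes
are split 70/30 into train/test at the genome level so no genome leaks
contigs into both sides.

``make_fixture`` builds a fully synthetic study system: a plasmid
reference database of i.i.d. random sequences, and genomes made of one
random chromosome plus plasmids that are point-mutated copies of database
sequences — so plasmid contigs carry detectable homology and chromosome
contigs do not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequence_io import CHROMOSOME, PLASMID, Contig

logger = logging.getLogger(__name__)

MIN_CONTIG_LEN = 50  # shorter fragments than any real read are discarded

#: Size-bin boundaries used to balance the training set (bp; last bin open).
BALANCE_BINS_DEFAULT: tuple[float, ...] = (
    50, 1e3, 2e3, 5e3, 1e4, 5e4, 1e5, math.inf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SizeDistribution:
    """Contig-size distribution as (lower, upper, probability) bins.

    Bins are [lower, upper) in bp, non-overlapping and ascending, with
    lower >= 50; target sizes are drawn uniformly within the chosen bin.
    """

    bins: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError("size distribution needs at least one bin")
        prev_upper = None
        total = 0.0
        for lower, upper, prob in self.bins:
            if lower < MIN_CONTIG_LEN:
                raise ValidationError(f"bin lower bound {lower} < {MIN_CONTIG_LEN}")
            if upper <= lower:
                raise ValidationError(f"empty bin [{lower},{upper})")
            if prev_upper is not None and lower < prev_upper:
                raise ValidationError("bins must be ascending and non-overlapping")
            if prob < 0:
                raise ValidationError("bin probabilities must be >= 0")
            prev_upper = upper
            total += prob
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"bin probabilities sum to {total}, not 1")

    def sample_sizes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        probs = np.array([b[2] for b in self.bins])
        which = rng.choice(len(self.bins), size=n, p=probs)
        lowers = np.array([b[0] for b in self.bins])
        uppers = np.array([b[1] for b in self.bins])
        return rng.integers(lowers[which], uppers[which])

    @classmethod
    def from_csv(cls, path) -> "SizeDistribution":
        """Two-column CSV: bin upper bound (bp), probability; lower bound of
        the first bin is 50, later bins abut."""
        table = pd.read_csv(path)
        uppers = table.iloc[:, 0].astype(int).tolist()
        probs = table.iloc[:, 1].astype(float).tolist()
        bins = []
        lower = MIN_CONTIG_LEN
        for upper, prob in zip(uppers, probs):
            bins.append((lower, upper, prob))
            lower = upper
        return cls(tuple(bins))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"upper_bp": [b[1] for b in self.bins],
             "probability": [b[2] for b in self.bins]}
        ).to_csv(path, index=False)


#: Default contig-size distribution of the synthetic fixtures: short-contig
#: dominated, as in real draft assemblies, but capped at 10 kb so fixture
#: replicons of tens of kb shred into enough contigs.
DEFAULT_SIZE_DISTRIBUTION = SizeDistribution(
    bins=(
        (50, 1000, 0.35),
        (1000, 2000, 0.25),
        (2000, 5000, 0.25),
        (5000, 10000, 0.15),
    )
)


@dataclass(frozen=True)
class BalanceSpec:
    """Per-size-bin down-sampling target for the training set."""

    size_bins: tuple[float, ...] = BALANCE_BINS_DEFAULT
    plasmid_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.size_bins) != sorted(self.size_bins):
            raise ValidationError("size bin boundaries must be ascending")
        if not (0.0 < self.plasmid_fraction < 1.0):
            raise ValidationError("plasmid_fraction must be in (0, 1)")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study system.

    Defaults give 50 genomes (one 40–60 kb chromosome plus 1–3 plasmids of
    2–10 kb copied from a 40-sequence database with 2% point mutations) —
    a scaled-down draft-genome cohort that shreds into roughly a thousand
    contigs.
    """

    n_db_plasmids: int = 40
    n_genomes: int = 50
    chromosome_length: tuple[int, int] = (40_000, 60_000)
    plasmid_length: tuple[int, int] = (2_000, 10_000)
    plasmids_per_genome: tuple[int, int] = (1, 3)
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_db_plasmids < 1 or self.n_genomes < 1:
            raise ValidationError("counts must be >= 1")
        if not (0.0 <= self.mutation_rate < 0.25):
            raise ValidationError("mutation_rate must be in [0, 0.25)")
        for lo, hi in (
            self.chromosome_length, self.plasmid_length, self.plasmids_per_genome
        ):
            if lo < 1 or hi < lo:
                raise ValidationError("ranges must satisfy 1 <= lo <= hi")


def shred_replicon(
    replicon: Contig,
    dist: SizeDistribution = DEFAULT_SIZE_DISTRIBUTION,
    min_len: int = MIN_CONTIG_LEN,
    seed: int = 0,
    mode: str = "per_draw",
) -> list[Contig]:
    """Cut one replicon left-to-right into contigs with sizes from ``dist``.

    Replicons are treated as linear. In the default ``per_draw`` mode each
    contig's target size is drawn independently; in ``quota`` mode a global
    list of target sizes long enough to cover the replicon is drawn up
    front and shuffled, fixing per-bin counts near their expectation. Any
    terminal fragment shorter than ``min_len`` is discarded, so the output
    tiles a prefix of the replicon. Contigs inherit the replicon's truth
    label and record their source coordinates.
    """
    if replicon.length < min_len:
        raise ValidationError(
            f"replicon {replicon.id!r} is shorter than min_len={min_len}"
        )
    if mode not in ("per_draw", "quota"):
        raise ValidationError(f"unknown shredding mode {mode!r}")
    rng = np.random.default_rng(seed)
    targets: list[int] = []
    if mode == "quota":
        min_size = min(b[0] for b in dist.bins)
        budget = replicon.length // min_size + 1
        targets = dist.sample_sizes(budget, rng).tolist()
        rng.shuffle(targets)
    contigs: list[Contig] = []
    pos = 0
    i = 0
    while pos < replicon.length:
        if mode == "per_draw":
            size = int(dist.sample_sizes(1, rng)[0])
        else:
            size = int(targets[len(contigs)])
        end = min(pos + size, replicon.length)
        if end - pos < min_len:
            break  # terminal remnant discarded
        i += 1
        contigs.append(
            Contig(
                id=f"{replicon.id}_c{i}",
                sequence=replicon.sequence[pos:end],
                truth_label=replicon.truth_label,
                source_id=replicon.id,
                source_start=pos,
                source_end=end,
            )
        )
        pos = end
    return contigs


def _bin_index(size: int, boundaries: Sequence[float]) -> int:
    for i in range(len(boundaries) - 1):
        if boundaries[i] <= size < boundaries[i + 1]:
            return i
    raise ValidationError(f"contig size {size} outside the size bins")


def balance_training_set(
    contigs: Sequence[Contig], spec: BalanceSpec | None = None
) -> tuple[list[Contig], pd.DataFrame]:
    """Down-sample per size bin toward the target plasmid fraction.

    Within each bin the over-represented class is randomly down-sampled
    (never duplicated) so the plasmid fraction is the closest achievable
    value to ``spec.plasmid_fraction``. Bins holding a single class cannot
    be balanced; they are kept unchanged and flagged in the report.

    Returns the balanced contigs (original relative order) and a per-bin
    report with before/after counts and an ``unbalanceable`` flag.
    """
    spec = spec or BalanceSpec()
    if len(contigs) == 0:
        raise ValidationError("cannot balance an empty contig collection")
    rng = np.random.default_rng(spec.seed)
    f = spec.plasmid_fraction
    bins: dict[int, dict[str, list[int]]] = {}
    for idx, c in enumerate(contigs):
        if c.truth_label not in (PLASMID, CHROMOSOME):
            raise ValidationError(f"contig {c.id!r} has no truth label")
        b = _bin_index(c.length, spec.size_bins)
        bins.setdefault(b, {PLASMID: [], CHROMOSOME: []})[c.truth_label].append(idx)
    keep: set[int] = set()
    rows = []
    for b in sorted(bins):
        plasmids = bins[b][PLASMID]
        chroms = bins[b][CHROMOSOME]
        p, c_ = len(plasmids), len(chroms)
        unbalanceable = p == 0 or c_ == 0
        keep_p, keep_c = p, c_
        if not unbalanceable:
            if p / (p + c_) > f:
                # too many plasmids: shrink them toward f of the fixed chroms
                keep_p = min(p, max(1, round(f * c_ / (1 - f))))
            elif p / (p + c_) < f:
                keep_c = min(c_, max(1, round(p * (1 - f) / f)))
            if keep_p < p:
                plasmids = rng.choice(plasmids, size=keep_p, replace=False).tolist()
            if keep_c < c_:
                chroms = rng.choice(chroms, size=keep_c, replace=False).tolist()
        else:
            logger.warning(
                "size bin %d holds a single class (%d plasmid / %d chromosome); "
                "unbalanceable, kept unchanged", b, p, c_,
            )
        keep.update(plasmids)
        keep.update(chroms)
        rows.append(
            {
                "bin": b,
                "lower_bp": spec.size_bins[b],
                "upper_bp": spec.size_bins[b + 1],
                "plasmid_before": p,
                "chromosome_before": c_,
                "plasmid_after": keep_p,
                "chromosome_after": keep_c,
                "unbalanceable": unbalanceable,
            }
        )
    balanced = [c for i, c in enumerate(contigs) if i in keep]
    return balanced, pd.DataFrame(rows)


def split_genomes(
    genome_ids: Sequence[str], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Partition genome ids into train/test sets at the genome level."""
    ids = list(genome_ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 genomes to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        base_idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def make_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[list[Contig], dict[str, list[Contig]], pd.DataFrame]:
    """Generate the synthetic plasmid database, genomes, and truth table.

    Returns ``(database, genomes, truth)`` where ``database`` is the list
    of reference plasmid sequences, ``genomes`` maps genome id to its
    labelled replicons (one chromosome plus its plasmids), and ``truth``
    is a table mapping every replicon to its class and, for plasmids, the
    database sequence it was copied (and mutated) from. Fully reproducible
    from ``spec.seed``.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    database = [
        Contig(
            id=f"dbp{i + 1:04d}",
            sequence=_random_sequence(
                int(rng.integers(spec.plasmid_length[0], spec.plasmid_length[1] + 1)),
                rng,
            ),
            truth_label=PLASMID,
        )
        for i in range(spec.n_db_plasmids)
    ]
    genomes: dict[str, list[Contig]] = {}
    rows = []
    for g in range(spec.n_genomes):
        genome_id = f"genome{g + 1:04d}"
        chrom_len = int(
            rng.integers(spec.chromosome_length[0], spec.chromosome_length[1] + 1)
        )
        replicons = [
            Contig(
                id=f"{genome_id}_chr",
                sequence=_random_sequence(chrom_len, rng),
                truth_label=CHROMOSOME,
            )
        ]
        rows.append(
            {"genome_id": genome_id, "replicon_id": f"{genome_id}_chr",
             "label": CHROMOSOME, "db_source": ""}
        )
        n_plasmids = int(
            rng.integers(spec.plasmids_per_genome[0], spec.plasmids_per_genome[1] + 1)
        )
        for p in range(n_plasmids):
            source = database[int(rng.integers(0, len(database)))]
            rep_id = f"{genome_id}_p{p + 1}"
            replicons.append(
                Contig(
                    id=rep_id,
                    sequence=_mutate(source.sequence, spec.mutation_rate, rng),
                    truth_label=PLASMID,
                )
            )
            rows.append(
                {"genome_id": genome_id, "replicon_id": rep_id,
                 "label": PLASMID, "db_source": source.id}
            )
        genomes[genome_id] = replicons
    return database, genomes, pd.DataFrame(rows)


def truth_table(contigs: Iterable[Contig]) -> pd.DataFrame:
    """Headered truth table (contig id, label, source id, start, end)."""
    return pd.DataFrame(
        [
            {
                "contig_id": c.id,
                "label": c.truth_label,
                "source_id": c.source_id or "",
                "source_start": c.source_start if c.source_start is not None else -1,
                "source_end": c.source_end if c.source_end is not None else -1,
            }
            for c in contigs
        ]
    )
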