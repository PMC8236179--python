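"""Per-contig feature vectors aggregated from filtered homology hits.

Each contig is summarised by seven predictors: the number of hits against
the plasmid database, four statistics of the per-hit query overlaps
(maximum, arithmetic mean, median, population variance), the contig size
in bp, and its G+C content. A contig with no hits gets all four overlap
statistics equal to 0 — the natural "no homology evidence" point — so the
classifier remains total over its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .homology import Hit, compute_overlap
from .sequence_io import Contig, gc_content

#: Column order of the feature table; models are trained and applied in
#: exactly this order.
FEATURE_NAMES: tuple[str, ...] = (
    "number_of_hits",
    "max_overlap",
    "average_overlap",
    "median_overlap",
    "variance_overlap",
    "contig_size",
    "gc_content",
)


@dataclass(frozen=True)
class FeatureVector:
    number_of_hits: int
    max_overlap: float
    average_overlap: float
    median_overlap: float
    variance_overlap: float
    contig_size: int
    gc_content: float

    def __post_init__(self) -> None:
        if self.number_of_hits == 0 and (
            self.max_overlap or self.average_overlap
            or self.median_overlap or self.variance_overlap
        ):
            raise ValidationError("zero-hit contig must have zero overlap stats")
        if self.max_overlap + 1e-12 < self.average_overlap:
            raise ValidationError("max overlap cannot be below the mean overlap")
        if self.max_overlap + 1e-12 < self.median_overlap:
            raise ValidationError("max overlap cannot be below the median overlap")
        if self.number_of_hits <= 1 and self.variance_overlap != 0:
            raise ValidationError("variance of <= 1 overlap must be 0")

    def as_tuple(self) -> tuple:
        return (
            self.number_of_hits,
            self.max_overlap,
            self.average_overlap,
            self.median_overlap,
            self.variance_overlap,
            self.contig_size,
            self.gc_content,
        )


def extract_features(contig: Contig, hits: Sequence[Hit]) -> FeatureVector:
    """Build the seven-feature vector for one contig from its hits.

    ``hits`` must already be e-value-filtered and restricted to this contig.
    The overlap statistics use the population (divide-by-n) variance, so a
    single hit yields variance 0, and the median of an even count is the
    midpoint of the two central values.
    """
    for h in hits:
        if h.query_id != contig.id:
            raise ValidationError(
                f"hit for query {h.query_id!r} passed with contig {contig.id!r}"
            )
    if hits:
        overlaps = np.array([compute_overlap(h, contig.length) for h in hits])
        max_o = float(overlaps.max())
        mean_o = float(overlaps.mean())
        median_o = float(np.median(overlaps))
        var_o = float(overlaps.var())  # population variance
    else:
        max_o = mean_o = median_o = var_o = 0.0
    return FeatureVector(
        number_of_hits=len(hits),
        max_overlap=max_o,
        average_overlap=mean_o,
        median_overlap=median_o,
        variance_overlap=var_o,
        contig_size=contig.length,
        gc_content=gc_content(contig.sequence),
    )


def features_table(
    contigs: Sequence[Contig], hits: Sequence[Hit]
) -> pd.DataFrame:
    """Feature table with one row per contig, indexed by contig id.

    Contigs with no hits are included with the zero-hit convention; row
    order follows the input contig order and is invariant to hit order.
    """
    ids = {c.id for c in contigs}
    by_query: dict[str, list[Hit]] = {}
    for h in hits:
        if h.query_id not in ids:
            raise ValidationError(
                f"hit references unknown contig {h.query_id!r}"
            )
        by_query.setdefault(h.query_id, []).append(h)
    rows = [
        extract_features(c, by_query.get(c.id, ())).as_tuple() for c in contigs
    ]
    return pd.DataFrame(
        rows,
        columns=list(FEATURE_NAMES),
        index=pd.Index([c.id for c in contigs], name="contig_id"),
    )


def write_features_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_features_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="contig_id")
    missing = [name for name in FEATURE_NAMES if name not in table.columns]
    if missing:
        raise ValidationError(f"feature CSV is missing columns: {missing}")
    return table[list(FEATURE_NAMES)]
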