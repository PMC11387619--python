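"""Error-profile characterization of call sets and truth-set benchmarking.

The profiler classifies a call set by the same evidence features the scorer
uses (proximity, co-occurrence, novelty, and the non-novel & co-occurring
combination); the benchmark scores calls against a known truth set with
precision, recall and F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .io import AlleleDatabase, AlignmentRecord
from .pileup import CandidateVariant
from .scoring import (
    annotate_cooccurrence,
    annotate_novelty,
    annotate_proximity,
)
from .simulate import SimulatedSample, TruthSet

Key = tuple[str, int, str]


def round_percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to 2 decimals (0 when total is 0)."""
    if total == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ErrorProfile:
    """Evidence-feature tallies over a call set (one call can hit several)."""

    total_variants: int
    proximity_count: int
    cooccurring_count: int
    novel_count: int
    nonnovel_cooccurring_count: int

    def __post_init__(self) -> None:
        for name in (
            "proximity_count",
            "cooccurring_count",
            "novel_count",
            "nonnovel_cooccurring_count",
        ):
            if getattr(self, name) > self.total_variants:
                raise ValueError(f"{name} exceeds total_variants")

    @property
    def empty(self) -> bool:
        return self.total_variants == 0

    @property
    def proximity_pct(self) -> float:
        return round_percent(self.proximity_count, self.total_variants)

    @property
    def cooccurring_pct(self) -> float:
        return round_percent(self.cooccurring_count, self.total_variants)

    @property
    def novel_pct(self) -> float:
        return round_percent(self.novel_count, self.total_variants)

    @property
    def nonnovel_cooccurring_pct(self) -> float:
        return round_percent(self.nonnovel_cooccurring_count, self.total_variants)

    def to_text(self, label: str = "calls") -> str:
        """Compact one-row report in the (count (pct)) layout."""
        return (
            f"{label}\t{self.total_variants}\t"
            f"{self.proximity_count} ({self.proximity_pct:.2f})\t"
            f"{self.cooccurring_count} ({self.cooccurring_pct:.2f})\t"
            f"{self.novel_count} ({self.novel_pct:.2f})"
        )


def profile_calls(
    calls: Sequence[CandidateVariant],
    db: AlleleDatabase | None = None,
    maf: float = 0.05,
    *,
    alignments: list[AlignmentRecord] | None = None,
    proximity_window: int = 5,
    reannotate: bool = False,
) -> ErrorProfile:
    """Classify a call set by its evidence features.

    By default the annotations already carried by the calls are tallied;
    with ``reannotate=True`` novelty (needs *db*), proximity, and
    co-occurrence (needs *alignments*) are recomputed first.
    """
    calls = list(calls)
    if reannotate:
        if db is not None:
            annotate_novelty(calls, db)
        annotate_proximity(calls, proximity_window)
        if alignments is not None:
            annotate_cooccurrence(calls, alignments, maf)
    return ErrorProfile(
        total_variants=len(calls),
        proximity_count=sum(c.is_proximal for c in calls),
        cooccurring_count=sum(c.cooccurring for c in calls),
        novel_count=sum(c.is_novel for c in calls),
        nonnovel_cooccurring_count=sum(
            (not c.is_novel) and c.cooccurring for c in calls
        ),
    )


@dataclass
class BenchmarkResult:
    """Precision / recall / F1 of a call set against a truth set.

    Metrics with a zero denominator are reported as 0.0 with the matching
    ``*_defined`` flag set to False, so averaging over many samples is total.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "BenchmarkResult":
        precision_defined = (tp + fp) > 0
        recall_defined = (tp + fn) > 0
        precision = tp / (tp + fp) if precision_defined else 0.0
        recall = tp / (tp + fn) if recall_defined else 0.0
        f1_defined = (precision + recall) > 0
        f1 = (
            2 * precision * recall / (precision + recall) if f1_defined else 0.0
        )
        return cls(
            tp, fp, fn, precision, recall, f1,
            precision_defined, recall_defined, f1_defined,
        )


def _call_keys(calls: Iterable) -> set[Key]:
    keys = set()
    for call in calls:
        keys.add(call.key if isinstance(call, CandidateVariant) else tuple(call))
    return keys


def score_calls(calls: Iterable, truth: TruthSet) -> BenchmarkResult:
    """TP/FP/FN on (gene, position, alt) identity against the truth set.

    Near-miss positions are plain FP + FN; there is no partial credit.
    """
    keys = _call_keys(calls)
    tp = len(keys & truth.variants)
    fp = len(keys - truth.variants)
    fn = len(truth.variants - keys)
    return BenchmarkResult.from_counts(tp, fp, fn)


def sweep(
    samples: Sequence[SimulatedSample],
    db: AlleleDatabase,
    maf_grid: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05),
    model_name: str = "clean",
    **call_kwargs,
) -> pd.DataFrame:
    """Mean precision/recall/F1 per (maf, minority-abundance) cell.

    Each simulated sample is called at every MAF of the grid with the chosen
    parameter model; results are averaged within cells keyed by MAF and the
    sample's minority abundance (as a whole percentage).
    """
    from .model import MinorityVariantModel

    rows = []
    for sample in samples:
        for maf in maf_grid:
            result = MinorityVariantModel(
                sample.alignments, db, maf=maf, model_name=model_name,
                **call_kwargs,
            ).fit()
            bench = result.score(sample.truth)
            rows.append(
                {
                    "maf": maf,
                    "minority_pct": round(sample.mix.minority_abundance * 100),
                    "precision": bench.precision,
                    "recall": bench.recall,
                    "f1": bench.f1,
                }
            )
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["maf", "minority_pct"], as_index=False)
        .agg(
            n=("f1", "size"),
            precision=("precision", "mean"),
            recall=("recall", "mean"),
            f1=("f1", "mean"),
        )
        .sort_values(["maf", "minority_pct"])
        .reset_index(drop=True)
    )
    return out
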