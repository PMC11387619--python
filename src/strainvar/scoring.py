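"""Evidence annotation and the SNV threshold-convergence algorithm.

Each minority-variant candidate is scored against four kinds of evidence:

* **novelty** (penalty ``np``) — the substitution is absent from every
  same-length database allele of the gene; sequencing errors are strongly
  enriched for novelty.
* **proximity** (penalty ``pp``) — another candidate lies within 5 bp;
  error bursts cluster.
* **density** (penalty ``dp``) — each additional candidate position within a
  15 bp window adds a further penalty term (count ``M``).
* **co-occurrence** (reward ``cor``) — the candidate rides the same reads as
  another candidate at a joint frequency above ``maf / 2``, the signature of
  a real minority strain rather than independent noise.

A candidate is retained while its relative abundance clears its personal
threshold.  The threshold starts at the user's minimum allele frequency (MAF)
and is adjusted by the four terms; the convergence loop then escalates the
co-occurrence reward and density penalty by the iteration-increase factor
``ii`` each round until the retained count stabilizes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .io import AlleleDatabase, AlignmentRecord
from .pileup import CandidateVariant

logger = logging.getLogger(__name__)

Key = tuple[str, int, str]


@dataclass(frozen=True)
class ParameterSet:
    """MAF plus the five tuned scoring values."""

    maf: float
    cor: float  # co-occurrence reward
    ii: float   # per-iteration escalation of cor and dp
    pp: float   # proximity penalty (multiplicative)
    np: float   # novelty penalty
    dp: float   # density penalty per clustered candidate

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 1):
            raise ValueError("maf must be in (0, 1]")
        for name in ("cor", "ii", "pp", "np", "dp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zeros(cls, maf: float) -> "ParameterSet":
        """Profiling mode: plain abundance thresholding at *maf*."""
        return cls(maf=maf, cor=0.0, ii=0.0, pp=0.0, np=0.0, dp=0.0)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def annotate_novelty(
    candidates: list[CandidateVariant],
    db: AlleleDatabase,
    template_lengths: dict[str, int] | None = None,
) -> list[CandidateVariant]:
    """Flag candidates whose alt base appears in no database allele of the gene.

    Only alleles whose length equals the gene's template length are consulted
    (positional identity).  When *template_lengths* is not given, any allele
    long enough to cover the position is consulted instead.  Novelty depends
    only on the database, so it is computed once per call set.
    """
    for cand in candidates:
        alleles = db.alleles(cand.gene_id)
        if template_lengths is not None:
            tlen = template_lengths[cand.gene_id]
            alleles = [a for a in alleles if len(a.sequence) == tlen]
        cand.is_novel = not any(
            cand.position < len(a.sequence)
            and a.sequence[cand.position] == cand.alt_base
            for a in alleles
        )
    return candidates


def _positions_by_gene(candidates) -> dict[str, np.ndarray]:
    by_gene: dict[str, set[int]] = {}
    for cand in candidates:
        by_gene.setdefault(cand.gene_id, set()).add(cand.position)
    return {g: np.array(sorted(p)) for g, p in by_gene.items()}


def annotate_proximity(
    candidates: list[CandidateVariant], window: int = 5
) -> list[CandidateVariant]:
    """Flag candidates with another candidate position within *window* bp.

    Two alt bases at the same position do not make each other proximal; the
    distance must be strictly positive.
    """
    positions = _positions_by_gene(candidates)
    for cand in candidates:
        pos = positions[cand.gene_id]
        delta = np.abs(pos - cand.position)
        cand.is_proximal = bool(np.any((delta > 0) & (delta <= window)))
    return candidates


def annotate_density(
    candidates: list[CandidateVariant], window: int = 15
) -> list[CandidateVariant]:
    """Count additional candidate positions within *window* bp on either side."""
    positions = _positions_by_gene(candidates)
    for cand in candidates:
        pos = positions[cand.gene_id]
        delta = np.abs(pos - cand.position)
        cand.density_M = int(np.sum((delta > 0) & (delta <= window)))
    return candidates


class CooccurrenceIndex:
    """Read-level joint frequencies between candidate pairs of one call set.

    For an ordered pair (A, B) in the same gene the joint frequency is the
    number of reads carrying both alt bases divided by the number of reads
    covering both positions with a base (``normalization="joint"``, default)
    or by the smaller single-position nucleotide depth
    (``normalization="single"``).  Pairs with no shared coverage have
    frequency 0.
    """

    def __init__(self, freq: dict[tuple[Key, Key], float]):
        self._freq = freq

    @classmethod
    def build(
        cls,
        candidates: list[CandidateVariant],
        alignments: list[AlignmentRecord],
        *,
        normalization: str = "joint",
    ) -> "CooccurrenceIndex":
        if normalization not in ("joint", "single"):
            raise ValueError("normalization must be 'joint' or 'single'")
        by_gene: dict[str, list[CandidateVariant]] = {}
        for cand in candidates:
            by_gene.setdefault(cand.gene_id, []).append(cand)
        joint: dict[tuple[int, int], int] = {}
        cover: dict[tuple[int, int], int] = {}
        offsets: dict[str, int] = {}
        flat: list[CandidateVariant] = []
        for gene_id, cands in by_gene.items():
            offsets[gene_id] = len(flat)
            flat.extend(cands)
        for rec in alignments:
            cands = by_gene.get(rec.gene_id)
            if not cands:
                continue
            base0 = offsets[rec.gene_id]
            covered: list[int] = []
            carrying: list[int] = []
            for i, cand in enumerate(cands):
                base = rec.base_at(cand.position)
                if base is None or base == "-":
                    continue
                covered.append(base0 + i)
                if base == cand.alt_base:
                    carrying.append(base0 + i)
            for a, b in itertools.combinations(covered, 2):
                cover[(a, b)] = cover.get((a, b), 0) + 1
            for a, b in itertools.combinations(carrying, 2):
                joint[(a, b)] = joint.get((a, b), 0) + 1
        freq: dict[tuple[Key, Key], float] = {}
        for (a, b), n_joint in joint.items():
            if normalization == "joint":
                denom = cover.get((a, b), 0)
            else:
                denom = min(flat[a].depth, flat[b].depth)
            if denom > 0:
                f = n_joint / denom
                freq[(flat[a].key, flat[b].key)] = f
                freq[(flat[b].key, flat[a].key)] = f
        return cls(freq)

    @classmethod
    def empty(cls) -> "CooccurrenceIndex":
        return cls({})

    def frequency(self, a: Key, b: Key) -> float:
        return self._freq.get((a, b), 0.0)

    def partners_above(
        self, key: Key, cutoff: float, allowed: set[Key] | None = None
    ) -> frozenset:
        out = set()
        for (a, b), f in self._freq.items():
            if a == key and f > cutoff and (allowed is None or b in allowed):
                out.add(b)
        return frozenset(out)


def annotate_cooccurrence(
    candidates: list[CandidateVariant],
    alignments: list[AlignmentRecord],
    maf: float,
    *,
    index: CooccurrenceIndex | None = None,
    normalization: str = "joint",
) -> list[CandidateVariant]:
    """Flag candidates co-occurring with another candidate above ``maf / 2``."""
    if index is None:
        index = CooccurrenceIndex.build(
            candidates, alignments, normalization=normalization
        )
    keys = {c.key for c in candidates}
    for cand in candidates:
        partners = index.partners_above(cand.key, maf / 2, allowed=keys)
        cand.partners = partners
        cand.cooccurring = bool(partners)
    return candidates


def variant_threshold(
    candidate: CandidateVariant,
    params: ParameterSet,
    current_cor: float | None = None,
    current_dp: float | None = None,
) -> float:
    """Per-candidate retention threshold in relative-abundance space.

    Starting from MAF, the adjustments are applied in fixed order — novelty,
    proximity (multiplicative), density, co-occurrence — and the result is
    floored at zero.  The order matters because the proximity penalty scales
    whatever threshold has accumulated so far.
    """
    cor = params.cor if current_cor is None else current_cor
    dp = params.dp if current_dp is None else current_dp
    t = params.maf
    if candidate.is_novel:
        t += params.maf * params.np
    if candidate.is_proximal:
        t += t * params.pp
    t += params.maf * dp * candidate.density_M
    if candidate.cooccurring:
        t -= params.maf * cor
    return max(t, 0.0)


@dataclass
class IterationState:
    iteration: int
    retained_count: int
    current_cor: float
    current_dp: float


@dataclass
class CallResult:
    """Outcome of the threshold-convergence loop."""

    final_variants: list[CandidateVariant]
    iterations_run: int
    converged: bool
    trace: list[IterationState] = field(default_factory=list)
    final_thresholds: dict[Key, float] = field(default_factory=dict)

    def keys(self) -> set[Key]:
        return {c.key for c in self.final_variants}

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.iteration, s.retained_count, s.current_cor, s.current_dp)
                for s in self.trace
            ],
            columns=["iteration", "retained_count", "current_cor", "current_dp"],
        )


def converge(
    candidates: list[CandidateVariant],
    params: ParameterSet,
    alignments: list[AlignmentRecord] | None = None,
    *,
    index: CooccurrenceIndex | None = None,
    max_iter: int = 100,
    proximity_window: int = 5,
    density_window: int = 15,
    recompute_on_survivors: bool = True,
) -> CallResult:
    """Run the threshold-convergence loop over annotated candidates.

    Novelty flags must already be set (database membership cannot change);
    proximity, density and co-occurrence are recomputed each iteration over
    the currently retained set by default, so removed noise stops penalizing
    true variants.  Dropped candidates never re-enter, which makes the
    retained count non-increasing and guarantees termination; *max_iter* is a
    safety valve, and exhausting it flags the result as unconverged.

    Co-occurrence evidence comes from *index* (or is built from *alignments*);
    with neither, no candidate is treated as co-occurring.
    """
    if index is None:
        index = (
            CooccurrenceIndex.build(candidates, alignments)
            if alignments is not None
            else CooccurrenceIndex.empty()
        )
    if not candidates:
        return CallResult([], 1, True, [IterationState(1, 0, params.cor, params.dp)])

    retained = list(candidates)
    cor_cur, dp_cur = params.cor, params.dp
    cutoff = params.maf / 2
    trace: list[IterationState] = []
    prev_count: int | None = None
    converged = False
    iterations = 0
    thresholds: dict[Key, float] = {}

    for iteration in range(1, max_iter + 1):
        iterations = iteration
        basis = retained if recompute_on_survivors else candidates
        annotate_proximity(basis, proximity_window)
        annotate_density(basis, density_window)
        allowed = {c.key for c in basis}
        for cand in basis:
            cand.partners = index.partners_above(cand.key, cutoff, allowed)
            cand.cooccurring = bool(cand.partners)
        thresholds = {
            c.key: variant_threshold(c, params, cor_cur, dp_cur) for c in retained
        }
        retained = [c for c in retained if c.abundance >= thresholds[c.key]]
        trace.append(IterationState(iteration, len(retained), cor_cur, dp_cur))
        if prev_count is not None and len(retained) == prev_count:
            converged = True
            break
        prev_count = len(retained)
        cor_cur += params.ii * params.cor
        dp_cur += params.ii * params.dp

    if not converged:
        logger.warning(
            "threshold convergence did not stabilize within %d iterations", max_iter
        )
    final_thresholds = {c.key: thresholds[c.key] for c in retained}
    return CallResult(retained, iterations, converged, trace, final_thresholds)
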