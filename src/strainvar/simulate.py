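"""Synthetic multi-strain marker-gene samples with known truth.

The generator emulates the experimental frame the caller targets: several
strains of one species, each defined by a database allele per gene plus
optional private substitutions, mixed at majority/minority abundances and
sampled to a fixed per-gene depth with an ONT-flavoured substitution/indel
error model.  Reads span single genes (the caller operates after per-gene
alignment, so inter-gene structure is irrelevant) and alignments are emitted
by construction — the true template and coordinates, not an aligner's guess.

Truth is the set of (gene, position, alt) where a minority strain's gene
consensus differs from the majority strain's, keyed in the majority frame.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import AlignmentRecord, AlleleDatabase, Read, OP_DEL, OP_INS, OP_MATCH
from .pileup import BASES, encode_sequence

Key = tuple[str, int, str]

_DUAL_MAJORITY = (0.90, 0.99)
_TRIPLE_MAJORITY = (0.80, 0.98)
_MINORITY = (0.01, 0.10)
#: Read lengths are drawn uniformly from this fraction of the gene length.
READ_LENGTH_RANGE = (0.7, 1.0)
_MEAN_READ_FRACTION = sum(READ_LENGTH_RANGE) / 2


@dataclass
class StrainSpec:
    """One strain: a database allele per gene plus private substitutions."""

    strain_id: str
    alleles: dict[str, str]  # gene_id -> allele_id
    substitutions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def gene_sequence(self, gene_id: str, db: AlleleDatabase) -> str:
        seq = list(db.get(gene_id, self.alleles[gene_id]).sequence)
        for pos, alt in self.substitutions.get(gene_id, ()):  # planted variants
            if seq[pos] == alt:
                raise ValueError(
                    f"{self.strain_id}/{gene_id}: substitution at {pos} equals "
                    "the allele base"
                )
            seq[pos] = alt
        return "".join(seq)


@dataclass
class MixSpec:
    """Strain composition of one simulated sample."""

    strains: list[StrainSpec]
    abundances: list[float]
    depth: int  # target per-gene coverage
    seed: int

    def __post_init__(self) -> None:
        if len(self.strains) != len(self.abundances):
            raise ValueError("one abundance per strain required")
        if len(self.strains) not in (2, 3):
            raise ValueError("only dual- and triple-strain mixes are supported")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 within 1e-9")
        majority = max(self.abundances)
        minorities = sorted(self.abundances)[:-1]
        lo, hi = _DUAL_MAJORITY if len(self.strains) == 2 else _TRIPLE_MAJORITY
        if not (lo <= majority <= hi):
            raise ValueError(f"majority abundance {majority} outside [{lo}, {hi}]")
        for m in minorities:
            if not (_MINORITY[0] <= m <= _MINORITY[1]):
                raise ValueError(f"minority abundance {m} outside {_MINORITY}")

    @property
    def majority_index(self) -> int:
        return int(np.argmax(self.abundances))

    @property
    def minority_abundance(self) -> float:
        return min(self.abundances)


@dataclass(frozen=True)
class SystematicErrorPair:
    """Two errors injected together on the same reads at a joint rate."""

    gene_id: str
    pos_a: int
    alt_a: str
    pos_b: int
    alt_b: str
    rate: float


@dataclass
class ErrorModel:
    """Per-base sequencing error model.

    Deletions default to twice the mismatch and insertion rates, the balance
    characteristic of nanopore reads.  ``cluster_fraction`` is the share of
    mismatch errors placed within 15 bp of a previously injected error on the
    same gene (error bursts); ``systematic_pairs`` injects co-occurring error
    pairs, emulating contaminated-style data where noise rides shared reads.
    Qualities are drawn per read around a mean Q of 18 +/- 4 so a default
    Q >= 14 filter removes a realistic tail; qualities are independent of the
    injected errors.
    """

    mismatch_rate: float = 0.01
    insertion_rate: float = 0.01
    deletion_rate: float = 0.02
    cluster_fraction: float = 0.0
    cluster_window: int = 15
    systematic_pairs: tuple[SystematicErrorPair, ...] = ()
    quality_mean: float = 18.0
    quality_sd: float = 4.0
    base_quality_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("mismatch_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0 <= self.cluster_fraction <= 1):
            raise ValueError("cluster_fraction must be in [0, 1]")

    @classmethod
    def noise_free(cls) -> "ErrorModel":
        return cls(mismatch_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
                   quality_mean=30.0, quality_sd=0.5)


@dataclass
class TruthSet:
    """Expected minority variants: (gene, 0-based position, alt base)."""

    variants: frozenset

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: Key) -> bool:
        return key in self.variants

    def __or__(self, other: "TruthSet") -> "TruthSet":
        return TruthSet(self.variants | other.variants)

    def restrict_to_map(self, vmap, maf: float, min_count: int = 3) -> "TruthSet":
        """The recoverable subset: truth variants whose realized pileup
        abundance is >= *maf* with count >= *min_count*."""
        from .pileup import BASE_INDEX

        kept = set()
        for gene_id, pos, alt in self.variants:
            if gene_id not in vmap:
                continue
            gp = vmap.gene(gene_id)
            count = int(gp.counts[pos, BASE_INDEX[alt]])
            depth = int(gp.depth[pos])
            if count >= min_count and depth > 0 and count / depth >= maf:
                kept.add((gene_id, pos, alt))
        return TruthSet(frozenset(kept))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tpos\talt\n")
            for gene_id, pos, alt in sorted(self.variants):
                fh.write(f"{gene_id}\t{pos}\t{alt}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthSet":
        variants = set()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("gene")
            for line in fh:
                gene_id, pos, alt = line.rstrip("\n").split("\t")
                variants.add((gene_id, int(pos), alt))
        return cls(frozenset(variants))


def make_synthetic_db(
    n_genes: int = 53,
    gene_len: int = 900,
    alleles_per_gene: int = 4,
    divergence: float = 0.01,
    seed: int = 0,
) -> AlleleDatabase:
    """Random marker-gene database in the rMLST shape (equal-length alleles).

    Gene ids follow the ``BACT000001`` pattern; allele ``1`` is the base
    sequence and each further allele substitutes ``ceil(divergence *
    gene_len)`` random positions.  Deterministic under *seed*.
    """
    if not (0 <= divergence <= 0.2):
        raise ValueError("divergence must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    db = AlleleDatabase()
    n_subs = int(np.ceil(divergence * gene_len))
    for g in range(n_genes):
        gene_id = f"BACT{g + 1:06d}"
        base = rng.integers(0, 4, size=gene_len)
        db.add(gene_id, "1", "".join(BASES[b] for b in base))
        for a in range(2, alleles_per_gene + 1):
            variant = base.copy()
            if n_subs:
                positions = rng.choice(gene_len, size=n_subs, replace=False)
                shifts = rng.integers(1, 4, size=n_subs)
                variant[positions] = (variant[positions] + shifts) % 4
            db.add(gene_id, str(a), "".join(BASES[b] for b in variant))
    return db


def type_expected_variants(
    strain_a: StrainSpec, strain_b: StrainSpec, db: AlleleDatabase
) -> TruthSet:
    """Positional diff of two strains' per-gene consensus sequences.

    *strain_a* is the majority (reference frame); every position where
    *strain_b* differs contributes (gene, pos, strain_b base).  Genes must use
    equal-length alleles.
    """
    variants = set()
    for gene_id in strain_a.alleles:
        if gene_id not in strain_b.alleles:
            continue
        seq_a = strain_a.gene_sequence(gene_id, db)
        seq_b = strain_b.gene_sequence(gene_id, db)
        if len(seq_a) != len(seq_b):
            raise ValueError(
                f"{gene_id}: allele lengths differ between strains "
                f"({len(seq_a)} vs {len(seq_b)}); positional diff impossible"
            )
        a = encode_sequence(seq_a)
        b = encode_sequence(seq_b)
        for pos in np.nonzero(a != b)[0]:
            variants.add((gene_id, int(pos), seq_b[pos]))
    return TruthSet(frozenset(variants))


def mix_truth(mix: MixSpec, db: AlleleDatabase) -> TruthSet:
    """Union of (majority vs each minority) consensus diffs."""
    majority = mix.strains[mix.majority_index]
    truth = TruthSet(frozenset())
    for i, strain in enumerate(mix.strains):
        if i == mix.majority_index:
            continue
        truth = truth | type_expected_variants(majority, strain, db)
    return truth


@dataclass
class SimulatedSample:
    mix: MixSpec
    reads: list[Read]
    alignments: list[AlignmentRecord]
    truth: TruthSet


def _runs_to_cigar(ops: np.ndarray) -> list[tuple[int, int]]:
    """Run-length-encode a per-column op array into CIGAR tuples."""
    if len(ops) == 0:
        return []
    boundaries = np.nonzero(np.diff(ops))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(ops)]))
    return [(int(ops[s]), int(e - s)) for s, e in zip(starts, ends)]


def _simulate_read(
    rng: np.random.Generator,
    strain_codes: np.ndarray,
    gene_len: int,
    error_model: ErrorModel,
    gene_error_pool: list[int],
    pairs: Sequence[SystematicErrorPair],
) -> tuple[int, np.ndarray, list[tuple[int, int]]]:
    """One read: (ref_start, read base codes, cigar)."""
    l_min = int(np.ceil(READ_LENGTH_RANGE[0] * gene_len))
    length = int(rng.integers(l_min, gene_len + 1))
    start = int(rng.integers(0, gene_len - length + 1))
    seg = strain_codes[start:start + length].copy()

    em = error_model
    n_mis = rng.binomial(length, em.mismatch_rate) if em.mismatch_rate else 0
    if n_mis:
        end = start + length - 1
        window = em.cluster_window
        mutated: set[int] = set()

        def place(pos: int) -> None:
            # never re-mutate a position within one read (no reversions)
            seg[pos - start] = (seg[pos - start] + rng.integers(1, 4)) % 4
            mutated.add(pos)
            gene_error_pool.append(pos)

        def draw(lo: int, hi: int) -> int | None:
            for _ in range(8):
                pos = int(rng.integers(lo, hi + 1))
                if pos not in mutated:
                    return pos
            return None

        budget = n_mis
        while budget > 0:
            budget -= 1
            clustered = em.cluster_fraction > 0 and (
                rng.random() < em.cluster_fraction
            )
            if not clustered:
                pos = draw(start, end)
                if pos is not None:
                    place(pos)
                continue
            reachable = [
                a for a in gene_error_pool if a - window <= end and a + window >= start
            ]
            if reachable:
                anchor = reachable[int(rng.integers(len(reachable)))]
                pos = draw(max(start, anchor - window), min(end, anchor + window))
                if pos is not None:
                    place(pos)
            else:
                # seed a fresh burst: a uniform error plus a companion within
                # the cluster window, so clustered errors always have a
                # neighbour from the first one on
                pos = draw(start, end)
                if pos is None:
                    continue
                place(pos)
                pos2 = draw(max(start, pos - window), min(end, pos + window))
                if pos2 is not None:
                    place(pos2)
                    budget = max(budget - 1, 0)
    for pair in pairs:
        if start <= pair.pos_a < start + length and start <= pair.pos_b < start + length:
            if rng.random() < pair.rate:
                seg[pair.pos_a - start] = encode_sequence(pair.alt_a)[0]
                seg[pair.pos_b - start] = encode_sequence(pair.alt_b)[0]

    del_mask = (
        rng.random(length) < em.deletion_rate
        if em.deletion_rate
        else np.zeros(length, dtype=bool)
    )
    ins_mask = (
        rng.random(length) < em.insertion_rate
        if em.insertion_rate
        else np.zeros(length, dtype=bool)
    )

    keep = ~del_mask
    read_codes = seg[keep]
    if ins_mask.any():
        ins_idx = np.nonzero(ins_mask)[0]
        # insert after column i -> before kept-array position cumsum(keep)[i]
        insert_at = np.cumsum(keep)[ins_idx]
        ins_bases = rng.integers(0, 4, size=len(ins_idx))
        read_codes = np.insert(read_codes, insert_at, ins_bases)
        ops = np.where(del_mask, OP_DEL, OP_MATCH).astype(np.int8)
        ops = np.insert(ops, ins_idx + 1, OP_INS)
    else:
        ops = np.where(del_mask, OP_DEL, OP_MATCH).astype(np.int8)
    return start, read_codes, _runs_to_cigar(ops)


def simulate_sample(
    mix: MixSpec,
    db: AlleleDatabase,
    error_model: ErrorModel | None = None,
) -> SimulatedSample:
    """Generate reads, by-construction alignments and truth for one mix.

    Per gene, the read count targets the mix depth given the mean read
    fraction, split across strains by a multinomial draw on the abundances.
    Deterministic under ``mix.seed``.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng(mix.seed)
    reads: list[Read] = []
    alignments: list[AlignmentRecord] = []
    pairs_by_gene: dict[str, list[SystematicErrorPair]] = {}
    for pair in em.systematic_pairs:
        pairs_by_gene.setdefault(pair.gene_id, []).append(pair)

    counter = itertools.count()
    base_array = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for gene_id in db.gene_ids():
        if gene_id not in mix.strains[0].alleles:
            continue
        gene_len = len(db.get(gene_id, mix.strains[0].alleles[gene_id]).sequence)
        n_reads = int(round(mix.depth / _MEAN_READ_FRACTION))
        per_strain = rng.multinomial(n_reads, mix.abundances)
        strain_codes = [
            encode_sequence(s.gene_sequence(gene_id, db)) for s in mix.strains
        ]
        gene_error_pool: list[int] = []
        gene_pairs = pairs_by_gene.get(gene_id, ())
        for s_idx, (strain, n_s) in enumerate(zip(mix.strains, per_strain)):
            allele_id = strain.alleles[gene_id]
            for _ in range(n_s):
                start, codes, cigar = _simulate_read(
                    rng, strain_codes[s_idx], gene_len, em, gene_error_pool,
                    gene_pairs,
                )
                seq = base_array[codes].tobytes().decode()
                mean_q = rng.normal(em.quality_mean, em.quality_sd)
                quals = np.clip(
                    np.rint(rng.normal(mean_q, em.base_quality_sd, size=len(seq))),
                    2, 41,
                ).astype(np.int64)
                read_id = f"read{next(counter):06d}_{gene_id}_{strain.strain_id}"
                reads.append(Read(read_id, seq, quals))
                alignments.append(
                    AlignmentRecord(
                        read_id=read_id,
                        gene_id=gene_id,
                        allele_id=allele_id,
                        ref_start=start,
                        cigar=cigar,
                        sequence=seq,
                        qualities=quals,
                    )
                )
    return SimulatedSample(mix, reads, alignments, mix_truth(mix, db))


def compose_mixtures(
    isolate_pool: Sequence[StrainSpec],
    max_combinations: int = 50,
    *,
    depth: int = 220,
    seed: int = 0,
) -> list[MixSpec]:
    """Dual- or triple-strain mix specs drawn from a pool of strains.

    Pools of two strains yield dual mixes (majority 90–99%), larger pools
    yield triple mixes (majority 80–98%, minorities 1–10% each); minority
    abundances are drawn uniformly and the majority absorbs the remainder.
    The number of specs is capped at *max_combinations*.
    """
    if len(isolate_pool) < 2:
        raise ValueError("need at least two strains to compose a mixture")
    rng = np.random.default_rng(seed)
    n_strains = 2 if len(isolate_pool) == 2 else 3
    combos = list(itertools.permutations(range(len(isolate_pool)), n_strains))
    rng.shuffle(combos)
    specs: list[MixSpec] = []
    for combo in combos:
        if len(specs) >= max_combinations:
            break
        if n_strains == 2:
            minority = float(rng.uniform(*_MINORITY))
            abundances = [1.0 - minority, minority]
        else:
            minorities = rng.uniform(*_MINORITY, size=2)
            abundances = [float(1.0 - minorities.sum()), *map(float, minorities)]
        specs.append(
            MixSpec(
                strains=[isolate_pool[i] for i in combo],
                abundances=abundances,
                depth=depth,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    if len(combos) >= max_combinations:
        # with a large pool the cap must be reached exactly
        assert len(specs) == max_combinations
    return specs


def subsample_reads(
    reads: Iterable[Read], fraction: float, seed: int = 100
) -> list[Read]:
    """Random read subsampling (seqtk-style) for users with their own FASTQs."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    return [r for r in reads if rng.random() < fraction]
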