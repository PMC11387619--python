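"""Top-allele selection, consensus variant map, and candidate extraction.

The variant map is the per-gene, per-position tally of observed nucleotides
from all alignments of a gene projected onto its best-supported allele (the
*template*).  Minority-variant candidates are non-consensus bases at a column
that clear a count floor and an abundance gate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlleleDatabase, AlignmentRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEL_INDEX = 4  # deletions tallied separately, never part of positional depth

# Map ASCII byte -> column index; N and anything else -> -1 (never tallied).
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A,C,G,T -> 0..3; N/other -> -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class GenePileup:
    gene_id: str
    template_allele_id: str
    template_seq: str
    counts: np.ndarray  # shape (len(template), 5): A C G T DEL

    @property
    def depth(self) -> np.ndarray:
        """Total positional depth: nucleotide counts only (DEL and N excluded)."""
        return self.counts[:, :4].sum(axis=1)


class VariantMap:
    """Per-gene consensus variant map (called bases and depths per position)."""

    def __init__(self) -> None:
        self.genes: dict[str, GenePileup] = {}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __iter__(self):
        return iter(self.genes.values())

    def gene(self, gene_id: str) -> GenePileup:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"gene not in variant map: {gene_id}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump (gene, pos, A, C, G, T, DEL, depth) for debugging."""
        rows = []
        for gp in self.genes.values():
            depth = gp.depth
            for pos in range(len(gp.template_seq)):
                a, c, g, t, d = gp.counts[pos]
                rows.append((gp.gene_id, pos, a, c, g, t, d, depth[pos]))
        return pd.DataFrame(
            rows, columns=["gene", "pos", "A", "C", "G", "T", "DEL", "depth"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_top_allele(
    alignments: list[AlignmentRecord], db: AlleleDatabase
) -> dict[str, str]:
    """Pick, per gene, the allele with the largest total aligned base count.

    The score of an allele is the number of read bases aligned to it
    (match + mismatch columns) summed over all its alignments; ties break to
    the lexicographically smallest allele id.
    """
    scores: dict[str, dict[str, int]] = {}
    for rec in alignments:
        _, read_pos = rec.column_arrays()
        n_bases = int((read_pos >= 0).sum())
        scores.setdefault(rec.gene_id, {}).setdefault(rec.allele_id, 0)
        scores[rec.gene_id][rec.allele_id] += n_bases
    top: dict[str, str] = {}
    for gene_id in db.gene_ids():
        per_allele = scores.get(gene_id)
        if not per_allele:
            logger.info("gene %s has no alignments; omitted", gene_id)
            continue
        best = max(per_allele.items(), key=lambda kv: (kv[1], ReverseStr(kv[0])))
        top[gene_id] = best[0]
    return top


class ReverseStr(str):
    """str whose ordering is reversed, for max()-with-min-tiebreak idioms."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def build_variant_map(
    alignments: list[AlignmentRecord],
    top_alleles: dict[str, str],
    db: AlleleDatabase,
) -> VariantMap:
    """Tally aligned read bases per template column.

    Alignments to a non-template allele of the same gene are projected onto
    the template positionally, which is valid only when the alleles have equal
    length (marker-gene alleles are typically length-conserved); unequal-length
    hits are dropped with a warning.  Deletions are tallied in their own
    column; insertions and N bases are ignored.
    """
    vmap = VariantMap()
    dropped = 0
    for gene_id, allele_id in top_alleles.items():
        template = db.get(gene_id, allele_id)
        vmap.genes[gene_id] = GenePileup(
            gene_id,
            allele_id,
            template.sequence,
            np.zeros((len(template.sequence), 5), dtype=np.int64),
        )
    for rec in alignments:
        gp = vmap.genes.get(rec.gene_id)
        if gp is None:
            continue
        if rec.allele_id != gp.template_allele_id:
            hit_len = len(db.get(rec.gene_id, rec.allele_id).sequence)
            if hit_len != len(gp.template_seq):
                dropped += 1
                continue
        refs, read_pos = rec.column_arrays()
        in_range = (refs >= 0) & (refs < len(gp.template_seq))
        refs, read_pos = refs[in_range], read_pos[in_range]
        has_base = read_pos >= 0
        codes = encode_sequence(rec.sequence)[read_pos[has_base]]
        valid = codes >= 0  # N bases never count toward any tally
        np.add.at(gp.counts, (refs[has_base][valid], codes[valid]), 1)
        np.add.at(gp.counts, (refs[~has_base], DEL_INDEX), 1)
    if dropped:
        warnings.warn(
            f"dropped {dropped} alignments to alleles whose length differs "
            "from the gene template (positional projection impossible)"
        )
    return vmap


def consensus_indices(gp: GenePileup) -> np.ndarray:
    """Per-column consensus base index; ties and zero depth fall to the template."""
    nt = gp.counts[:, :4]
    best = nt.max(axis=1)
    arg = nt.argmax(axis=1)
    template_codes = encode_sequence(gp.template_seq)
    tie = (nt == best[:, None]).sum(axis=1) > 1
    fallback = tie | (best == 0)
    arg = np.where(fallback, template_codes, arg)
    # N in the template with zero depth: keep template code (-1 handled by caller)
    return arg


def consensus_sequence(vmap: VariantMap, gene_id: str) -> str:
    """Most frequent nucleotide per column; tie or empty column -> template base."""
    gp = vmap.gene(gene_id)
    arg = consensus_indices(gp)
    out = []
    for pos, code in enumerate(arg):
        out.append(BASES[code] if code >= 0 else gp.template_seq[pos])
    return "".join(out)


@dataclass
class CandidateVariant:
    """A (gene, position, alt base) with support and evidence annotations.

    ``ref_base`` is the column consensus base, which equals the template base
    except where the majority strain itself differs from the database allele.
    Evidence flags start unset and are filled by the scoring layer.
    """

    gene_id: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    count: int
    depth: int
    is_novel: bool = False
    is_proximal: bool = False
    density_M: int = 0
    cooccurring: bool = False
    partners: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt base equals reference base")
        if not (0 < self.count <= self.depth):
            raise ValueError("count must satisfy 0 < count <= depth")

    @property
    def abundance(self) -> float:
        return self.count / self.depth

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.gene_id, self.position, self.alt_base)


def extract_candidates(
    vmap: VariantMap,
    maf: float,
    cor: float,
    min_count: int = 3,
    *,
    gate: str = "product",
) -> list[CandidateVariant]:
    """Initial minority-variant candidates from the variant map.

    A non-consensus nucleotide qualifies when its count is >= *min_count* and
    its relative abundance clears the entry gate.  The default gate is the
    literal product ``maf * cor``; ``gate="offset"`` uses the alternative
    reading ``maf - maf * cor`` (the two coincide at cor = 0.5).  The count
    floor applies at extraction only; the convergence loop afterwards works
    purely on abundances.
    """
    if not (0 < maf <= 1):
        raise ValueError("maf must be in (0, 1]")
    if gate == "product":
        min_abundance = maf * cor
    elif gate == "offset":
        min_abundance = maf - maf * cor
    else:
        raise ValueError(f"unknown gate {gate!r} (use 'product' or 'offset')")
    out: list[CandidateVariant] = []
    for gene_id in sorted(vmap.genes):
        gp = vmap.genes[gene_id]
        cons = consensus_indices(gp)
        depth = gp.depth
        nt = gp.counts[:, :4]
        enough = (nt >= min_count) & (depth[:, None] > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            abund = nt / np.where(depth[:, None] == 0, 1, depth[:, None])
        hits = enough & (abund >= min_abundance)
        hits[np.arange(len(cons)), np.clip(cons, 0, 3)] &= cons < 0  # drop consensus
        for pos, base_idx in zip(*np.nonzero(hits)):
            ref_code = cons[pos]
            ref = BASES[ref_code] if ref_code >= 0 else gp.template_seq[pos]
            if BASES[base_idx] == ref:
                continue
            out.append(
                CandidateVariant(
                    gene_id=gene_id,
                    position=int(pos),
                    ref_base=ref,
                    alt_base=BASES[base_idx],
                    count=int(nt[pos, base_idx]),
                    depth=int(depth[pos]),
                )
            )
    out.sort(key=lambda c: c.key)
    return out
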