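"""Model/results surface wiring the pipeline end to end.

:class:`MinorityVariantModel` is built from alignments and an allele database
and configured with the calling parameters; :meth:`fit` runs top-allele
selection, pileup, candidate extraction, evidence annotation and threshold
convergence, returning a :class:`MinorityVariantResults` that carries the
calls, the iteration trace and summary/reporting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import params as params_mod
from .benchmark import BenchmarkResult, ErrorProfile, profile_calls, score_calls
from .io import (
    AlignmentRecord,
    AlleleDatabase,
    load_allele_db,
    read_sam,
    write_calls_tsv,
)
from .pileup import (
    CandidateVariant,
    VariantMap,
    build_variant_map,
    extract_candidates,
    select_top_allele,
)
from .scoring import (
    CallResult,
    CooccurrenceIndex,
    ParameterSet,
    annotate_novelty,
    converge,
)
from .simulate import TruthSet


class MinorityVariantModel:
    """Minority-variant caller over marker-gene alignments.

    Parameters
    ----------
    alignments
        Read-to-allele alignment records (from :func:`strainvar.io.read_sam`
        or the simulator).
    database
        Marker-gene allele database; also the novelty oracle.
    maf
        Minimum allele frequency: the baseline abundance threshold.
    params
        Explicit :class:`ParameterSet`; overrides *model_name*.
    model_name
        Bundled trained parameter model to interpolate at *maf*
        (default ``"combined"``).
    min_count
        Minimum read support for a candidate (count floor at extraction).
    gate
        Candidate entry gate: ``"product"`` (abundance >= maf * cor) or
        ``"offset"`` (abundance >= maf - maf * cor).
    """

    def __init__(
        self,
        alignments: list[AlignmentRecord],
        database: AlleleDatabase,
        *,
        maf: float = 0.05,
        params: ParameterSet | None = None,
        model_name: str = "combined",
        min_count: int = 3,
        proximity_window: int = 5,
        density_window: int = 15,
        max_iter: int = 100,
        gate: str = "product",
        cooccurrence_normalization: str = "joint",
        recompute_on_survivors: bool = True,
    ):
        self.alignments = alignments
        self.database = database
        self.maf = maf
        self.params = params if params is not None else params_mod.lookup(
            maf, model_name
        )
        if abs(self.params.maf - maf) > 1e-12:
            self.params = ParameterSet(maf=maf, **{
                k: v for k, v in self.params.as_dict().items() if k != "maf"
            })
        self.min_count = min_count
        self.proximity_window = proximity_window
        self.density_window = density_window
        self.max_iter = max_iter
        self.gate = gate
        self.cooccurrence_normalization = cooccurrence_normalization
        self.recompute_on_survivors = recompute_on_survivors

    @classmethod
    def from_files(
        cls,
        sam_path: str | Path,
        db_path: str | Path,
        header_separator: str = "_",
        **kwargs,
    ) -> "MinorityVariantModel":
        db = load_allele_db(db_path, header_separator)
        alignments = read_sam(sam_path, db, header_separator)
        return cls(alignments, db, **kwargs)

    def fit(self) -> "MinorityVariantResults":
        top_alleles = select_top_allele(self.alignments, self.database)
        vmap = build_variant_map(self.alignments, top_alleles, self.database)
        candidates = extract_candidates(
            vmap, self.maf, self.params.cor, self.min_count, gate=self.gate
        )
        template_lengths = {
            gp.gene_id: len(gp.template_seq) for gp in vmap
        }
        annotate_novelty(candidates, self.database, template_lengths)
        index = CooccurrenceIndex.build(
            candidates,
            self.alignments,
            normalization=self.cooccurrence_normalization,
        )
        call_result = converge(
            candidates,
            self.params,
            index=index,
            max_iter=self.max_iter,
            proximity_window=self.proximity_window,
            density_window=self.density_window,
            recompute_on_survivors=self.recompute_on_survivors,
        )
        return MinorityVariantResults(
            model=self,
            variant_map=vmap,
            top_alleles=top_alleles,
            candidates=candidates,
            call_result=call_result,
        )


@dataclass
class MinorityVariantResults:
    """Fitted call set plus diagnostics."""

    model: MinorityVariantModel
    variant_map: VariantMap
    top_alleles: dict[str, str]
    candidates: list[CandidateVariant]  # initial extraction, annotated
    call_result: CallResult

    @property
    def variants(self) -> list[CandidateVariant]:
        return self.call_result.final_variants

    @property
    def iterations_run(self) -> int:
        return self.call_result.iterations_run

    @property
    def converged(self) -> bool:
        return self.call_result.converged

    @property
    def params(self) -> ParameterSet:
        return self.model.params

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": c.gene_id,
                "position": c.position,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "count": c.count,
                "depth": c.depth,
                "abundance": c.abundance,
                "novel": c.is_novel,
                "proximal": c.is_proximal,
                "density_M": c.density_M,
                "cooccurring": c.cooccurring,
                "threshold": self.call_result.final_thresholds.get(c.key),
            }
            for c in self.variants
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "position", "ref", "alt", "count", "depth",
                "abundance", "novel", "proximal", "density_M", "cooccurring",
                "threshold",
            ],
        )

    def trace_frame(self) -> pd.DataFrame:
        return self.call_result.trace_frame()

    def score(self, truth: TruthSet) -> BenchmarkResult:
        return score_calls(self.variants, truth)

    def profile(self, which: str = "final") -> ErrorProfile:
        """Evidence-feature profile of the final calls or the initial candidates."""
        calls = self.variants if which == "final" else self.candidates
        return profile_calls(calls)

    def save_calls(self, path: str | Path) -> None:
        write_calls_tsv(self.variants, path)

    def save_trace(self, path: str | Path) -> None:
        self.trace_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Minority variant calling summary",
            "================================",
            f"genes with alignments : {len(self.top_alleles)}",
            f"alignments            : {len(self.model.alignments)}",
            f"MAF                   : {p.maf:g}",
            "parameters            : "
            f"cor={p.cor:.4g} ii={p.ii:.4g} pp={p.pp:.4g} "
            f"np={p.np:.4g} dp={p.dp:.4g}",
            f"initial candidates    : {len(self.candidates)}",
            f"final variants        : {len(self.variants)}",
            f"iterations            : {self.iterations_run}"
            + ("" if self.converged else "  (NOT converged)"),
        ]
        frame = self.to_frame()
        if not frame.empty:
            lines.append("")
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)
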