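"""In-memory orchestration of the full funnel, shared by the CLI and tests.

Stages, in order: select significant SNPs -> sample a matched random
control set -> top-Q filter the eQTL catalog -> intersect both SNP sets
with the catalog under allele harmonization -> subtract control-overlapping
signals -> chi-square enrichment -> classify desired actions -> match drugs
-> prioritize by CNS tissue -> annotate known genes and orthologs.  Every
stage's counts land in the funnel dict so that input/output/removal
accounting is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from . import drugs, pipeline
from .errors import DataError
from .models import (
    CandidatePair,
    DrugInteraction,
    EnrichmentResult,
    EqtlAssociation,
    GwasRecord,
    MatchedTarget,
    OrthologRecord,
    SnpSet,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds for one pipeline run (all defaults logged on use)."""

    p_threshold: float = 5e-3
    q_fraction: float = 0.05
    per_tissue_q: bool = False
    approved_only: bool = True
    control_from_full: bool = False
    yates: bool = False
    min_ortholog_identity: float = 50.0
    seed: int = 0


@dataclass
class PipelineResult:
    significant: SnpSet
    control: SnpSet
    sig_matches: List[MatchedTarget]
    ctrl_matches: List[MatchedTarget]
    final_matches: List[MatchedTarget]
    enrichment: Optional[EnrichmentResult]
    intervenable_genes: FrozenSet[str]
    candidates: Tuple[CandidatePair, ...]
    prioritized: List[CandidatePair]
    known_overlap: FrozenSet[str]
    funnel: Dict[str, int]
    reports: Dict[str, object] = field(default_factory=dict)


def run_pipeline(
    gwas_records: Sequence[GwasRecord],
    eqtls: Sequence[EqtlAssociation],
    interactions: Sequence[DrugInteraction],
    params: PipelineParams = PipelineParams(),
    cns_tissues: Optional[Sequence[str]] = None,
    exclude_genes: Sequence[str] = (),
    include_pairs: Sequence[CandidatePair] = (),
    known_genes: Optional[Sequence[str]] = None,
    orthologs: Optional[Sequence[OrthologRecord]] = None,
) -> PipelineResult:
    """Run the full funnel in memory and return every intermediate product."""
    log.info(
        "pipeline start: %d GWAS records, %d eQTL rows, %d interactions; "
        "p<=%g, top %.0f%% Q, seed=%d",
        len(gwas_records), len(eqtls), len(interactions),
        params.p_threshold, 100 * params.q_fraction, params.seed,
    )
    significant = pipeline.select_significant_snps(gwas_records, params.p_threshold)
    if len(significant) == 0:
        raise DataError(
            f"no SNPs pass p <= {params.p_threshold}; nothing to analyze"
        )
    control = pipeline.sample_control_snps(
        gwas_records, exclude=significant, size=len(significant),
        seed=params.seed, from_full=params.control_from_full,
    )
    top_eqtls = pipeline.filter_top_q(eqtls, params.q_fraction, per_tissue=params.per_tissue_q)

    sig_matches, sig_report = pipeline.intersect_eqtls(significant, gwas_records, top_eqtls)
    ctrl_matches, ctrl_report = pipeline.intersect_eqtls(control, gwas_records, top_eqtls)
    final_matches, subtract_report = pipeline.subtract_control_overlap(sig_matches, ctrl_matches)

    enrichment: Optional[EnrichmentResult] = None
    enrichment_note = None
    try:
        enrichment = pipeline.eqtl_enrichment_test(
            n_sig_eqtl=sig_report["n_matched_snps"],
            n_sig_total=len(significant),
            n_ctrl_eqtl=ctrl_report["n_matched_snps"],
            n_ctrl_total=len(control),
            yates=params.yates,
        )
    except DataError as exc:
        enrichment_note = str(exc)
        log.warning("enrichment test skipped: %s", exc)

    classified = drugs.attach_desired_actions(final_matches)
    match_result = drugs.match_drugs(
        classified, interactions, approved_only=params.approved_only
    )
    prioritized, prio_report = drugs.prioritize(
        match_result.candidates,
        cns_tissues=cns_tissues,
        exclude_genes=exclude_genes,
        include_pairs=include_pairs,
    )
    known_overlap: FrozenSet[str] = frozenset()
    if known_genes:
        target_genes = {m.gene_symbol or m.gene_id for m in final_matches}
        overlap, _ = drugs.annotate_known_genes(target_genes, known_genes)
        known_overlap = frozenset(overlap)
        known_upper = {g.upper() for g in known_genes}
        prioritized = [
            c.with_flags("known_ad_gene") if c.gene_symbol.upper() in known_upper else c
            for c in prioritized
        ]
    if orthologs:
        prioritized = drugs.annotate_orthologs(
            prioritized, orthologs, min_identity=params.min_ortholog_identity
        )

    funnel = {
        "n_gwas_records": len(gwas_records),
        "n_significant_snps": len(significant),
        "n_control_snps": len(control),
        "n_eqtl_associations": len(eqtls),
        "n_eqtl_top_q": len(top_eqtls),
        "n_sig_match_rows": sig_report["n_match_rows"],
        "n_sig_matched_snps": sig_report["n_matched_snps"],
        "n_ctrl_match_rows": ctrl_report["n_match_rows"],
        "n_ctrl_matched_snps": ctrl_report["n_matched_snps"],
        "n_overlap_removed": subtract_report["n_removed"],
        "n_final_eqtl_rows": subtract_report["n_kept"],
        "n_target_genes": subtract_report["n_distinct_genes"],
        "n_intervenable_genes": match_result.report["n_intervenable_genes"],
        "n_candidate_pairs": match_result.report["n_candidate_pairs"],
        "n_candidate_genes": match_result.report["n_candidate_genes"],
        "n_prioritized_pairs": len(prioritized),
        "n_prioritized_genes": len({c.gene_symbol for c in prioritized}),
        "n_known_gene_matches": len(known_overlap),
    }
    reports = {
        "intersect_significant": sig_report,
        "intersect_control": ctrl_report,
        "subtract": subtract_report,
        "match": dict(match_result.report),
        "prioritize": prio_report,
    }
    if enrichment_note:
        reports["enrichment_note"] = enrichment_note
    return PipelineResult(
        significant=significant,
        control=control,
        sig_matches=sig_matches,
        ctrl_matches=ctrl_matches,
        final_matches=classified,
        enrichment=enrichment,
        intervenable_genes=match_result.intervenable_genes,
        candidates=match_result.candidates,
        prioritized=prioritized,
        known_overlap=known_overlap,
        funnel=funnel,
        reports=reports,
    )
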