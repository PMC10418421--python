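"""Directionality rule, drug matching, and the prioritization funnel.

The central idea: a drug should mimic the protective genetic state.  If a
risk allele (odds ratio > 1) raises a gene's expression, or a protective
allele (odds ratio < 1) lowers it, reducing the gene product is desirable —
search for an inhibitor-class drug.  In the opposite quadrants an
activator-class drug is desired.  Matched targets are joined to the
interaction database by gene symbol, filtered to interaction types
compatible with the desired action, and narrowed to genes whose eQTL tissue
is central-nervous-system relevant.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ConfigurationError, DataError
from .models import (
    CandidatePair,
    DesiredAction,
    DrugInteraction,
    GeneAnnotation,
    MatchedTarget,
    OrthologRecord,
)

log = logging.getLogger(__name__)

#: interaction-type vocabulary compatible with each desired action
DEFAULT_VOCABULARY: Dict[DesiredAction, FrozenSet[str]] = {
    DesiredAction.INHIBITOR: frozenset(
        {"inhibitor", "antagonist", "blocker", "negative modulator", "inverse agonist"}
    ),
    DesiredAction.ACTIVATOR: frozenset(
        {"activator", "agonist", "positive modulator", "inducer"}
    ),
}

#: tissue labels treated as central nervous system, in addition to any label
#: containing "brain" (case-insensitive)
DEFAULT_CNS_TISSUES: FrozenSet[str] = frozenset(
    {
        "Putamen",
        "Cerebellum",
        "Caudate",
        "Substantianigra",
        "Amygdala",
        "Cortex",
        "Frontalcortex (BA9)",
        "Hippocampus",
        "Hypothalamus",
        "Spinalcord",
    }
)


def classify_direction(odds_ratio: float, slope: float) -> DesiredAction:
    """Infer the desired drug action from the joint sign of OR and slope.

    inhibitor iff sign(ln OR) * sign(slope) > 0, activator iff < 0,
    indeterminate when either factor is exactly null (OR = 1 or slope = 0).
    """
    if not (odds_ratio > 0 and math.isfinite(odds_ratio)):
        raise DataError(f"odds ratio must be positive and finite, got {odds_ratio}")
    if not math.isfinite(slope):
        raise DataError(f"slope must be finite, got {slope}")
    product = np.sign(math.log(odds_ratio)) * np.sign(slope)
    if product > 0:
        return DesiredAction.INHIBITOR
    if product < 0:
        return DesiredAction.ACTIVATOR
    return DesiredAction.INDETERMINATE


def map_action_to_interaction_types(
    action: DesiredAction,
    vocabulary: Optional[Mapping[DesiredAction, Iterable[str]]] = None,
) -> FrozenSet[str]:
    """Interaction-type strings compatible with ``action`` (user-overridable)."""
    if action == DesiredAction.INDETERMINATE:
        raise DataError("indeterminate targets have no compatible interaction types")
    vocab = DEFAULT_VOCABULARY if vocabulary is None else vocabulary
    try:
        return frozenset(vocab[action])
    except KeyError:
        raise ConfigurationError(f"vocabulary has no entry for action {action.value!r}") from None


def attach_desired_actions(targets: Sequence[MatchedTarget]) -> List[MatchedTarget]:
    """Classify every matched target, returning copies carrying desired_action."""
    return [t.with_action(classify_direction(t.odds_ratio, t.slope)) for t in targets]


@dataclass(frozen=True)
class MatchResult:
    """Nested output of drug matching.

    ``intervenable_genes``: genes with at least one (approved) interaction of
    any type.  ``candidates``: pairs whose interaction type is compatible
    with the target's desired action — always a subset of the intervenable
    genes.
    """

    intervenable_genes: FrozenSet[str]
    candidates: Tuple[CandidatePair, ...]
    report: Mapping = field(default_factory=dict)


def match_drugs(
    targets: Sequence[MatchedTarget],
    interactions: Sequence[DrugInteraction],
    approved_only: bool = True,
    vocabulary: Optional[Mapping[DesiredAction, Iterable[str]]] = None,
) -> MatchResult:
    """Join desired-action targets to the drug-interaction table by gene symbol.

    Targets must carry ``desired_action`` (see :func:`attach_desired_actions`);
    indeterminate targets are excluded and counted.  Genes whose targets
    disagree on direction across tissues are kept per (gene, tissue) and
    listed under ``conflicting_direction_genes`` in the report.
    """
    usable = [i for i in interactions if i.approved or not approved_only]
    by_gene: Dict[str, List[DrugInteraction]] = defaultdict(list)
    for i in usable:
        by_gene[i.gene_symbol.upper()].append(i)

    n_indeterminate = 0
    n_missing_action = 0
    candidates: List[CandidatePair] = []
    intervenable: Set[str] = set()
    actions_per_gene: Dict[str, Set[DesiredAction]] = defaultdict(set)
    for t in targets:
        if t.desired_action is None:
            n_missing_action += 1
            raise DataError(f"target {t.rsid}/{t.gene_id} lacks a desired action; classify first")
        symbol = (t.gene_symbol or t.gene_id).strip()
        key = symbol.upper()
        gene_interactions = by_gene.get(key, [])
        if gene_interactions:
            intervenable.add(symbol)
        if t.desired_action == DesiredAction.INDETERMINATE:
            n_indeterminate += 1
            continue
        actions_per_gene[key].add(t.desired_action)
        allowed = map_action_to_interaction_types(t.desired_action, vocabulary)
        for i in gene_interactions:
            if i.interaction_type in allowed:
                candidates.append(
                    CandidatePair(
                        gene_symbol=symbol,
                        gene_id=t.gene_id,
                        tissue=t.tissue,
                        rsid=t.rsid,
                        odds_ratio=t.odds_ratio,
                        slope=t.slope,
                        q_value=t.q_value,
                        desired_action=t.desired_action,
                        drug_name=i.drug_name,
                        interaction_type=i.interaction_type,
                        approved=i.approved,
                    )
                )
    conflicting = sorted(g for g, acts in actions_per_gene.items() if len(acts) > 1)
    report = {
        "n_targets": len(targets),
        "n_indeterminate": n_indeterminate,
        "n_intervenable_genes": len(intervenable),
        "n_candidate_pairs": len(candidates),
        "n_candidate_genes": len({c.gene_symbol for c in candidates}),
        "conflicting_direction_genes": conflicting,
    }
    if conflicting:
        log.info("genes with conflicting desired actions across tissues: %s", conflicting)
    return MatchResult(
        intervenable_genes=frozenset(intervenable),
        candidates=tuple(candidates),
        report=report,
    )


def is_cns_tissue(tissue: str, cns_tissues: Optional[Iterable[str]] = None) -> bool:
    cns = DEFAULT_CNS_TISSUES if cns_tissues is None else frozenset(cns_tissues)
    return tissue in cns or "brain" in tissue.lower()


def prioritize(
    candidates: Sequence[CandidatePair],
    cns_tissues: Optional[Iterable[str]] = None,
    exclude_genes: Iterable[str] = (),
    include_pairs: Sequence[CandidatePair] = (),
) -> Tuple[List[CandidatePair], Dict[str, object]]:
    """Keep CNS-tissue candidates, drop excluded genes, append manual inclusions.

    Manual inclusions are appended verbatim with a ``manually_included``
    flag (they exist precisely because they fail the automatic criteria).
    A manual inclusion of an excluded gene is a contradictory configuration
    and raises.  Output is stably sorted by (gene, drug).
    """
    excluded_upper = {g.upper() for g in exclude_genes}
    for p in include_pairs:
        if p.gene_symbol.upper() in excluded_upper:
            raise ConfigurationError(
                f"contradictory config: gene {p.gene_symbol!r} is both excluded "
                f"and manually included (drug {p.drug_name!r})"
            )
    kept: List[CandidatePair] = []
    excluded_rows: List[str] = []
    for c in candidates:
        if c.gene_symbol.upper() in excluded_upper:
            excluded_rows.append(c.gene_symbol)
            continue
        if is_cns_tissue(c.tissue, cns_tissues):
            kept.append(c.with_flags("cns_tissue"))
    kept.extend(p.with_flags("manually_included") for p in include_pairs)
    kept.sort(key=lambda c: (c.gene_symbol, c.drug_name))
    report = {
        "n_input": len(candidates),
        "n_kept": len(kept),
        "n_excluded_known": len(excluded_rows),
        "excluded_genes_seen": sorted(set(excluded_rows)),
        "n_manually_included": len(include_pairs),
    }
    return kept, report


def annotate_known_genes(candidate_genes: Iterable[str], known: Iterable[str]):
    """Exact (case-normalized) overlap between candidate genes and a known list."""
    cand = {g.upper(): g for g in candidate_genes}
    known_upper = {g.upper() for g in known}
    overlap = {cand[g] for g in cand if g in known_upper}
    return overlap, len(overlap)


def annotate_orthologs(
    candidates: Sequence[CandidatePair],
    orthologs: Sequence[OrthologRecord],
    min_identity: float = 50.0,
) -> List[CandidatePair]:
    """Flag candidates whose gene has a model-organism ortholog.

    A gene qualifies via a curated-source record (identity irrelevant) or an
    alignment-source record with at least ``min_identity`` percent identity.
    """
    if not 0 <= min_identity <= 100:
        raise ConfigurationError(f"min_identity must be in [0, 100], got {min_identity}")
    has: Set[str] = set()
    for o in orthologs:
        if o.source == "curated" or o.percent_identity >= min_identity:
            has.add(o.human_gene.upper())
    return [
        c.with_flags("has_ortholog") if c.gene_symbol.upper() in has else c
        for c in candidates
    ]


def nearest_gene_assignment(
    snps: Sequence, annotation: Sequence[GeneAnnotation]
) -> Tuple[Dict[str, str], List[str]]:
    """Assign each SNP to its nearest annotated gene (structural assignment).

    ``snps`` yields objects with ``rsid``, ``chrom`` and 1-based ``pos``.
    Distance to a gene interval [start, end) is 0 inside the gene; ties
    break lexicographically by gene_id.  SNPs on chromosomes without genes
    are returned unassigned.
    """
    per_chrom: Dict[str, List[GeneAnnotation]] = defaultdict(list)
    for g in annotation:
        per_chrom[g.chrom].append(g)
    arrays = {}
    for chrom, genes in per_chrom.items():
        genes.sort(key=lambda g: g.gene_id)  # argmin then picks the smallest id on ties
        arrays[chrom] = (
            np.array([g.start for g in genes]),
            np.array([g.end for g in genes]),
            [g.gene_id for g in genes],
        )
    assigned: Dict[str, str] = {}
    unassigned: List[str] = []
    for s in snps:
        entry = arrays.get(s.chrom)
        if entry is None:
            unassigned.append(s.rsid)
            continue
        starts, ends, ids = entry
        pos0 = s.pos - 1
        dist = np.maximum(starts - pos0, 0) + np.maximum(pos0 - (ends - 1), 0)
        assigned[s.rsid] = ids[int(np.argmin(dist))]
    if unassigned:
        log.info("%d SNPs on chromosomes with no annotated genes", len(unassigned))
    return assigned, unassigned


def compare_assignments(
    functional: Mapping[str, Set[str]], structural: Mapping[str, str]
) -> float:
    """Fraction of shared SNPs whose nearest gene is absent from the functional gene set.

    Quantifies how often a structural (nearest-gene) assignment disagrees
    with the expression-based assignment.
    """
    shared = set(functional) & set(structural)
    if not shared:
        raise DataError("no shared rsids between functional and structural assignments")
    discordant = sum(1 for r in shared if structural[r] not in functional[r])
    return discordant / len(shared)
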