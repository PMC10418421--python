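"""Domain record types shared across the pipeline.

The pipeline moves from per-SNP disease associations (:class:`GwasRecord`)
through tissue expression effects (:class:`EqtlAssociation`) to harmonized
SNP-gene-tissue targets (:class:`MatchedTarget`) and finally to prioritized
gene-drug pairs (:class:`CandidatePair`).  Everything is an immutable
dataclass so stages can be re-run and compared without aliasing surprises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import cached_property
from typing import Mapping, Optional


class DesiredAction(str, Enum):
    """Pharmacological action wanted at a target.

    ``inhibitor``: reduce the protein's activity; chosen when the disease
    risk direction and the expression direction agree in sign (a risk allele
    raises expression, or a protective allele lowers it), so lowering the
    gene product mimics the protective state.  ``activator`` covers the
    opposite quadrants; ``indeterminate`` marks targets with a null effect
    on either axis.
    """

    INHIBITOR = "inhibitor"
    ACTIVATOR = "activator"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True, slots=True)
class GwasRecord:
    """One SNP's disease-association summary.

    ``beta`` is the natural-log odds ratio per copy of ``effect_allele``;
    ``other_allele`` is the non-effect (reference) allele.  Positions are
    1-based.
    """

    rsid: str
    chrom: str
    pos: int
    other_allele: str
    effect_allele: str
    beta: float
    p_value: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True, slots=True)
class EqtlAssociation:
    """One significant variant-gene expression association in a tissue.

    ``slope`` is the change in normalized expression per copy of ``alt``;
    ``q_value`` is the minimum FDR at which the association is called
    significant.  Coordinates are parsed out of the ``chr{c}_{pos}_{ref}_
    {alt}_{build}`` variant id (1-based position).
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    build: str
    gene_id: str
    tissue: str
    slope: float
    q_value: float
    gene_symbol: Optional[str] = None


@dataclass(frozen=True, slots=True)
class DrugInteraction:
    """One gene-drug relation from the interaction database."""

    gene_symbol: str
    drug_name: str
    interaction_type: str
    approved: bool
    pubchem_id: Optional[str] = None


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """Gene interval, stored 0-based half-open internally."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass(frozen=True, slots=True)
class OrthologRecord:
    """A human gene's predicted or curated model-organism ortholog."""

    human_gene: str
    ortholog_gene: str
    percent_identity: float
    source: str = "alignment"  # {curated, alignment}

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )


@dataclass(frozen=True)
class SnpSet:
    """An ordered, de-duplicated set of rsids with its provenance.

    ``threshold_or_seed`` records the p-value cutoff for the significant set
    or the RNG seed for the sampled control set.
    """

    label: str
    rsids: tuple
    threshold_or_seed: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rsids", tuple(dict.fromkeys(self.rsids)))

    @cached_property
    def rsid_set(self) -> frozenset:
        return frozenset(self.rsids)

    def __len__(self) -> int:
        return len(self.rsids)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.rsid_set


@dataclass(frozen=True, slots=True)
class MatchedTarget:
    """A GWAS SNP harmonized to a tissue eQTL.

    Both ``beta`` (= ln odds ratio) and ``slope`` are expressed per copy of
    the GWAS effect allele: when the effect allele is the eQTL's reference
    allele the slope sign is negated and ``harmonization`` is ``flipped``,
    otherwise ``direct``.
    """

    rsid: str
    gene_id: str
    gene_symbol: Optional[str]
    tissue: str
    beta: float
    odds_ratio: float
    slope: float
    q_value: float
    harmonization: str  # {direct, flipped}
    desired_action: Optional[DesiredAction] = None

    def with_action(self, action: DesiredAction) -> "MatchedTarget":
        return replace(self, desired_action=action)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """2x2 Pearson chi-square comparison of eQTL rates in two SNP sets."""

    n_sig_eqtl: int
    n_sig_total: int
    n_ctrl_eqtl: int
    n_ctrl_total: int
    proportion_sig: float
    proportion_ctrl: float
    chi2_statistic: float
    df: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "n_sig_eqtl": self.n_sig_eqtl,
            "n_sig_total": self.n_sig_total,
            "n_ctrl_eqtl": self.n_ctrl_eqtl,
            "n_ctrl_total": self.n_ctrl_total,
            "proportion_sig": self.proportion_sig,
            "proportion_ctrl": self.proportion_ctrl,
            "chi2_statistic": self.chi2_statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


#: priority flags a CandidatePair may carry
PRIORITY_FLAGS = frozenset(
    {"cns_tissue", "manually_included", "excluded_known", "known_ad_gene", "has_ortholog"}
)


@dataclass(frozen=True, slots=True)
class CandidatePair:
    """A prioritized (gene, tissue, SNP, drug, action) row — the pipeline's product."""

    gene_symbol: str
    gene_id: str
    tissue: str
    rsid: str
    odds_ratio: float
    slope: float
    q_value: float
    desired_action: DesiredAction
    drug_name: str
    interaction_type: str
    approved: bool
    priority_flags: frozenset = frozenset()

    def with_flags(self, *flags: str) -> "CandidatePair":
        return replace(self, priority_flags=self.priority_flags | frozenset(flags))


@dataclass(frozen=True)
class ParseReport:
    """Machine-readable accounting of a reader call.

    Invariant: ``n_read == n_kept + n_dropped``; ``n_deduplicated`` counts
    the subset of dropped rows removed as duplicates, and ``details`` breaks
    the drops down by reason.
    """

    n_read: int
    n_kept: int
    n_dropped: int
    n_deduplicated: int = 0
    details: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_read != self.n_kept + self.n_dropped:
            raise ValueError(
                f"inconsistent report: {self.n_read} read != "
                f"{self.n_kept} kept + {self.n_dropped} dropped"
            )

    def as_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "n_deduplicated": self.n_deduplicated,
            "details": dict(self.details),
        }
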