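"""SNP selection, matched random controls, eQTL intersection, and enrichment.

The statistical core of the tool: take GWAS summary records, keep the SNPs
below a (deliberately permissive) p-value cutoff, draw a same-size random
control set, intersect both with Q-filtered tissue eQTL associations under
allele harmonization, remove control-overlapping signals, and quantify the
excess of eQTLs among associated SNPs with a 2x2 Pearson chi-square test.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError
from .models import EnrichmentResult, EqtlAssociation, GwasRecord, MatchedTarget, SnpSet

log = logging.getLogger(__name__)


def select_significant_snps(records: Sequence[GwasRecord], p_threshold: float) -> SnpSet:
    """Keep SNPs with ``p_value <= p_threshold`` (inclusive comparison)."""
    if not 0 < p_threshold < 1:
        raise ConfigurationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    rsids = tuple(r.rsid for r in records if r.p_value <= p_threshold)
    if not rsids:
        log.warning("no SNPs pass p <= %g; downstream stages will be empty", p_threshold)
    else:
        log.info("selected %d/%d SNPs at p <= %g", len(rsids), len(records), p_threshold)
    return SnpSet(label="significant", rsids=rsids, threshold_or_seed=p_threshold)


def sample_control_snps(
    records: Sequence[GwasRecord],
    exclude: SnpSet,
    size: int,
    seed: int,
    from_full: bool = False,
) -> SnpSet:
    """Uniform sample of ``size`` rsids without replacement.

    By default the pool is the complement of ``exclude`` (the significant
    set); ``from_full=True`` samples from every record instead.  The draw is
    reproducible given ``seed`` and returned in record order.
    """
    if from_full:
        pool = [r.rsid for r in records]
    else:
        excluded = exclude.rsid_set
        pool = [r.rsid for r in records if r.rsid not in excluded]
    if size > len(pool):
        raise DataError(
            f"cannot sample {size} control SNPs from a pool of {len(pool)} "
            f"({len(records)} records, {len(exclude)} excluded)"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    chosen = tuple(pool[i] for i in sorted(idx))
    return SnpSet(label="control", rsids=chosen, threshold_or_seed=seed)


def chromosome_distribution(
    snp_set: SnpSet, records: Sequence[GwasRecord]
) -> Dict[str, Dict[str, float]]:
    """Observed per-chromosome counts in ``snp_set`` vs the expectation under
    uniform sampling from ``records``.

    ``expected_c = |set| * n_records_on_c / n_records``.  Every rsid in the
    set must exist among the records.
    """
    by_rsid = {r.rsid: r.chrom for r in records}
    observed: Counter = Counter()
    for rsid in snp_set.rsids:
        if rsid not in by_rsid:
            raise DataError(f"rsid {rsid} in set {snp_set.label!r} not found in records")
        observed[by_rsid[rsid]] += 1
    totals = Counter(r.chrom for r in records)
    n = len(records)
    size = len(snp_set)
    out = {}
    for chrom in sorted(totals, key=lambda c: (len(c), c)):
        out[chrom] = {
            "observed": observed.get(chrom, 0),
            "expected": size * totals[chrom] / n,
        }
    return out


def volcano_table(
    snp_set: SnpSet, records: Sequence[GwasRecord], p_floor: float = 1e-300
) -> List[Tuple[str, float, float]]:
    """Rows of (rsid, beta, -log10 p) for plotting, with p floored for finiteness."""
    by_rsid = {r.rsid: r for r in records}
    rows = []
    for rsid in snp_set.rsids:
        r = by_rsid[rsid]
        rows.append((rsid, r.beta, -math.log10(max(r.p_value, p_floor))))
    return rows


def filter_top_q(
    eqtls: Sequence[EqtlAssociation],
    fraction: float = 0.05,
    per_tissue: bool = False,
) -> List[EqtlAssociation]:
    """Keep the ``ceil(fraction * n)`` associations with the smallest q-values.

    The cut is taken over the pooled table by default, or within each tissue
    with ``per_tissue=True``.  Ties at the boundary break by input order and
    the kept rows preserve their original order.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    if not eqtls:
        log.warning("filter_top_q: empty input")
        return []
    if per_tissue:
        kept_idx: set = set()
        by_tissue: Dict[str, List[int]] = {}
        for i, e in enumerate(eqtls):
            by_tissue.setdefault(e.tissue, []).append(i)
        for idxs in by_tissue.values():
            k = math.ceil(fraction * len(idxs))
            ranked = sorted(idxs, key=lambda i: (eqtls[i].q_value, i))[:k]
            kept_idx.update(ranked)
        return [eqtls[i] for i in sorted(kept_idx)]
    k = math.ceil(fraction * len(eqtls))
    ranked = sorted(range(len(eqtls)), key=lambda i: (eqtls[i].q_value, i))[:k]
    return [eqtls[i] for i in sorted(ranked)]


def intersect_eqtls(
    snp_set: SnpSet,
    gwas_records: Sequence[GwasRecord],
    eqtls: Sequence[EqtlAssociation],
) -> Tuple[List[MatchedTarget], Dict[str, int]]:
    """Match SNPs in ``snp_set`` to eQTL associations by coordinates and alleles.

    A SNP matches an association when chromosome and position agree and the
    GWAS allele pair equals the eQTL {ref, alt} pair as unordered sets.  If
    the GWAS effect allele is the eQTL alt, the slope is used as-is
    (``direct``); if it is the ref, the slope sign is negated (``flipped``)
    so that both beta and slope are expressed per effect-allele copy.
    Allele-set mismatches are counted, not errors.  One target is emitted
    per (SNP, gene, tissue).
    """
    by_rsid = {r.rsid: r for r in gwas_records}
    by_pos: Dict[Tuple[str, int], List[EqtlAssociation]] = {}
    for e in eqtls:
        by_pos.setdefault((e.chrom, e.pos), []).append(e)

    matches: List[MatchedTarget] = []
    seen: set = set()
    n_mismatch = 0
    n_positional = 0
    for rsid in snp_set.rsids:
        rec = by_rsid.get(rsid)
        if rec is None:
            raise DataError(f"rsid {rsid} in set {snp_set.label!r} not found in GWAS records")
        candidates = by_pos.get((rec.chrom, rec.pos))
        if not candidates:
            continue
        n_positional += 1
        gwas_alleles = {rec.other_allele, rec.effect_allele}
        for e in candidates:
            if gwas_alleles != {e.ref, e.alt}:
                n_mismatch += 1
                continue
            if rec.effect_allele == e.alt:
                harmonization, slope = "direct", e.slope
            else:
                harmonization, slope = "flipped", -e.slope
            key = (rsid, e.gene_id, e.tissue)
            if key in seen:
                continue
            seen.add(key)
            matches.append(
                MatchedTarget(
                    rsid=rsid,
                    gene_id=e.gene_id,
                    gene_symbol=e.gene_symbol,
                    tissue=e.tissue,
                    beta=rec.beta,
                    odds_ratio=math.exp(rec.beta),
                    slope=slope,
                    q_value=e.q_value,
                    harmonization=harmonization,
                )
            )
    report = {
        "n_set": len(snp_set),
        "n_snps_with_position_hit": n_positional,
        "n_match_rows": len(matches),
        "n_matched_snps": len({m.rsid for m in matches}),
        "n_allele_mismatch": n_mismatch,
    }
    return matches, report


def subtract_control_overlap(
    sig_matches: Sequence[MatchedTarget],
    ctrl_matches: Sequence[MatchedTarget],
) -> Tuple[List[MatchedTarget], Dict[str, int]]:
    """Remove significant-set rows whose rsid also matched in the control set.

    Keying is by rsid (a shared SNP removes every one of its gene/tissue
    rows).  Reports the removal count and the distinct gene count of the
    remainder.
    """
    ctrl_rsids = {m.rsid for m in ctrl_matches}
    kept = [m for m in sig_matches if m.rsid not in ctrl_rsids]
    report = {
        "n_input": len(sig_matches),
        "n_removed": len(sig_matches) - len(kept),
        "n_kept": len(kept),
        "n_distinct_genes": len({m.gene_id for m in kept}),
    }
    return kept, report


def eqtl_enrichment_test(
    n_sig_eqtl: int,
    n_sig_total: int,
    n_ctrl_eqtl: int,
    n_ctrl_total: int,
    yates: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square (df=1) on the 2x2 eQTL-by-set contingency table.

    Rows are (significant, control) SNP sets; columns are (eQTL, non-eQTL).
    No continuity correction by default.  Raises if any expected cell is
    zero, recommending an exact test instead.
    """
    if n_sig_total <= 0 or n_ctrl_total <= 0:
        raise DataError("set totals must be positive")
    if not (0 <= n_sig_eqtl <= n_sig_total and 0 <= n_ctrl_eqtl <= n_ctrl_total):
        raise DataError("eQTL counts must lie within their set totals")
    table = np.array(
        [
            [n_sig_eqtl, n_sig_total - n_sig_eqtl],
            [n_ctrl_eqtl, n_ctrl_total - n_ctrl_eqtl],
        ],
        dtype=float,
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        raise DataError(
            "a 2x2 expected cell is zero; the chi-square approximation is invalid "
            "(use Fisher's exact test)"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=yates)
    return EnrichmentResult(
        n_sig_eqtl=n_sig_eqtl,
        n_sig_total=n_sig_total,
        n_ctrl_eqtl=n_ctrl_eqtl,
        n_ctrl_total=n_ctrl_total,
        proportion_sig=n_sig_eqtl / n_sig_total,
        proportion_ctrl=n_ctrl_eqtl / n_ctrl_total,
        chi2_statistic=float(chi2),
        df=int(dof),
        p_value=float(p),
    )
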