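"""Coupled GWAS / eQTL / drug-database simulator with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
a mostly-null GWAS over a toy genome (22 chromosomes x 10 Mb), a small set
of planted disease genes whose SNPs carry strong effects and true eQTLs
with a sign chosen to make a known drug action desirable, a large
background eQTL catalog (most catalog variants never appear in any GWAS
hit list), and an interaction database containing each planted gene's true
drug plus decoys.  Because every planted association is constructed to
survive each pipeline stage, the full funnel can be tested end-to-end with
a fully known answer and zero downloads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .drugs import DEFAULT_VOCABULARY
from .errors import ConfigurationError
from .io import format_variant_id
from .models import DesiredAction, DrugInteraction, EqtlAssociation, GwasRecord

_BASES = np.array(list("ACGT"))
_CNS_TISSUE = "Brain_Cortex"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``effect_beta_mean``/``sd`` set the planted log-odds effect magnitude
    (default 0.3 +- 0.05, i.e. OR ~ 1.35 — strong for a common-variant study
    but appropriate for a planted-truth fixture); ``effect_se`` is the
    standard error used to convert planted betas to p-values (0.02 puts
    planted p below ~1e-13).  ``concordant_fraction`` is the fraction of
    planted genes whose slope sign makes an inhibitor desirable.
    ``eqtl_background_rate`` is the probability a null GWAS SNP is also a
    catalog eQTL; ``n_background_eqtl_variants`` adds catalog-only rows at
    positions absent from the GWAS, mirroring how real eQTL catalogs dwarf
    any GWAS hit list (and giving the top-Q cut a realistic denominator).
    """

    n_snps: int = 10_000
    n_genes: int = 500
    n_tissues: int = 3
    n_planted: int = 20
    effect_beta_mean: float = 0.3
    effect_beta_sd: float = 0.05
    effect_se: float = 0.02
    slope_mean: float = 0.5
    slope_sd: float = 0.1
    concordant_fraction: float = 0.5
    eqtl_background_rate: float = 0.01
    n_background_eqtl_variants: int = 10_000
    seed: int = 0
    n_chromosomes: int = 22
    chrom_length: int = 10_000_000
    build: str = "b38"

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_genes", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_planted < 0:
            raise ConfigurationError("n_planted must be >= 0")
        if self.n_planted > self.n_snps:
            raise ConfigurationError(
                f"n_planted ({self.n_planted}) exceeds n_snps ({self.n_snps})"
            )
        if self.n_planted > self.n_genes:
            raise ConfigurationError(
                f"n_planted ({self.n_planted}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("concordant_fraction", "eqtl_background_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the simulator planted, for verifying pipeline recovery."""

    planted_snps: Set[str] = field(default_factory=set)
    planted_genes: Dict[str, DesiredAction] = field(default_factory=dict)
    true_drugs: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    snp_to_gene: Dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "planted_snps": sorted(self.planted_snps),
            "planted_genes": {g: a.value for g, a in sorted(self.planted_genes.items())},
            "true_drugs": {g: list(v) for g, v in sorted(self.true_drugs.items())},
            "snp_to_gene": dict(sorted(self.snp_to_gene.items())),
        }


def _gene_symbol(i: int) -> str:
    return f"SGENE{i:04d}"


def _gene_id(i: int) -> str:
    return f"SIMG{i:06d}.1"


def tissue_labels(config: SimulationConfig) -> List[str]:
    """Tissue label set; the first tissue is always CNS so planted eQTLs
    survive CNS prioritization."""
    labels = [_CNS_TISSUE]
    labels += [f"Tissue_{i:02d}" for i in range(2, config.n_tissues + 1)]
    return labels


def simulate_gwas(config: SimulationConfig) -> Tuple[List[GwasRecord], GroundTruth]:
    """Simulate GWAS summary statistics with planted associated SNPs.

    Null SNPs draw p ~ Uniform(0,1) and beta ~ Normal(0, 0.01); planted SNPs
    draw |beta| ~ Normal(effect_beta_mean, sd) with a random risk/protective
    sign and p as the two-sided normal tail of beta / effect_se.  Positions
    are uniform over the toy genome with biallelic ACGT alleles.
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_snps
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n)
    positions = rng.integers(1, config.chrom_length + 1, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_shift) % 4
    betas = rng.normal(0.0, 0.01, size=n)
    pvals = rng.uniform(0.0, 1.0, size=n)
    pvals = np.clip(pvals, 1e-12, 1.0)  # p must be in (0, 1]

    planted_idx = rng.choice(n, size=config.n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_planted)
    magnitudes = np.abs(rng.normal(config.effect_beta_mean, config.effect_beta_sd, size=config.n_planted))
    betas[planted_idx] = signs * magnitudes
    z = magnitudes / config.effect_se
    pvals[planted_idx] = np.maximum(2.0 * stats.norm.sf(z), 1e-300)

    # expected action per planted gene: exactly concordant_fraction inhibitors
    n_inhib = int(round(config.concordant_fraction * config.n_planted))
    action_flags = np.zeros(config.n_planted, dtype=bool)
    action_flags[:n_inhib] = True
    rng.shuffle(action_flags)

    truth = GroundTruth()
    records = []
    for i in range(n):
        records.append(
            GwasRecord(
                rsid=f"rs{i + 1:07d}",
                chrom=str(chroms[i]),
                pos=int(positions[i]),
                other_allele=str(_BASES[ref_idx[i]]),
                effect_allele=str(_BASES[alt_idx[i]]),
                beta=float(betas[i]),
                p_value=float(pvals[i]),
            )
        )
    for j, idx in enumerate(planted_idx):
        rsid = records[idx].rsid
        gene = _gene_symbol(j)
        truth.planted_snps.add(rsid)
        truth.snp_to_gene[rsid] = gene
        truth.planted_genes[gene] = (
            DesiredAction.INHIBITOR if action_flags[j] else DesiredAction.ACTIVATOR
        )
    return records, truth


def simulate_eqtls(
    config: SimulationConfig,
    gwas_records: Sequence[GwasRecord],
    truth: GroundTruth,
) -> List[EqtlAssociation]:
    """Simulate the significant variant-gene association catalog.

    Planted SNPs each get one eQTL for their planted gene in a CNS tissue,
    with the slope sign chosen so the directionality rule yields the
    expected action, and a q-value placed inside the global top-Q cut.
    Null GWAS SNPs become background eQTLs for random genes with probability
    ``eqtl_background_rate``; catalog-only variants fill out the table.
    Variant coordinates and alleles are copied from the GWAS records so
    intersection succeeds by construction.
    """
    rng = np.random.default_rng([config.seed, 23])
    tissues = tissue_labels(config)
    by_rsid = {r.rsid: r for r in gwas_records}
    planted_rsids = sorted(truth.planted_snps)

    rows: List[dict] = []
    # background eQTLs among null GWAS SNPs
    null_records = [r for r in gwas_records if r.rsid not in truth.planted_snps]
    hits = rng.random(len(null_records)) < config.eqtl_background_rate
    for r, hit in zip(null_records, hits):
        if not hit:
            continue
        gene = int(rng.integers(0, config.n_genes))
        rows.append(
            dict(
                variant_id=format_variant_id(r.chrom, r.pos, r.other_allele, r.effect_allele, config.build),
                chrom=r.chrom, pos=r.pos, ref=r.other_allele, alt=r.effect_allele,
                gene_id=_gene_id(gene), gene_symbol=_gene_symbol(gene),
                tissue=tissues[int(rng.integers(0, len(tissues)))],
                slope=float(rng.normal(0.0, config.slope_mean)),
                q_value=float(rng.uniform(0.0, 1.0)),
            )
        )
    # catalog-only variants: vectorized draws over fresh toy-genome coordinates
    n_cat = config.n_background_eqtl_variants
    cat_chrom = rng.integers(1, config.n_chromosomes + 1, size=n_cat)
    cat_pos = rng.integers(1, config.chrom_length + 1, size=n_cat)
    cat_ref = rng.integers(0, 4, size=n_cat)
    cat_alt = (cat_ref + rng.integers(1, 4, size=n_cat)) % 4
    cat_gene = rng.integers(0, config.n_genes, size=n_cat)
    cat_tissue = rng.integers(0, len(tissues), size=n_cat)
    cat_slope = rng.normal(0.0, config.slope_mean, size=n_cat)
    cat_q = rng.uniform(0.0, 1.0, size=n_cat)
    for i in range(n_cat):
        chrom, ref, alt = str(cat_chrom[i]), str(_BASES[cat_ref[i]]), str(_BASES[cat_alt[i]])
        gene = int(cat_gene[i])
        rows.append(
            dict(
                variant_id=format_variant_id(chrom, int(cat_pos[i]), ref, alt, config.build),
                chrom=chrom, pos=int(cat_pos[i]), ref=ref, alt=alt,
                gene_id=_gene_id(gene), gene_symbol=_gene_symbol(gene),
                tissue=tissues[int(cat_tissue[i])],
                slope=float(cat_slope[i]),
                q_value=float(cat_q[i]),
            )
        )

    # q-value cap that lands every planted row inside the global top-5% cut
    n_total = len(rows) + len(planted_rsids)
    k = math.ceil(0.05 * n_total)
    background_q = np.sort(np.array([r["q_value"] for r in rows]))
    if len(planted_rsids) and k > len(planted_rsids) and len(background_q):
        q_cap = float(background_q[k - len(planted_rsids)]) * 0.5
    else:
        q_cap = 1e-8

    planted_rows: List[dict] = []
    for rsid in planted_rsids:
        r = by_rsid[rsid]
        gene_symbol = truth.snp_to_gene[rsid]
        gene_index = int(gene_symbol.replace("SGENE", ""))
        action = truth.planted_genes[gene_symbol]
        magnitude = abs(float(rng.normal(config.slope_mean, config.slope_sd))) or config.slope_mean
        # inhibitor desired <=> sign(beta) * sign(slope) > 0
        sign = math.copysign(1.0, r.beta) if action == DesiredAction.INHIBITOR else -math.copysign(1.0, r.beta)
        planted_rows.append(
            dict(
                variant_id=format_variant_id(r.chrom, r.pos, r.other_allele, r.effect_allele, config.build),
                chrom=r.chrom, pos=r.pos, ref=r.other_allele, alt=r.effect_allele,
                gene_id=_gene_id(gene_index), gene_symbol=gene_symbol,
                tissue=_CNS_TISSUE,
                slope=sign * magnitude,
                q_value=float(rng.uniform(0.0, q_cap)),
            )
        )

    return [
        EqtlAssociation(
            variant_id=d["variant_id"], chrom=d["chrom"], pos=d["pos"], ref=d["ref"],
            alt=d["alt"], build=config.build, gene_id=d["gene_id"], tissue=d["tissue"],
            slope=d["slope"], q_value=d["q_value"], gene_symbol=d["gene_symbol"],
        )
        for d in planted_rows + rows
    ]


def simulate_drug_db(
    config: SimulationConfig,
    truth: GroundTruth,
    wrong_direction_decoys: bool = True,
    unapproved_decoys: bool = True,
    n_decoy_genes: int = 30,
) -> List[DrugInteraction]:
    """Simulate the interaction database: true drugs plus decoys.

    Each planted gene gets exactly one approved interaction whose type
    matches its expected action.  Decoys: an approved wrong-direction drug
    for each planted gene, an unapproved experimental drug per planted gene,
    and approved drugs for random unplanted genes.  With all decoys off the
    table holds exactly one interaction per planted gene.
    """
    rng = np.random.default_rng([config.seed, 37])
    interactions: List[DrugInteraction] = []
    all_types = sorted(DEFAULT_VOCABULARY[DesiredAction.INHIBITOR] | DEFAULT_VOCABULARY[DesiredAction.ACTIVATOR])
    for i, (gene, action) in enumerate(sorted(truth.planted_genes.items())):
        true_type = "inhibitor" if action == DesiredAction.INHIBITOR else "activator"
        drug = f"DRUG-{gene}"
        interactions.append(DrugInteraction(gene, drug, true_type, True, pubchem_id=str(90000 + i)))
        truth.true_drugs[gene] = (drug, true_type)
        if wrong_direction_decoys:
            wrong_type = "agonist" if action == DesiredAction.INHIBITOR else "antagonist"
            interactions.append(DrugInteraction(gene, f"ANTI-{gene}", wrong_type, True))
        if unapproved_decoys:
            interactions.append(DrugInteraction(gene, f"EXP-{gene}", true_type, False))
    if n_decoy_genes:
        planted_indices = {int(g.replace("SGENE", "")) for g in truth.planted_genes}
        unplanted = [i for i in range(config.n_genes) if i not in planted_indices]
        chosen = rng.choice(len(unplanted), size=min(n_decoy_genes, len(unplanted)), replace=False)
        for j in sorted(chosen):
            gene = _gene_symbol(unplanted[j])
            dtype = all_types[int(rng.integers(0, len(all_types)))]
            interactions.append(DrugInteraction(gene, f"MISC-{gene}", dtype, True))
    return interactions


def simulate_all(config: SimulationConfig, **drug_kwargs):
    """Run all three simulators; returns (gwas, eqtls, interactions, truth)."""
    records, truth = simulate_gwas(config)
    eqtls = simulate_eqtls(config, records, truth)
    interactions = simulate_drug_db(config, truth, **drug_kwargs)
    return records, eqtls, interactions, truth


def write_simulation(config: SimulationConfig, outdir, **drug_kwargs) -> Dict[str, object]:
    """Write simulated inputs in their real on-disk dialects plus truth.json.

    Produces ``gwas.tsv`` (odds-ratio scale), one GTEx-dialect
    ``{tissue}.signif_variant_gene_pairs.txt`` per tissue, DGIdb-dialect
    ``interactions.tsv``, and ``truth.json``.  Reading these back through
    the normal readers is itself a format-compatibility test.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, eqtls, interactions, truth = simulate_all(config, **drug_kwargs)

    gwas_path = outdir / "gwas.tsv"
    with open(gwas_path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\todds_ratio\tp_value\n")
        for r in records:
            fh.write(
                f"{r.rsid}\t{r.chrom}\t{r.pos}\t{r.other_allele}\t{r.effect_allele}\t"
                f"{repr(math.exp(r.beta))}\t{repr(r.p_value)}\n"
            )

    eqtl_paths = []
    for tissue in tissue_labels(config):
        path = outdir / f"{tissue}.signif_variant_gene_pairs.txt"
        with open(path, "w") as fh:
            fh.write("variant_id\tgene_id\tgene_name\tslope\tqval\n")
            for e in eqtls:
                if e.tissue == tissue:
                    fh.write(
                        f"{e.variant_id}\t{e.gene_id}\t{e.gene_symbol}\t"
                        f"{repr(e.slope)}\t{repr(e.q_value)}\n"
                    )
        eqtl_paths.append(path)

    drug_path = outdir / "interactions.tsv"
    with open(drug_path, "w") as fh:
        fh.write("gene_name\tdrug_name\tinteraction_types\tapproved\tpubchem_cid\n")
        for i in interactions:
            fh.write(
                f"{i.gene_symbol}\t{i.drug_name}\t{i.interaction_type}\t"
                f"{'true' if i.approved else 'false'}\t{i.pubchem_id or ''}\n"
            )

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "gwas": gwas_path,
        "eqtls": eqtl_paths,
        "interactions": drug_path,
        "truth": truth_path,
    }
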