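import math

import pytest
from hypothesis import HealthCheck, settings

from eqtl2drug.models import (
    CandidatePair,
    DesiredAction,
    EqtlAssociation,
    GwasRecord,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


def make_gwas(rsid="rs1", chrom="1", pos=100, ref="A", alt="G", odds_ratio=1.2, p=1e-4):
    """GWAS record from odds-ratio scale (effect per alt-allele copy)."""
    return GwasRecord(
        rsid=rsid,
        chrom=chrom,
        pos=pos,
        other_allele=ref,
        effect_allele=alt,
        beta=math.log(odds_ratio),
        p_value=p,
    )


def make_eqtl(
    chrom="1", pos=100, ref="A", alt="G", gene_id="SIMG000001.1",
    gene_symbol="GENE1", tissue="Brain_Cortex", slope=0.5, q=1e-4, build="b38",
):
    return EqtlAssociation(
        variant_id=f"chr{chrom}_{pos}_{ref}_{alt}_{build}",
        chrom=chrom, pos=pos, ref=ref, alt=alt, build=build,
        gene_id=gene_id, tissue=tissue, slope=slope, q_value=q,
        gene_symbol=gene_symbol,
    )


def make_pair(
    gene="GENE1", drug="DRUG1", tissue="Brain_Cortex",
    action=DesiredAction.INHIBITOR, interaction_type="inhibitor", rsid="rs1",
):
    return CandidatePair(
        gene_symbol=gene, gene_id=f"ID_{gene}", tissue=tissue, rsid=rsid,
        odds_ratio=1.2, slope=0.5, q_value=1e-4, desired_action=action,
        drug_name=drug, interaction_type=interaction_type, approved=True,
    )


@pytest.fixture
def prkd3_target_inputs():
    """The protective-allele, negative-slope worked example: a SNP with
    OR 0.91 (effect allele G) matching a Putamen eQTL with slope -0.22."""
    gwas = make_gwas(
        rsid="rs2540974", chrom="2", pos=37_430_000, ref="A", alt="G",
        odds_ratio=0.91, p=1.12e-4,
    )
    eqtl = make_eqtl(
        chrom="2", pos=37_430_000, ref="A", alt="G",
        gene_id="ENSG00000115825.12", gene_symbol="PRKD3",
        tissue="Putamen", slope=-0.22, q=1.02e-4,
    )
    return gwas, eqtl
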