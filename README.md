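# eqtl2drug

Drug-repurposing candidate discovery from GWAS summary statistics and
tissue eQTLs.

## The problem

Genome-wide association studies identify thousands of variants linked to a
complex disease, but a SNP by itself says nothing about *which* gene it
perturbs or in *which direction*. `eqtl2drug` is for computational
geneticists and drug-repurposing teams who want to turn a summary-statistics
file into a short, direction-aware list of approved drugs worth testing:

1. **Select** associated SNPs at a permissive p-value cutoff
   (default p ≤ 5×10⁻³ — the point is to feed the expression filter, not to
   claim genome-wide significance), and draw a same-size **random control
   set** from the remaining SNPs.
2. **Intersect** both sets with significant tissue eQTL associations
   (GTEx-style `variant_id` files, top 5% of q-values) under allele
   harmonization: a SNP matches when chromosome, position, and the unordered
   allele pair agree; if the GWAS effect allele is the eQTL *reference*
   allele the expression slope is sign-flipped so both effects are per
   effect-allele copy.
3. **Subtract** signals that also matched in the control set, and quantify
   the eQTL excess among associated SNPs with a 2×2 Pearson χ² test.
4. **Classify** each surviving (SNP, gene, tissue) target by the
   directionality rule: with OR the disease odds ratio and β_e the
   expression slope,

   ```
   desired action = inhibitor   if sign(ln OR) · sign(β_e) > 0
                    activator   if sign(ln OR) · sign(β_e) < 0
                    indeterminate otherwise
   ```

   A risk allele that raises expression (or a protective allele that lowers
   it) makes *less* gene product desirable; the opposite quadrants call for
   an activator/agonist.
5. **Match** targets to a drug–gene interaction table (DGIdb-style
   `interactions.tsv`), keeping approved drugs whose interaction type is
   compatible with the desired action, and **prioritize** candidates whose
   eQTL tissue is central-nervous-system relevant, with hooks for manual
   inclusions, known-gene exclusions, and model-organism ortholog
   annotation (≥50% identity by default).

A coupled synthetic-data generator plants druggable genes with known
effects, so the entire funnel is testable end-to-end with zero downloads.

## Worked example

Simulate a small study (2,000 SNPs, 8 planted druggable genes) and run the
full pipeline on the written files:

```bash
eqtl2drug simulate --outdir sim --seed 7 --n-snps 2000 --n-genes 100 --n-planted 8
eqtl2drug run --gwas sim/gwas.tsv \
    --eqtls sim/Brain_Cortex.signif_variant_gene_pairs.txt \
    --eqtls sim/Tissue_02.signif_variant_gene_pairs.txt \
    --eqtls sim/Tissue_03.signif_variant_gene_pairs.txt \
    --interactions sim/interactions.tsv --outdir out --seed 7
```

which prints the funnel:

```
20 significant SNPs -> 8 eQTL SNPs (control 0) -> 8 rows / 8 genes
  -> 8 intervenable -> 8 direction-compatible -> 8 prioritized
```

Reading: 20 of 2,000 SNPs pass p ≤ 5×10⁻³ (the 8 planted ones plus ~12
null SNPs expected by chance); exactly the 8 planted SNPs survive the
top-5%-q eQTL intersection while the random control set catches none; all 8
genes have an approved drug of the right direction and a CNS eQTL tissue.
`out/candidates.tsv` holds one prioritized gene–drug row each, e.g.

```
gene       tissue        rsid       odds_ratio  slope    desired_action  drug            interaction_type
SGENE0000  Brain_Cortex  rs0001459  0.770       -0.355   inhibitor       DRUG-SGENE0000  inhibitor
SGENE0001  Brain_Cortex  rs0001185  0.683       +0.451   activator       DRUG-SGENE0001  activator
```

The first row is the protective-allele/lower-expression quadrant (OR < 1,
slope < 0 → inhibitor); the second is protective/higher-expression →
activator. `out/funnel.json`, `out/enrichment.json`,
`out/matched_targets.tsv`, and the volcano tables carry the intermediate
numbers, each stamped with the seed and thresholds used.

One-off queries use the same machinery:

```bash
$ eqtl2drug classify --odds-ratio 0.91 --slope -0.22
inhibitor
$ eqtl2drug enrich 439 41919 123 41919
{"chi2_statistic": 178.87881228121248, ..., "p_value": 8.515795434247548e-41}
```

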