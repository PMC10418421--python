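# Methods

## Model and assumptions

`eqtl2drug` treats drug repurposing as a sign problem. For a biallelic SNP
with disease odds ratio OR (per copy of the effect allele) and a
variant–gene expression slope β_e (per copy of the eQTL's alternative
allele), the package assumes that pharmacologically pushing the gene
product in the direction the *protective* allele pushes expression is
beneficial. After harmonizing both effects onto the same allele, the
desired action is

- **inhibitor** when sign(ln OR) · sign(β_e) > 0 (risk allele raises
  expression, or protective allele lowers it),
- **activator** when the product is negative,
- **indeterminate** when OR = 1 or β_e = 0 exactly (such targets are
  excluded from drug matching and counted).

This is deliberately a marginal, per-SNP model. It assumes (a) the eQTL and
the disease association are driven by the same allele rather than by two
variants in linkage disequilibrium — no colocalization posterior is
computed; (b) effects combine monotonically, so the sign of a single
tissue's slope is a usable proxy for the direction of a lifelong exposure;
and (c) drug interaction types ("inhibitor", "agonist", …) map cleanly onto
the two directions. All three assumptions fail sometimes in real data;
the tool is a prioritization funnel, not an inference engine.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 5×10⁻³ | GWAS inclusion cutoff (inclusive ≤). Deliberately permissive: the expression intersection, not the p-value, does the filtering. A stricter 10⁻³ is one flag away; the value used is logged and embedded in every output. |
| `q_fraction` | 0.05 | fraction of eQTL rows kept, smallest q-values first, over the pooled catalog (per-tissue cut available). The cut keeps ⌈fraction·n⌉ rows; boundary ties break by input order. |
| `control_from_full` | false | the random control set is drawn from the complement of the significant set; the flag switches to the full SNP list. Control size always equals the significant-set size. |
| `yates` | false | Pearson χ² without continuity correction; a flag enables Yates. The test refuses to run (and says so) when any expected cell is zero — use an exact test there. |
| `min_ortholog_identity` | 50.0 | percent-identity floor for alignment-derived orthologs; curated orthologs pass regardless. |
| `cns_tissues` | see below | tissue labels counted as CNS. |
| `seed` | 0 | single RNG seed; it drives control sampling and is written into every output header. |

Allele harmonization in the intersection: a GWAS SNP matches an eQTL row
when chromosome, 1-based position, and the *unordered* allele pair agree.
If the GWAS effect allele is the eQTL alt, the slope is used as-is
(`direct`); if it is the ref, the slope sign is negated (`flipped`), so
beta and slope are always per effect-allele copy. Allele-pair mismatches at
a shared position are counted and reported, not errors. No strand flipping
is attempted; palindromic (A/T, C/G) variants are matched like any other,
both sources being assumed forward-stranded. Matching is by coordinates
rather than rsid because eQTL catalogs key on `variant_id`.

Control-overlap subtraction keys on rsid alone: a SNP that matched an eQTL
in the control set removes every one of its (gene, tissue) rows from the
significant side. Enrichment is computed on distinct matched SNPs per set,
with the two set sizes as denominators, before subtraction.

Drug matching joins on the case-normalized gene symbol (interaction
databases carry no stable gene ids). The default interaction-type
vocabulary maps inhibitor-desired targets to {inhibitor, antagonist,
blocker, negative modulator, inverse agonist} and activator-desired targets
to {activator, agonist, positive modulator, inducer}; both are
user-overridable. "Intervenable" genes (any approved interaction) are a
superset of "candidates" (direction-compatible interaction). A gene whose
tissues disagree on direction is emitted once per (gene, tissue) and listed
in the report, never silently collapsed.

The default CNS tissue set is any label containing "brain"
(case-insensitive) plus the explicit labels Putamen, Cerebellum, Caudate,
Substantianigra, Amygdala, Cortex, Frontalcortex (BA9), Hippocampus,
Hypothalamus, and Spinalcord — eQTL file dialects differ in whether the
organ prefix survives in filenames, so both spellings are covered. Manual
inclusions (candidates that fail the automatic criteria but are kept for
cause, e.g. a tissue with too few donors for CNS significance) are appended
verbatim and flagged `manually_included`; the rule engine is never bent to
admit them. A manual inclusion of an excluded gene is rejected as
contradictory configuration.

## Synthetic data: what it emulates and what it does not

The generator plants `n_planted` druggable genes in a toy genome of 22
chromosomes × 10 Mb. Planted SNPs draw |β| ~ N(0.3, 0.05) with random
risk/protective sign and p-values from the two-sided normal tail at
standard error 0.02 (p ≲ 10⁻¹³), so they always clear any sensible
threshold; null SNPs draw p ~ U(0,1) and β ~ N(0, 0.01). Each planted SNP
gets one eQTL for its gene in a CNS tissue whose slope sign realizes the
intended desired action (`concordant_fraction` of planted genes are made
inhibitor-desirable, default 0.5). Null SNPs become background eQTLs with
probability `eqtl_background_rate` (default 0.01), and
`n_background_eqtl_variants` (default 10,000) catalog-only rows at
positions absent from the GWAS fill out the association table — real eQTL
catalogs dwarf any GWAS hit list, and without this bulk the top-5% q cut
would retain fewer rows than there are planted associations. Planted
q-values are drawn Uniform(0, q_cap) with q_cap set per simulation to half
the q-value at the cut boundary, guaranteeing the funnel is exercised; this
is a fixture-construction device, not a statistical claim about q-value
distributions. The drug table holds one approved true drug per planted gene
plus three decoy classes: approved wrong-direction drugs for planted genes,
unapproved drugs for planted genes, and approved drugs for random unplanted
genes (30 by default).

Deliberately absent: linkage disequilibrium (the pipeline treats SNPs
independently), realistic allele-frequency spectra, winner's curse, and
tissue-sharing of eQTLs. Passing tests on this generator therefore shows
the funnel's logic is correct — harmonization, direction, joins, counts —
not that the method is well-powered or well-calibrated on real LD-structured
data.

## Numerical and design choices

- Thresholds are inclusive (≤) for both p and q.
- Volcano p-values are floored at 10⁻³⁰⁰ before −log10.
- Duplicate rsids in GWAS input keep the smallest-p record (count logged);
  duplicate (gene, drug, type) interaction rows collapse with approval
  OR-ed.
- Nearest-gene assignment (used only for the structural-vs-functional
  comparison) measures distance to the 0-based half-open gene interval,
  zero inside, ties broken lexicographically by gene id; gene annotation is
  accepted as BED4+ natively or GTF converted on read.
- The enrichment χ² is delegated to `scipy.stats.chi2_contingency`; the
  test suite checks it against an independently coded Pearson sum with an
  erfc-based χ²₁ survival function.
- All randomness flows through `numpy.random.default_rng` seeded from the
  single config seed (the simulator derives per-component child seeds from
  it); reruns with identical inputs and seed are byte-identical.
- Test and acceptance problem sizes (10,000 SNPs, 500 genes, 20 planted,
  seed sweeps of 20–100) were chosen so a full sweep completes in tens of
  seconds on one CPU while keeping every binomial check at ≥3-standard-
  error resolution.

## Known limitations

- Per-SNP marginal reasoning: no LD clumping, no conditional analysis, no
  colocalization. A "candidate" here is a hypothesis generator.
- The published proportions for the enrichment worked example ("1.2% vs
  0.38%") are not consistent with the published counts (439 and 123 of
  41,919 are 1.05% and 0.29%); the package always reports proportions from
  its actual counts, and the worked example's p-value is reproduced to
  order of magnitude (the 10⁻⁴¹–10⁻⁴⁰ decade), not to the printed digit.
- Gene-symbol joins inherit the interaction database's symbol vintage;
  an id→symbol bridge is supported but not curated here.
- Interaction-type vocabularies drift between database releases; the
  default map covers the common types and anything unmapped (including the
  frequent empty type, normalized to "unknown") simply never matches.
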