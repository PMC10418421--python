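"""Directionality rule, drug matching, prioritization, gene assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eqtl2drug import drugs
from eqtl2drug.errors import ConfigurationError, DataError
from eqtl2drug.models import (
    DesiredAction,
    DrugInteraction,
    GeneAnnotation,
    MatchedTarget,
    OrthologRecord,
)

from conftest import make_pair


def make_target(gene="PRKD3", tissue="Putamen", odds_ratio=0.91, slope=-0.22,
                rsid="rs1", action=None):
    import math
    return MatchedTarget(
        rsid=rsid, gene_id=f"ID_{gene}", gene_symbol=gene, tissue=tissue,
        beta=math.log(odds_ratio), odds_ratio=odds_ratio, slope=slope,
        q_value=1e-4, harmonization="direct", desired_action=action,
    )


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "odds_ratio,slope,expected",
        [
            (1.2, 0.5, DesiredAction.INHIBITOR),     # risk allele raises expression
            (0.8, 0.5, DesiredAction.ACTIVATOR),     # protective allele raises expression
            (1.2, -0.5, DesiredAction.ACTIVATOR),    # risk allele lowers expression
            (0.8, -0.5, DesiredAction.INHIBITOR),    # protective allele lowers expression
            (1.0, 0.5, DesiredAction.INDETERMINATE),
            (1.2, 0.0, DesiredAction.INDETERMINATE),
        ],
    )
    def test_sign_quadrants_and_boundaries(self, odds_ratio, slope, expected):
        assert drugs.classify_direction(odds_ratio, slope) == expected

    @pytest.mark.parametrize(
        "gene,odds_ratio,slope",
        [("PRKD3", 0.91, -0.22), ("DMPK", 1.10, 0.22), ("NDUFS2", 1.11, 0.27)],
    )
    def test_concordant_table_rows_yield_inhibitor(self, gene, odds_ratio, slope):
        assert drugs.classify_direction(odds_ratio, slope) == DesiredAction.INHIBITOR

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_nonpositive_odds_ratio_rejected(self, bad):
        with pytest.raises(DataError):
            drugs.classify_direction(bad, 0.5)

    @given(
        odds_ratio=st.floats(min_value=0.01, max_value=100.0,
                             allow_nan=False, allow_infinity=False),
        slope=st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    def test_antisymmetry(self, odds_ratio, slope):
        """Negating the slope (or inverting the OR) swaps inhibitor and
        activator and fixes indeterminate."""
        swap = {
            DesiredAction.INHIBITOR: DesiredAction.ACTIVATOR,
            DesiredAction.ACTIVATOR: DesiredAction.INHIBITOR,
            DesiredAction.INDETERMINATE: DesiredAction.INDETERMINATE,
        }
        base = drugs.classify_direction(odds_ratio, slope)
        assert drugs.classify_direction(odds_ratio, -slope) == swap[base]
        assert drugs.classify_direction(1.0 / odds_ratio, slope) == swap[base]


class TestVocabularyMap:
    def test_inhibitor_defaults(self):
        types = drugs.map_action_to_interaction_types(DesiredAction.INHIBITOR)
        assert {"inhibitor", "antagonist"} <= types

    def test_activator_defaults(self):
        assert "activator" in drugs.map_action_to_interaction_types(DesiredAction.ACTIVATOR)

    def test_custom_vocabulary_wins(self):
        vocab = {DesiredAction.INHIBITOR: {"x"}}
        assert drugs.map_action_to_interaction_types(DesiredAction.INHIBITOR, vocab) == {"x"}

    def test_indeterminate_has_no_types(self):
        with pytest.raises(DataError):
            drugs.map_action_to_interaction_types(DesiredAction.INDETERMINATE)


class TestMatchDrugs:
    def test_concordant_pair_matches(self):
        targets = drugs.attach_desired_actions([make_target()])
        interactions = [DrugInteraction("PRKD3", "MIDOSTAURIN", "inhibitor", True)]
        result = drugs.match_drugs(targets, interactions)
        assert result.intervenable_genes == {"PRKD3"}
        (pair,) = result.candidates
        assert (pair.gene_symbol, pair.drug_name) == ("PRKD3", "MIDOSTAURIN")
        assert pair.desired_action == DesiredAction.INHIBITOR

    def test_direction_mismatch_is_intervenable_but_not_candidate(self):
        targets = drugs.attach_desired_actions(
            [make_target(odds_ratio=0.91, slope=0.4)]  # activator desired
        )
        interactions = [DrugInteraction("PRKD3", "MIDOSTAURIN", "inhibitor", True)]
        result = drugs.match_drugs(targets, interactions)
        assert result.intervenable_genes == {"PRKD3"}
        assert result.candidates == ()

    def test_unapproved_only_means_not_intervenable(self):
        targets = drugs.attach_desired_actions([make_target()])
        interactions = [DrugInteraction("PRKD3", "EXPDRUG", "inhibitor", False)]
        result = drugs.match_drugs(targets, interactions, approved_only=True)
        assert result.intervenable_genes == frozenset()
        assert result.candidates == ()

    def test_indeterminate_targets_excluded_and_counted(self):
        targets = drugs.attach_desired_actions([make_target(odds_ratio=1.0)])
        interactions = [DrugInteraction("PRKD3", "MIDOSTAURIN", "inhibitor", True)]
        result = drugs.match_drugs(targets, interactions)
        assert result.candidates == ()
        assert result.report["n_indeterminate"] == 1

    def test_candidates_subset_of_intervenable(self):
        rng = np.random.default_rng(1)
        targets = drugs.attach_desired_actions(
            [
                make_target(gene=f"G{i}", rsid=f"rs{i}",
                            odds_ratio=float(np.exp(rng.normal())),
                            slope=float(rng.normal()))
                for i in range(30)
            ]
        )
        interactions = [
            DrugInteraction(f"G{i}", f"D{i}", t, True)
            for i in range(0, 30, 2)
            for t in ("inhibitor", "agonist")
        ]
        result = drugs.match_drugs(targets, interactions)
        assert {c.gene_symbol for c in result.candidates} <= result.intervenable_genes

    def test_conflicting_directions_reported_per_tissue(self):
        targets = drugs.attach_desired_actions([
            make_target(tissue="Putamen", slope=-0.2),
            make_target(tissue="Cortex", slope=0.2, rsid="rs2"),
        ])
        interactions = [
            DrugInteraction("PRKD3", "MIDOSTAURIN", "inhibitor", True),
            DrugInteraction("PRKD3", "SOMEAGONIST", "agonist", True),
        ]
        result = drugs.match_drugs(targets, interactions)
        assert result.report["conflicting_direction_genes"] == ["PRKD3"]
        assert {(c.tissue, c.drug_name) for c in result.candidates} == {
            ("Putamen", "MIDOSTAURIN"), ("Cortex", "SOMEAGONIST"),
        }


class TestPrioritize:
    def test_non_cns_tissue_dropped_unless_included(self):
        cns = make_pair(gene="PRKD3", tissue="Putamen")
        thyroid = make_pair(gene="KCNH6", tissue="Thyroid", drug="NS1643",
                            action=DesiredAction.ACTIVATOR, interaction_type="activator")
        kept, _ = drugs.prioritize([cns, thyroid])
        assert [c.gene_symbol for c in kept] == ["PRKD3"]
        kept, _ = drugs.prioritize([cns], include_pairs=[thyroid])
        assert {c.gene_symbol for c in kept} == {"KCNH6", "PRKD3"}
        (manual,) = [c for c in kept if c.gene_symbol == "KCNH6"]
        assert "manually_included" in manual.priority_flags

    def test_excluded_gene_removed_and_reported(self):
        pairs = [make_pair(gene="MARK3", tissue="Cortex"), make_pair(gene="PRKD3", tissue="Putamen")]
        kept, report = drugs.prioritize(pairs, exclude_genes={"MARK3"})
        assert all(c.gene_symbol != "MARK3" for c in kept)
        assert report["excluded_genes_seen"] == ["MARK3"]

    def test_empty_cns_set_empties_output(self):
        pairs = [make_pair(tissue="Putamen")]
        kept, _ = drugs.prioritize(pairs, cns_tissues=frozenset())
        assert kept == []

    def test_contradictory_include_and_exclude_raises(self):
        pair = make_pair(gene="MARK3")
        with pytest.raises(ConfigurationError, match="MARK3"):
            drugs.prioritize([], exclude_genes={"MARK3"}, include_pairs=[pair])

    def test_never_invents_rows(self):
        pairs = [make_pair(gene=f"G{i}", tissue=t)
                 for i, t in enumerate(["Putamen", "Thyroid", "Brain_Cortex"])]
        extra = make_pair(gene="X1", tissue="Liver")
        kept, _ = drugs.prioritize(pairs, include_pairs=[extra])
        identity = lambda c: (c.gene_symbol, c.drug_name, c.rsid, c.tissue)
        assert {identity(c) for c in kept} <= {identity(c) for c in pairs + [extra]}

    def test_stable_sort_by_gene_then_drug(self):
        pairs = [make_pair(gene="B", drug="Z", tissue="Cortex"),
                 make_pair(gene="A", drug="Y", tissue="Cortex"),
                 make_pair(gene="A", drug="X", tissue="Cortex")]
        kept, _ = drugs.prioritize(pairs)
        assert [(c.gene_symbol, c.drug_name) for c in kept] == [("A", "X"), ("A", "Y"), ("B", "Z")]


class TestKnownGenesAndOrthologs:
    ADSP_STYLE = {"ACE", "APH1B", "PTK2B", "INPP5D", "PRKD3"}

    def test_overlap_counted(self):
        overlap, n = drugs.annotate_known_genes({"ACE", "PRKD3", "FOO"}, self.ADSP_STYLE)
        assert overlap == {"ACE", "PRKD3"} and n == 2

    def test_disjoint_sets(self):
        assert drugs.annotate_known_genes({"FOO"}, self.ADSP_STYLE) == (set(), 0)

    def test_identical_sets(self):
        overlap, n = drugs.annotate_known_genes(self.ADSP_STYLE, self.ADSP_STYLE)
        assert n == len(self.ADSP_STYLE)

    def test_alignment_identity_threshold(self):
        pairs = [make_pair(gene="PRKD3"), make_pair(gene="LOWID")]
        orthologs = [
            OrthologRecord("PRKD3", "dkf-2", 53.52, "alignment"),
            OrthologRecord("PRKD3", "dkf-1", 65.83, "alignment"),
            OrthologRecord("LOWID", "xyz-1", 49.9, "alignment"),
        ]
        out = drugs.annotate_orthologs(pairs, orthologs, min_identity=50)
        flags = {c.gene_symbol: "has_ortholog" in c.priority_flags for c in out}
        assert flags == {"PRKD3": True, "LOWID": False}

    def test_curated_record_ignores_identity(self):
        pairs = [make_pair(gene="DMPK")]
        out = drugs.annotate_orthologs(pairs, [OrthologRecord("DMPK", "mrck-1", 0.0, "curated")])
        assert "has_ortholog" in out[0].priority_flags


class _Snp:
    def __init__(self, rsid, chrom, pos):
        self.rsid, self.chrom, self.pos = rsid, chrom, pos


class TestNearestGene:
    def test_snp_inside_gene(self):
        genes = [GeneAnnotation("A", "A", "1", 100, 200), GeneAnnotation("B", "B", "1", 500, 600)]
        assigned, _ = drugs.nearest_gene_assignment([_Snp("rs1", "1", 150)], genes)
        assert assigned == {"rs1": "A"}

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [GeneAnnotation("ENSG002", "b", "1", 1200, 1300),
                 GeneAnnotation("ENSG001", "a", "1", 800, 900)]
        # SNP at 1-based 1000: 100 bp right of ENSG001's end, 100 bp left of ENSG002
        assigned, _ = drugs.nearest_gene_assignment([_Snp("rs1", "1", 1000)], genes)
        assert assigned == {"rs1": "ENSG001"}

    def test_unassigned_on_geneless_chromosome(self):
        genes = [GeneAnnotation("A", "A", "1", 100, 200)]
        assigned, unassigned = drugs.nearest_gene_assignment([_Snp("rs1", "22", 150)], genes)
        assert assigned == {} and unassigned == ["rs1"]

    def test_agrees_with_all_pairs_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = []
            for i in range(10):
                start = int(rng.integers(0, 100_000))
                genes.append(GeneAnnotation(f"ENSG{i:03d}", f"g{i}",
                                            str(rng.integers(1, 4)), start,
                                            start + int(rng.integers(100, 5000))))
            snps = [_Snp(f"rs{j}", str(rng.integers(1, 4)), int(rng.integers(1, 110_000)))
                    for j in range(50)]
            assigned, unassigned = drugs.nearest_gene_assignment(snps, genes)
            for snp in snps:
                best = None
                for g in genes:
                    if g.chrom != snp.chrom:
                        continue
                    pos0 = snp.pos - 1
                    d = max(g.start - pos0, 0) + max(pos0 - (g.end - 1), 0)
                    if best is None or (d, g.gene_id) < best:
                        best = (d, g.gene_id)
                if best is None:
                    assert snp.rsid in unassigned
                else:
                    assert assigned[snp.rsid] == best[1]


class TestCompareAssignments:
    def test_identical_mappings_agree(self):
        functional = {f"rs{i}": {f"G{i}"} for i in range(5)}
        structural = {f"rs{i}": f"G{i}" for i in range(5)}
        assert drugs.compare_assignments(functional, structural) == 0.0

    def test_fully_disjoint(self):
        functional = {f"rs{i}": {f"G{i}"} for i in range(5)}
        structural = {f"rs{i}": "OTHER" for i in range(5)}
        assert drugs.compare_assignments(functional, structural) == 1.0

    def test_planted_discordance_fraction(self):
        functional = {f"rs{i}": {f"G{i}"} for i in range(10)}
        structural = {f"rs{i}": (f"G{i}" if i >= 3 else "NEAREST") for i in range(10)}
        assert drugs.compare_assignments(functional, structural) == pytest.approx(0.30)

    def test_empty_shared_set_errors(self):
        with pytest.raises(DataError):
            drugs.compare_assignments({"rs1": {"G"}}, {"rs2": "G"})
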