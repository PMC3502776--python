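import numpy as np
import pytest

from marrowmatch.alleles import Locus, parse_allele
from marrowmatch.frequencies import ProbabilityCategory, categorize
from marrowmatch.rules import (
    ClassifierConfig,
    RuleId,
    classify_search,
    rare_allele_rule,
    rare_association_rule,
    risk_haplotype_rule,
    within_serotype_share,
)

from .conftest import HAP1, HAP2, make_genotype


@pytest.fixture(scope="module")
def config():
    from marrowmatch import datasets

    return ClassifierConfig(
        conserved_haplotype_whitelist=datasets.load_conserved_haplotypes()
    )


class TestRareAlleleRule:
    def test_low_share_fires(self, config):
        hit = rare_allele_rule(parse_allele("B*44:05"), 0.02, config)
        assert hit is not None and hit.rule_id is RuleId.rare_allele

    def test_five_to_ten_percent_share_does_not_fire(self, config):
        # alleles at 5-10% of their serotype are a haplotype-context
        # problem, not a rare-allele hit at the default threshold
        assert rare_allele_rule(parse_allele("DRB1*13:03"), 0.08, config) is None

    def test_common_share_does_not_fire(self, config):
        assert rare_allele_rule(parse_allele("A*02:01"), 0.5, config) is None

    def test_share_computed_from_table(self, demo_table, serotype_map, config):
        share = within_serotype_share(parse_allele("B*44:05"), demo_table, serotype_map)
        assert share is not None and share < 0.05
        common = within_serotype_share(parse_allele("B*07:02"), demo_table, serotype_map)
        assert common is not None and common > 0.5


class TestRareAssociationRule:
    def test_rare_bc_association_fires(self, config):
        pair = (parse_allele("B*18:01"), parse_allele("C*02:02"))
        hit = rare_association_rule("B_C", pair, 0.01, config)
        assert hit is not None and hit.rule_id is RuleId.rare_BC_association

    def test_rare_drb1_dqb1_association_fires(self, config):
        pair = (parse_allele("DRB1*15:01"), parse_allele("DQB1*06:03"))
        hit = rare_association_rule("DRB1_DQB1", pair, 0.02, config)
        assert hit is not None and hit.rule_id is RuleId.rare_DRB1DQB1_association

    def test_modal_partner_does_not_fire(self, config):
        pair = (parse_allele("DRB1*15:01"), parse_allele("DQB1*06:02"))
        assert rare_association_rule("DRB1_DQB1", pair, 0.9, config) is None


class TestRiskHaplotypeRule:
    @pytest.mark.parametrize(
        "b_allele, expected",
        [
            ("B*51:01", RuleId.C_mm_risk_haplotype),
            ("B*15:01", RuleId.C_mm_risk_haplotype),
            ("B*35:02", RuleId.B35_allele_mm_risk),
            ("B*35:08", RuleId.B35_allele_mm_risk),
        ],
    )
    def test_risk_b_alleles_fire(self, config, b_allele, expected):
        g = make_genotype(
            "p", (HAP1[0], b_allele, *HAP1[2:]), HAP2
        )
        hits = risk_haplotype_rule(g, config)
        assert expected in {h.rule_id for h in hits}

    def test_benign_b_alleles_fire_nothing(self, config):
        g = make_genotype("p", HAP1, HAP2)  # B*08:01 / B*07:02
        assert risk_haplotype_rule(g, config) == ()

    def test_untyped_b_locus_raises(self, config):
        from marrowmatch.genotypes import Genotype

        g = make_genotype("p", HAP1, HAP2)
        stripped = Genotype("p", {l: a for l, a in g.typings.items() if l is not Locus.B})
        with pytest.raises(ValueError):
            risk_haplotype_rule(stripped, config)


class TestClassifySearch:
    def test_few_bmdw_donors_forces_low(self, demo_table, serotype_map, config):
        p = make_genotype("p", HAP1, HAP2)
        res = classify_search(p, demo_table, bmdw_count=2, config=config,
                              serotype_map=serotype_map, n_donors=10_000)
        assert res.category is ProbabilityCategory.low
        assert res.hits[0].rule_id is RuleId.few_bmdw_donors

    def test_no_hits_returns_frequency_category(self, demo_table, serotype_map, config):
        # the two most frequent haplotypes: a clean high-probability phenotype
        p = make_genotype(
            "p",
            ("A*01:01", "B*08:01", "C*07:01", "DRB1*03:01", "DQB1*02:01"),
            ("A*03:01", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"),
        )
        res = classify_search(p, demo_table, bmdw_count=500, config=config,
                              serotype_map=serotype_map, n_donors=10_000)
        assert res.hits == ()
        assert res.category is res.pre_demotion is ProbabilityCategory.high
        assert res.category is categorize(res.probability.p_registry)

    def test_rare_allele_hit_suppressed_by_conserved_haplotype(
        self, demo_table, serotype_map, config
    ):
        # the conserved rare-allele haplotype: rare allele travels with
        # B*07:02-C*07:02-DRB1*15:01, so the warning is withdrawn
        p = make_genotype(
            "p",
            ("A*02:151", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"),
            ("A*03:01", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"),
        )
        res = classify_search(p, demo_table, bmdw_count=500, config=config,
                              serotype_map=serotype_map, n_donors=10_000)
        assert RuleId.rare_allele not in {h.rule_id for h in res.hits}

        bare = ClassifierConfig()  # no whitelist: the hit fires
        res2 = classify_search(p, demo_table, bmdw_count=500, config=bare,
                               serotype_map=serotype_map, n_donors=10_000)
        assert RuleId.rare_allele in {h.rule_id for h in res2.hits}

    def test_each_rule_family_demotes_one_step(self, demo_table, serotype_map, config):
        # C-mismatch-risk B allele on an otherwise high phenotype
        p = make_genotype(
            "p",
            ("A*01:01", "B*08:01", "C*07:01", "DRB1*03:01", "DQB1*02:01"),
            ("A*02:01", "B*15:01", "C*03:04", "DRB1*04:01", "DQB1*03:02"),
        )
        res = classify_search(p, demo_table, bmdw_count=500, config=config,
                              serotype_map=serotype_map, n_donors=10_000)
        assert res.pre_demotion is ProbabilityCategory.high
        assert RuleId.C_mm_risk_haplotype in {h.rule_id for h in res.hits}
        families = {h.rule_id for h in res.hits if h.severity}
        ladder = [ProbabilityCategory.high, ProbabilityCategory.intermediate,
                  ProbabilityCategory.low]
        expected = ladder[min(2, len(families))]
        assert res.category is expected

    def test_non_european_ancestry_counts_as_one_family(
        self, demo_table, serotype_map, config
    ):
        p = make_genotype(
            "p",
            ("A*01:01", "B*08:01", "C*07:01", "DRB1*03:01", "DQB1*02:01"),
            ("A*03:01", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"),
        )
        res = classify_search(p, demo_table, bmdw_count=500, ancestry_flag=True,
                              config=config, serotype_map=serotype_map,
                              n_donors=10_000)
        assert res.pre_demotion is ProbabilityCategory.high
        assert res.category is ProbabilityCategory.intermediate

    def test_category_never_above_frequency_category_when_hit_active(
        self, demo_table, serotype_map, config
    ):
        rng = np.random.default_rng(3)
        from marrowmatch.registry import sample_patient_genotypes

        ladder = [ProbabilityCategory.high, ProbabilityCategory.intermediate,
                  ProbabilityCategory.low]
        for p in sample_patient_genotypes([demo_table], [1.0], 30, rng):
            res = classify_search(p, demo_table, bmdw_count=500, config=config,
                                  serotype_map=serotype_map, n_donors=10_000)
            if any(h.severity for h in res.hits):
                assert ladder.index(res.category) >= ladder.index(res.pre_demotion)

    def test_rules_only_mode_reports_missing_estimate(self, serotype_map, config):
        p = make_genotype("p", HAP1, HAP2)
        res = classify_search(p, None, bmdw_count=500, config=config,
                              serotype_map=serotype_map)
        assert res.probability is None
        assert "unavailable" in res.note
        assert res.category is None  # no rule fired, no numeric estimate

    def test_warning_rule_enum_is_closed(self):
        assert {r.value for r in RuleId} == {
            "few_bmdw_donors",
            "non_european",
            "rare_allele",
            "rare_BC_association",
            "rare_DRB1DQB1_association",
            "C_mm_risk_haplotype",
            "B35_allele_mm_risk",
        }

    def test_config_yaml_round_trip(self, tmp_path, config):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "rare_allele_threshold": 0.04,
                    "bmdw_min_donors": 5,
                    "b35_risk_alleles": ["B*35:02"],
                    "conserved_haplotype_whitelist": [
                        list(h) for h in config.conserved_haplotype_whitelist
                    ],
                }
            )
        )
        loaded = ClassifierConfig.from_yaml(path)
        assert loaded.rare_allele_threshold == 0.04
        assert loaded.bmdw_min_donors == 5
        assert loaded.b35_risk_alleles == ("B*35:02",)
        assert loaded.conserved_haplotype_whitelist == config.conserved_haplotype_whitelist
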