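"""Funnel stages: significance filter, eQTL intersection, mechanism rule,
drug matching, ortholog filter, and the assembled cascade."""

import json

import numpy as np
import pytest

from gwasfunnel import (
    DrugGeneInteraction,
    EqtlRecord,
    FunnelConfig,
    GeneratorConfig,
    GwasSnp,
    MechanismCall,
    MechanismError,
    ValidationError,
    filter_orthologs,
    generate_bundle,
    intersect_cns_eqtls,
    match_drugs,
    OrthologPair,
    required_mechanism,
    run_funnel,
    select_significant,
)
from gwasfunnel.funnel import harmonized_direction


def snp(p, snp_id="rs1", odds_ratio=1.5, effect="A", other="G"):
    return GwasSnp(snp_id, "chr1", 100, effect, other, odds_ratio, p)


def test_select_significant_strict_inequality():
    snps = [snp(0.5, "a"), snp(0.009, "b"), snp(0.01, "c")]
    assert [s.snp_id for s in select_significant(snps, 0.01)] == ["b"]
    assert select_significant(snps, 1) == snps
    assert select_significant(snps + [snp(1.0, "d")], 1) == snps  # p=1 fails p<1
    assert select_significant(snps, 0) == []


def test_select_significant_preserves_order_and_alpha_one():
    snps = [snp(0.3, "a"), snp(0.7, "b"), snp(0.1, "c")]
    assert [s.snp_id for s in select_significant(snps, 1.0)] == ["a", "b", "c"]


def test_select_significant_binomial_count():
    """10,000 uniform(0,1] p-values at alpha=1e-3: retained count within
    3 sigma of the Binomial(10000, 1e-3) mean."""
    rng = np.random.default_rng(2024)
    snps = [snp(float(1 - rng.random()), f"rs{i}") for i in range(10_000)]
    kept = len(select_significant(snps, 1e-3))
    mean, sigma = 10.0, np.sqrt(10_000 * 1e-3 * 0.999)
    assert abs(kept - mean) <= 3 * sigma


def eqtl(snp_id, gene, tissue, direction=1, allele="A"):
    return EqtlRecord(snp_id, gene, tissue, direction, 1e-5, allele)


def test_intersect_requires_cns_tissue():
    selected = [snp(1e-4, "rs1")]
    assert len(intersect_cns_eqtls(selected, [eqtl("rs1", "G1", "Cerebellum")],
                                   FunnelConfig().tissues)) == 1
    assert intersect_cns_eqtls(selected, [eqtl("rs1", "G1", "Liver")],
                               FunnelConfig().tissues) == []
    with pytest.raises(ValidationError, match="empty"):
        intersect_cns_eqtls(selected, [], frozenset())


def test_intersect_planted_overlap_counts_genes(small_bundle):
    cfg = small_bundle.config
    selected = select_significant(small_bundle.gwas, cfg.alpha)
    pairs = intersect_cns_eqtls(selected, small_bundle.eqtls, frozenset(cfg.tissues))
    genes = {e.gene_id for _, e in pairs}
    assert small_bundle.truth.gene_ids <= genes


@pytest.mark.parametrize(
    "odds_ratio, direction, action, risk_or, risk_dir",
    [
        (1.5, +1, "inhibitor", 1.5, +1),  # risk allele raises mRNA
        (1.5, -1, "activator", 1.5, -1),  # risk allele lowers mRNA
        (0.8, +1, "activator", 1.25, -1),  # protective allele raises mRNA
        (0.8, -1, "inhibitor", 1.25, +1),
    ],
)
def test_required_mechanism_rule(odds_ratio, direction, action, risk_or, risk_dir):
    got_action, got_or, got_dir = required_mechanism(odds_ratio, direction)
    assert got_action == action
    assert got_or == pytest.approx(risk_or)
    assert got_dir == risk_dir
    assert got_or > 1


def test_required_mechanism_or_one_errors():
    with pytest.raises(MechanismError, match="exactly 1"):
        required_mechanism(1.0, 1)


def test_harmonization_modes():
    s = snp(1e-4, effect="A", other="G")
    assert harmonized_direction(s, eqtl("rs1", "G1", "Cortex", +1, "A")) == +1
    assert harmonized_direction(s, eqtl("rs1", "G1", "Cortex", +1, "G")) == -1
    unharmonized = EqtlRecord("rs1", "G1", "Cortex", +1, 1e-5, None)
    with pytest.raises(MechanismError, match="harmoniz"):
        harmonized_direction(s, unharmonized, "strict")
    assert harmonized_direction(s, unharmonized, "assume") == +1
    mismatched = eqtl("rs1", "G1", "Cortex", +1, "C")
    with pytest.raises(MechanismError, match="neither"):
        harmonized_direction(s, mismatched)


def call(gene="G1", action="inhibitor"):
    return MechanismCall(gene, action, "rs1", 1.5, +1 if action == "inhibitor" else -1)


def test_match_drugs_by_action_and_approval():
    dgi = [
        DrugGeneInteraction("G1", "drugA", "inhibitor", True),
        DrugGeneInteraction("G1", "drugB", "activator", True),
        DrugGeneInteraction("G1", "drugC", "inhibitor", False),
        DrugGeneInteraction("G2", "drugD", "inhibitor", True),
    ]
    matched = match_drugs(call("G1", "inhibitor"), dgi, approved_only=True)
    assert [d.drug_name for d in matched] == ["drugA"]
    assert match_drugs(call("G1", "activator"), dgi)[0].drug_name == "drugB"
    assert [d.drug_name for d in match_drugs(call("G1", "inhibitor"), dgi, False)] == [
        "drugA", "drugC",
    ]
    assert match_drugs(call("G3", "inhibitor"), dgi) == []


def test_match_drugs_random_tables_equal_bruteforce():
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(8)]
    actions = ["inhibitor", "activator", "other"]
    for _ in range(50):
        dgi = [
            DrugGeneInteraction(
                str(rng.choice(genes)), f"d{j}", str(rng.choice(actions)),
                bool(rng.random() < 0.5),
            )
            for j in range(rng.integers(1, 20))
        ]
        g = str(rng.choice(genes))
        a = str(rng.choice(actions[:2]))
        approved_only = bool(rng.random() < 0.5)
        c = call(g, a)
        expect = [
            d for d in dgi
            if d.gene_id == g and d.action == a and (d.approved or not approved_only)
        ]
        assert match_drugs(c, dgi, approved_only) == expect


def test_filter_orthologs_threshold_inclusive():
    pairs = [
        OrthologPair("G1", "ce-b", 35.0, "s"),
        OrthologPair("G1", "ce-a", 62.0, "s"),
    ]
    assert filter_orthologs("G1", pairs, 40.0).percent_identity == 62.0
    assert filter_orthologs("G1", [OrthologPair("G1", "ce-a", 40.0, "s")], 40.0) is not None
    assert filter_orthologs("G1", [OrthologPair("G1", "ce-a", 39.99, "s")], 40.0) is None
    tie = [OrthologPair("G1", "ce-z", 50.0, "s"), OrthologPair("G1", "ce-a", 50.0, "s")]
    assert filter_orthologs("G1", tie, 40.0).model_gene == "ce-a"


def test_filter_orthologs_random_equals_bruteforce():
    rng = np.random.default_rng(8)
    for _ in range(50):
        pairs = [
            OrthologPair(f"G{rng.integers(0, 4)}", f"ce-{j}", float(rng.uniform(0, 100)), "s")
            for j in range(rng.integers(1, 15))
        ]
        g = f"G{rng.integers(0, 4)}"
        thr = float(rng.uniform(0, 100))
        got = filter_orthologs(g, pairs, thr)
        eligible = [o for o in pairs if o.human_gene == g and o.percent_identity >= thr]
        if not eligible:
            assert got is None
        else:
            best = sorted(eligible, key=lambda o: (-o.percent_identity, o.model_gene))[0]
            assert got == best


def test_run_funnel_recovers_single_planted_candidate(small_bundle):
    cfg = small_bundle.config
    report = run_funnel(
        small_bundle.gwas, small_bundle.genes, small_bundle.eqtls,
        small_bundle.dgi, small_bundle.orthologs,
        config=FunnelConfig(alpha=cfg.alpha),
    )
    (planted,) = small_bundle.truth.candidates
    ranked = report.ranked()
    assert ranked[0].gene_id == planted.gene_id
    assert ranked[0].mechanism.required_action == planted.required_action
    assert report.stage_counts["ortholog_genes"] == len(ranked)
    assert report.check_monotone()


def test_run_funnel_alpha_zero_is_empty(small_bundle):
    report = run_funnel(
        small_bundle.gwas, small_bundle.genes, small_bundle.eqtls,
        small_bundle.dgi, small_bundle.orthologs, config=FunnelConfig(alpha=0.0),
    )
    assert report.stage_counts["significant_snps"] == 0
    assert report.stage_counts["ortholog_genes"] == 0
    assert report.candidates == []


def test_run_funnel_ranking_prefers_more_support():
    cfg = GeneratorConfig(
        n_snps=2_000, n_genes=40, n_chroms=2, n_planted=2, planted_support=(3, 1),
        bg_eqtl_rate=0.0, bg_drug_rate=0.0, bg_ortholog_rate=0.0,
    )
    bundle = generate_bundle(cfg, seed=21)
    report = run_funnel(
        bundle.gwas, bundle.genes, bundle.eqtls, bundle.dgi, bundle.orthologs,
        config=FunnelConfig(alpha=cfg.alpha),
    )
    ranked = report.ranked()
    assert len(ranked) == 2
    assert ranked[0].n_support > ranked[1].n_support
    by_gene = {c.gene_id: c for c in ranked}
    supports = {
        c.gene_id: len(c.supporting_snps) for c in bundle.truth.candidates
    }
    assert by_gene[ranked[0].gene_id].n_support == max(supports.values())


def test_discordant_gene_excluded_then_kept_by_majority():
    snps = [
        snp(1e-4, "rs1", odds_ratio=1.5),
        snp(1e-4, "rs2", odds_ratio=1.4),
        snp(1e-4, "rs3", odds_ratio=0.6),
    ]
    genes = []
    eqtls = [
        eqtl("rs1", "G1", "Cortex", +1),  # inhibitor
        eqtl("rs2", "G1", "Cortex", +1),  # inhibitor
        eqtl("rs3", "G1", "Cortex", +1),  # activator (risk flip)
    ]
    dgi = [DrugGeneInteraction("G1", "drugA", "inhibitor", True)]
    orth = [OrthologPair("G1", "ce-1", 80.0, "s")]
    excl = run_funnel(snps, genes, eqtls, dgi, orth, config=FunnelConfig(alpha=0.01))
    assert excl.stage_counts["mechanism_genes"] == 0
    assert excl.candidates[0].discordant
    maj = run_funnel(
        snps, genes, eqtls, dgi, orth,
        config=FunnelConfig(alpha=0.01, discordant_policy="majority"),
    )
    assert maj.stage_counts["ortholog_genes"] == 1
    assert maj.ranked()[0].mechanism.required_action == "inhibitor"


def test_bbb_filter_applies_when_annotation_present():
    snps = [snp(1e-4, "rs1", odds_ratio=1.5)]
    eqtls_ = [eqtl("rs1", "G1", "Cortex", +1)]
    dgi = [
        DrugGeneInteraction("G1", "drugA", "inhibitor", True),
        DrugGeneInteraction("G1", "drugB", "inhibitor", True),
    ]
    orth = [OrthologPair("G1", "ce-1", 80.0, "s")]
    report = run_funnel(
        snps, [], eqtls_, dgi, orth, config=FunnelConfig(alpha=0.01),
        bbb={"drugA": False, "drugB": True},
    )
    assert report.stage_counts["bbb_genes"] == 1
    (c,) = report.ranked()
    assert [d.drug_name for d in c.matched_drugs] == ["drugB"]
    blocked = run_funnel(
        snps, [], eqtls_, dgi, orth, config=FunnelConfig(alpha=0.01),
        bbb={"drugA": False, "drugB": False},
    )
    assert blocked.stage_counts["bbb_genes"] == 0


def test_allele_flip_invariance_single_report(small_bundle):
    """Replacing (effect, OR, direction-as-written) by the other-allele
    representation for every SNP leaves the funnel report identical."""
    flipped = [
        GwasSnp(s.snp_id, s.chrom, s.pos, s.other_allele, s.effect_allele,
                1.0 / s.odds_ratio, s.p_value)
        for s in small_bundle.gwas
    ]
    cfg = FunnelConfig(alpha=small_bundle.config.alpha)
    a = run_funnel(small_bundle.gwas, small_bundle.genes, small_bundle.eqtls,
                   small_bundle.dgi, small_bundle.orthologs, config=cfg)
    b = run_funnel(flipped, small_bundle.genes, small_bundle.eqtls,
                   small_bundle.dgi, small_bundle.orthologs, config=cfg)
    assert a.stage_counts == b.stage_counts
    ja, jb = json.loads(a.to_json()), json.loads(b.to_json())
    assert ja == jb
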