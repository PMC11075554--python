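"""The candidate-prioritization funnel.

Stages, in order: association-significance filter on the GWAS table;
annotation of the surviving SNPs; intersection with CNS-tissue eQTL
records; inference of the required pharmacological mechanism from the
risk-oriented odds ratio and eQTL direction; matching against approved
drug-gene interactions of that mechanism; ortholog filter for the model
organism; and an optional blood-brain-barrier permeability filter when
a per-drug annotation is supplied.  The report records the count
surviving each stage and the final ranked candidate table.

The mechanism rule: re-orient every association to its *risk* allele
(OR > 1; an OR < 1 record is flipped to the opposite allele via
OR -> 1/OR, eQTL direction -> -direction).  If the risk allele raises
target mRNA (direction +1) the gene calls for an *inhibitor*; if it
lowers mRNA, an *activator*.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotate import annotate_all
from .io_formats import (
    CNS_TISSUES,
    DrugGeneInteraction,
    EqtlRecord,
    GeneModel,
    GwasSnp,
    OrthologPair,
    ValidationError,
)

logger = logging.getLogger(__name__)

INHIBITOR = "inhibitor"
ACTIVATOR = "activator"


class MechanismError(ValidationError):
    """A mechanism call cannot be made (OR exactly 1, or unharmonized alleles)."""


@dataclass(frozen=True)
class MechanismCall:
    """The drug mechanism a gene requires, derived from one supporting SNP.

    ``risk_or`` and ``risk_direction`` are re-oriented to the risk
    allele, so ``risk_or > 1`` always and ``required_action`` is
    'inhibitor' iff ``risk_direction`` is +1.
    """

    gene_id: str
    required_action: str
    supporting_snp: str
    risk_or: float
    risk_direction: int


@dataclass
class CandidateRecord:
    """A gene's state as it traverses the funnel."""

    gene_id: str
    passed_eqtl: bool = False
    mechanism: Optional[MechanismCall] = None
    matched_drugs: list[DrugGeneInteraction] = field(default_factory=list)
    best_ortholog: Optional[OrthologPair] = None
    bbb_permeable: Optional[bool] = None
    promoter_distance_bp: Optional[int] = None
    rank: Optional[int] = None
    n_support: int = 0
    best_p: Optional[float] = None
    discordant: bool = False


@dataclass(frozen=True)
class FunnelConfig:
    """Tunable thresholds of the funnel.

    alpha
        GWAS significance threshold (SNPs with p < alpha survive).
    tissues
        Tissue names defining the CNS-eQTL intersection.
    min_identity
        Minimum ortholog percent identity (inclusive).
    approved_only
        Restrict drug matching to approved interactions.
    harmonization
        'strict' errors on eQTL records lacking an effect allele;
        'assume' treats them as already oriented to the GWAS effect allele.
    discordant_policy
        'exclude' drops genes whose supporting SNPs imply conflicting
        mechanisms; 'majority' keeps the majority call (ties dropped).
    """

    alpha: float = 1e-3
    tissues: frozenset[str] = CNS_TISSUES
    min_identity: float = 40.0
    approved_only: bool = True
    harmonization: str = "strict"
    discordant_policy: str = "exclude"

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.harmonization not in ("strict", "assume"):
            raise ValidationError(f"harmonization must be strict|assume, got {self.harmonization!r}")
        if self.discordant_policy not in ("exclude", "majority"):
            raise ValidationError(
                f"discordant_policy must be exclude|majority, got {self.discordant_policy!r}"
            )

    def echo(self) -> dict:
        return {
            "alpha": self.alpha,
            "tissues": sorted(self.tissues),
            "min_identity": self.min_identity,
            "approved_only": self.approved_only,
            "harmonization": self.harmonization,
            "discordant_policy": self.discordant_policy,
        }


@dataclass
class FunnelReport:
    """Stage-by-stage counts plus the final ranked candidate table."""

    stage_counts: dict[str, int]
    candidates: list[CandidateRecord]
    config_echo: dict

    #: stages whose counts are numbers of distinct genes (monotone suffix)
    GENE_STAGES = (
        "cns_eqtl_genes",
        "mechanism_genes",
        "drug_matched_genes",
        "ortholog_genes",
        "bbb_genes",
    )

    def ranked(self) -> list[CandidateRecord]:
        return [c for c in self.candidates if c.rank is not None]

    def candidates_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(
            self.candidates, key=lambda c: (c.rank is None, c.rank or 0, c.gene_id)
        ):
            rows.append(
                {
                    "rank": c.rank if c.rank is not None else "",
                    "gene_id": c.gene_id,
                    "required_action": c.mechanism.required_action if c.mechanism else "",
                    "risk_or": round(c.mechanism.risk_or, 6) if c.mechanism else "",
                    "risk_direction": f"{c.mechanism.risk_direction:+d}" if c.mechanism else "",
                    "n_support": c.n_support,
                    "best_p": repr(c.best_p) if c.best_p is not None else "",
                    "matched_drugs": ";".join(sorted(d.drug_name for d in c.matched_drugs)),
                    "model_ortholog": c.best_ortholog.model_gene if c.best_ortholog else "",
                    "percent_identity": c.best_ortholog.percent_identity if c.best_ortholog else "",
                    "bbb_permeable": "" if c.bbb_permeable is None else str(c.bbb_permeable).lower(),
                    "promoter_distance_bp": c.promoter_distance_bp
                    if c.promoter_distance_bp is not None
                    else "",
                    "discordant": str(c.discordant).lower(),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "rank", "gene_id", "required_action", "risk_or", "risk_direction",
                "n_support", "best_p", "matched_drugs", "model_ortholog",
                "percent_identity", "bbb_permeable", "promoter_distance_bp", "discordant",
            ],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "config": self.config_echo,
                "candidates": [
                    {
                        "rank": c.rank,
                        "gene_id": c.gene_id,
                        "required_action": c.mechanism.required_action if c.mechanism else None,
                        "n_support": c.n_support,
                        "best_p": c.best_p,
                        "matched_drugs": sorted(d.drug_name for d in c.matched_drugs),
                        "model_ortholog": c.best_ortholog.model_gene if c.best_ortholog else None,
                    }
                    for c in self.ranked()
                ],
            },
            indent=2,
            sort_keys=True,
        )

    def check_monotone(self) -> bool:
        """True when the significance filter shrinks the SNP set and the
        gene-counted stages are non-increasing in funnel order."""
        if self.stage_counts["significant_snps"] > self.stage_counts["total_snps"]:
            return False
        gene_counts = [
            self.stage_counts[s] for s in self.GENE_STAGES if s in self.stage_counts
        ]
        return all(a >= b for a, b in zip(gene_counts, gene_counts[1:]))


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------


def select_significant(snps: Sequence[GwasSnp], alpha: float) -> list[GwasSnp]:
    """SNPs with p-value strictly below ``alpha``, original order preserved."""
    if not (0 <= alpha <= 1):
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    return [s for s in snps if s.p_value < alpha]


def intersect_cns_eqtls(
    selected: Sequence[GwasSnp],
    eqtls: Sequence[EqtlRecord],
    tissues: frozenset[str] | set[str],
) -> list[tuple[GwasSnp, EqtlRecord]]:
    """All (SNP, eQTL) pairs where a selected SNP is an eQTL in one of
    ``tissues``.  A gene appears once per supporting pair."""
    if not tissues:
        raise ValidationError("tissue set is empty; the CNS filter would be vacuous")
    by_id = {s.snp_id: s for s in selected}
    return [
        (by_id[e.snp_id], e)
        for e in eqtls
        if e.tissue in tissues and e.snp_id in by_id
    ]


def harmonized_direction(snp: GwasSnp, eqtl: EqtlRecord, harmonization: str = "strict") -> int:
    """eQTL direction re-expressed per copy of the GWAS effect allele.

    When the eQTL record is oriented to the GWAS other allele the sign
    flips; a record with no allele errors in strict mode and is assumed
    pre-harmonized in 'assume' mode.
    """
    if eqtl.effect_allele is None:
        if harmonization == "assume":
            return eqtl.direction
        raise MechanismError(
            f"eQTL record {eqtl.snp_id}/{eqtl.gene_id} has no effect allele; "
            "harmonize alleles or run with harmonization='assume'"
        )
    if eqtl.effect_allele == snp.effect_allele:
        return eqtl.direction
    if eqtl.effect_allele == snp.other_allele:
        return -eqtl.direction
    raise MechanismError(
        f"eQTL record {eqtl.snp_id}/{eqtl.gene_id} effect allele "
        f"{eqtl.effect_allele} matches neither GWAS allele "
        f"({snp.effect_allele}/{snp.other_allele})"
    )


def required_mechanism(odds_ratio: float, direction: int) -> tuple[str, float, int]:
    """Mechanism required to antagonize a harmonized (OR, eQTL direction) pair.

    Returns ``(required_action, risk_or, risk_direction)`` after
    re-orienting to the risk allele: an OR below 1 is flipped
    (OR -> 1/OR, direction -> -direction).  Risk allele raising
    expression demands an inhibitor; lowering it, an activator.
    """
    if not odds_ratio > 0:
        raise ValidationError(f"odds_ratio must be > 0, got {odds_ratio}")
    if direction not in (1, -1):
        raise ValidationError(f"direction must be +1 or -1, got {direction}")
    if odds_ratio == 1:
        raise MechanismError("odds ratio is exactly 1: no risk direction to orient to")
    if odds_ratio > 1:
        risk_or, risk_direction = odds_ratio, direction
    else:
        risk_or, risk_direction = 1.0 / odds_ratio, -direction
    action = INHIBITOR if risk_direction == 1 else ACTIVATOR
    return action, risk_or, risk_direction


def match_drugs(
    call: MechanismCall,
    dgi: Sequence[DrugGeneInteraction],
    approved_only: bool = True,
) -> list[DrugGeneInteraction]:
    """Interactions for the call's gene whose action equals the required one."""
    return [
        d
        for d in dgi
        if d.gene_id == call.gene_id
        and d.action == call.required_action
        and (d.approved or not approved_only)
    ]


def filter_orthologs(
    gene_id: str,
    orthologs: Sequence[OrthologPair],
    min_identity: float = 40.0,
) -> Optional[OrthologPair]:
    """Highest-identity ortholog of ``gene_id`` at or above the threshold
    (inclusive); ties broken toward the smaller model gene id."""
    eligible = [
        o
        for o in orthologs
        if o.human_gene == gene_id and o.percent_identity >= min_identity
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda o: (-o.percent_identity, o.model_gene))


def _gene_mechanisms(
    pairs: Sequence[tuple[GwasSnp, EqtlRecord]], config: FunnelConfig
) -> tuple[dict[str, list[MechanismCall]], dict[str, bool]]:
    """Per-gene mechanism calls and a per-gene discordance flag.

    Pairs whose SNP has OR exactly 1 carry no risk direction and are
    dropped with a warning.
    """
    calls: dict[str, list[MechanismCall]] = {}
    for snp, eqtl in pairs:
        if snp.odds_ratio == 1:
            logger.warning(
                "SNP %s has OR exactly 1; pair with %s carries no mechanism",
                snp.snp_id, eqtl.gene_id,
            )
            continue
        direction = harmonized_direction(snp, eqtl, config.harmonization)
        action, risk_or, risk_dir = required_mechanism(snp.odds_ratio, direction)
        calls.setdefault(eqtl.gene_id, []).append(
            MechanismCall(eqtl.gene_id, action, snp.snp_id, risk_or, risk_dir)
        )
    discordant = {
        g: len({c.required_action for c in cl}) > 1 for g, cl in calls.items()
    }
    return calls, discordant


def _resolve_mechanism(
    calls: list[MechanismCall], policy: str
) -> Optional[MechanismCall]:
    """One representative call per gene under the discordance policy.

    Concordant genes keep their first call; under 'majority' the first
    call with the majority action is kept, with exact ties dropped.
    """
    actions = {c.required_action for c in calls}
    if len(actions) == 1:
        return calls[0]
    if policy == "exclude":
        return None
    n_inh = sum(c.required_action == INHIBITOR for c in calls)
    n_act = len(calls) - n_inh
    if n_inh == n_act:
        return None
    winner = INHIBITOR if n_inh > n_act else ACTIVATOR
    return next(c for c in calls if c.required_action == winner)


def run_funnel(
    gwas: Sequence[GwasSnp],
    genes: Sequence[GeneModel],
    eqtls: Sequence[EqtlRecord],
    dgi: Sequence[DrugGeneInteraction],
    orthologs: Sequence[OrthologPair],
    config: FunnelConfig = FunnelConfig(),
    bbb: Optional[Mapping[str, bool]] = None,
) -> FunnelReport:
    """Execute every funnel stage and return the stage counts and the
    ranked candidate table.

    ``bbb``, when given, maps drug names to blood-brain-barrier
    permeability (a precomputed annotation); candidates are then
    additionally required to retain at least one permeable drug.

    Final ranking: more supporting SNP-eQTL pairs first, then smaller
    best supporting GWAS p-value, then smaller distance from a
    supporting SNP to the candidate's own promoter, then gene_id.
    """
    counts: dict[str, int] = {"total_snps": len(gwas)}

    selected = select_significant(gwas, config.alpha)
    counts["significant_snps"] = len(selected)

    annotations = {a.snp_id: a for a in annotate_all(selected, genes)}

    pairs = intersect_cns_eqtls(selected, eqtls, config.tissues)
    gene_order: list[str] = []
    for _, e in pairs:
        if e.gene_id not in gene_order:
            gene_order.append(e.gene_id)
    counts["cns_eqtl_genes"] = len(gene_order)

    calls, discord = _gene_mechanisms(pairs, config)
    gene_tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
    support: dict[str, list[tuple[GwasSnp, EqtlRecord]]] = {}
    for snp, e in pairs:
        support.setdefault(e.gene_id, []).append((snp, e))

    candidates: dict[str, CandidateRecord] = {}
    for gid in gene_order:
        snps_for_gene = {s.snp_id: s for s, _ in support[gid]}
        best_p = min(s.p_value for s in snps_for_gene.values())
        dist = None
        if gid in gene_tss:
            chrom, tss = gene_tss[gid]
            dists = [abs(s.pos0 - tss) for s in snps_for_gene.values() if s.chrom == chrom]
            dist = min(dists) if dists else None
        candidates[gid] = CandidateRecord(
            gene_id=gid,
            passed_eqtl=True,
            n_support=len(support[gid]),
            best_p=best_p,
            promoter_distance_bp=dist,
            discordant=discord.get(gid, False),
        )

    with_mechanism: list[str] = []
    for gid in gene_order:
        resolved = _resolve_mechanism(calls[gid], config.discordant_policy) if gid in calls else None
        if resolved is not None:
            candidates[gid].mechanism = resolved
            with_mechanism.append(gid)
    counts["mechanism_genes"] = len(with_mechanism)

    with_drugs: list[str] = []
    for gid in with_mechanism:
        matched = match_drugs(candidates[gid].mechanism, dgi, config.approved_only)
        if matched:
            candidates[gid].matched_drugs = matched
            with_drugs.append(gid)
    counts["drug_matched_genes"] = len(with_drugs)

    with_ortholog: list[str] = []
    for gid in with_drugs:
        best = filter_orthologs(gid, orthologs, config.min_identity)
        if best is not None:
            candidates[gid].best_ortholog = best
            with_ortholog.append(gid)
    counts["ortholog_genes"] = len(with_ortholog)

    final = with_ortholog
    if bbb is not None:
        passing = []
        for gid in with_ortholog:
            c = candidates[gid]
            permeable = [d for d in c.matched_drugs if bbb.get(d.drug_name, False)]
            c.bbb_permeable = bool(permeable)
            if permeable:
                c.matched_drugs = permeable
                passing.append(gid)
        counts["bbb_genes"] = len(passing)
        final = passing

    big = float("inf")
    final_sorted = sorted(
        final,
        key=lambda gid: (
            -candidates[gid].n_support,
            candidates[gid].best_p,
            candidates[gid].promoter_distance_bp
            if candidates[gid].promoter_distance_bp is not None
            else big,
            gid,
        ),
    )
    for rank, gid in enumerate(final_sorted, start=1):
        candidates[gid].rank = rank

    logger.info("funnel stage counts: %s", counts)
    return FunnelReport(
        stage_counts=counts,
        candidates=[candidates[g] for g in gene_order],
        config_echo=config.echo(),
    )
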