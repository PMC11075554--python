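"""Synthetic input bundles with planted ground-truth candidates.

The generator emits every table the funnel consumes — GWAS summary
statistics, gene models, eQTL records, drug-gene interactions,
ortholog pairs — plus the record of which genes were constructed to
pass every funnel stage (the planted truth).  Background association
p-values are uniform on (0, 1] and background log odds ratios are
normal with a small standard deviation (0.03 by default, putting
background ORs in the ~1.02-1.04 band typical of a modest case-control
GWAS); planted supporting SNPs get p-values below the significance
threshold and inflated odds ratios.

eQTL directions follow a per-gene latent expression-risk relationship:
each gene carries one sign for the expression change associated with
the disease-risk allele, and every eQTL record for that gene is
written consistently with it (optionally corrupted at a configurable
noise rate).  This makes the generated data coherent under the
mechanism rule, so a gene's inhibitor/activator call does not depend
on which of its supporting SNPs clear the significance threshold.

A paralysis-assay generator produces event tables with exponential
event times under a configurable group hazard ratio, observed on a
periodic inspection grid and right-censored at the end of the assay.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .funnel import ACTIVATOR, INHIBITOR
from .io_formats import (
    CNS_TISSUES,
    NON_CNS_TISSUES,
    DrugGeneInteraction,
    EqtlRecord,
    EventTable,
    GeneModel,
    GwasSnp,
    OrthologPair,
    ValidationError,
    write_dgi,
    write_eqtls,
    write_events,
    write_genes,
    write_gwas,
    write_orthologs,
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic bundle.

    Background rates are per-SNP (eQTL records) or per-gene (drug and
    ortholog tables); with the defaults the probability that any
    background gene jointly passes every funnel stage is well below
    1e-4, so the final candidate set is the planted set for almost
    every seed.
    """

    n_snps: int = 10_000
    n_genes: int = 500
    n_chroms: int = 5
    n_planted: int = 1
    alpha: float = 1e-3
    tissues: tuple[str, ...] = tuple(sorted(CNS_TISSUES))
    bg_eqtl_rate: float = 0.05
    bg_drug_rate: float = 0.3
    bg_ortholog_rate: float = 0.3
    bg_log_or_sd: float = 0.03
    cns_fraction: float = 0.5
    direction_noise: float = 0.0
    allele_flip_rate: float = 0.0
    planted_support: tuple[int, ...] = (1,)
    planted_log_or_mean: float = 0.2
    planted_log_or_sd: float = 0.05
    min_identity: float = 40.0
    chrom_length: int = 10_000_000
    gene_overlap: bool = False

    def validate(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValidationError(
                f"infeasible config: n_planted={self.n_planted} > n_genes={self.n_genes}"
            )
        if self.n_chroms < 1 or self.n_genes < 1 or self.n_snps < 1:
            raise ValidationError("n_snps, n_genes and n_chroms must be positive")
        if self.n_planted > 0 and not (0 < self.alpha <= 1):
            raise ValidationError(
                "planting candidates requires a positive significance threshold"
            )
        total_support = sum(
            self.planted_support[i % len(self.planted_support)]
            for i in range(self.n_planted)
        )
        if total_support > self.n_snps:
            raise ValidationError("more planted supporting SNPs than SNPs")
        if not self.tissues:
            raise ValidationError("tissue list must be nonempty")


@dataclass
class PlantedCandidate:
    gene_id: str
    required_action: str
    supporting_snps: list[str]
    drug_name: str
    model_gene: str
    percent_identity: float


@dataclass
class PlantedTruth:
    """The generator's record of which genes must pass every funnel stage."""

    candidates: list[PlantedCandidate]
    background: dict[str, int]

    @property
    def gene_ids(self) -> set[str]:
        return {c.gene_id for c in self.candidates}

    def to_json(self) -> str:
        return json.dumps(
            {
                "candidates": [dataclasses.asdict(c) for c in self.candidates],
                "background": self.background,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        obj = json.loads(text)
        return cls(
            candidates=[PlantedCandidate(**c) for c in obj["candidates"]],
            background=obj["background"],
        )


@dataclass
class Bundle:
    """An in-memory input bundle plus its planted truth."""

    gwas: list[GwasSnp]
    genes: list[GeneModel]
    eqtls: list[EqtlRecord]
    dgi: list[DrugGeneInteraction]
    orthologs: list[OrthologPair]
    truth: PlantedTruth
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gwas": out / "gwas.tsv",
            "genes": out / "genes.bed",
            "eqtls": out / "eqtls.tsv",
            "dgi": out / "dgi.tsv",
            "orthologs": out / "orthologs.tsv",
            "truth": out / "truth.json",
        }
        write_gwas(self.gwas, paths["gwas"])
        write_genes(self.genes, paths["genes"])
        write_eqtls(self.eqtls, paths["eqtls"])
        write_dgi(self.dgi, paths["dgi"])
        write_orthologs(self.orthologs, paths["orthologs"])
        paths["truth"].write_text(self.truth.to_json() + "\n", encoding="utf-8")
        return paths


def _place_genes(config: GeneratorConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Genes spread over chromosomes; non-overlapping by slotting each
    gene into its own window unless ``gene_overlap`` is set."""
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for c, count in enumerate(per_chrom, start=1):
        chrom = f"chr{c}"
        if count == 0:
            continue
        if config.gene_overlap:
            for _ in range(count):
                length = int(rng.integers(5_000, 30_000))
                start = int(rng.integers(0, max(1, config.chrom_length - length)))
                genes.append(
                    GeneModel(
                        gene_id=f"GENE{gid:04d}",
                        chrom=chrom,
                        start=start,
                        end=start + length,
                        strand=rng.choice(("+", "-")),
                    )
                )
                gid += 1
        else:
            slot = config.chrom_length // count
            if slot < 35_000:
                raise ValidationError(
                    "chromosome too short for non-overlapping gene placement"
                )
            for k in range(count):
                length = int(rng.integers(5_000, 30_000))
                start = k * slot + int(rng.integers(0, slot - length))
                genes.append(
                    GeneModel(
                        gene_id=f"GENE{gid:04d}",
                        chrom=chrom,
                        start=start,
                        end=start + length,
                        strand=rng.choice(("+", "-")),
                    )
                )
                gid += 1
    return genes


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    eff = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    oth = (eff + shift) % 4
    bases = np.array(_BASES)
    return bases[eff], bases[oth]


def generate_bundle(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> Bundle:
    """Generate a complete schema-valid bundle, deterministic per seed.

    When ``out_dir`` is given the tables are also written as
    gwas.tsv / genes.bed / eqtls.tsv / dgi.tsv / orthologs.tsv /
    truth.json.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    genes = _place_genes(config, rng)
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}

    planted_idx = rng.choice(config.n_genes, size=config.n_planted, replace=False)
    planted_genes = [gene_ids[i] for i in sorted(planted_idx)]
    planted_set = set(planted_genes)

    # latent per-gene expression-risk direction; planted genes get theirs
    # from the drawn required action
    latent = rng.choice((1, -1), size=config.n_genes)
    required: dict[str, str] = {}
    for i, gid_ in enumerate(planted_genes):
        action = str(rng.choice((INHIBITOR, ACTIVATOR)))
        required[gid_] = action
        latent[gene_ids.index(gid_)] = 1 if action == INHIBITOR else -1
    latent_by_gene = dict(zip(gene_ids, latent))

    # --- GWAS table -------------------------------------------------------
    n = config.n_snps
    snp_numbers = rng.permutation(10 * n)[:n]
    snp_ids = [f"rs{int(v) + 1:07d}" for v in snp_numbers]
    chrom_idx = rng.integers(1, config.n_chroms + 1, size=n)
    positions = rng.integers(1, config.chrom_length + 1, size=n)
    eff, oth = _draw_alleles(rng, n)
    log_or = rng.normal(0.0, config.bg_log_or_sd, size=n)
    p_values = 1.0 - rng.random(n)  # uniform on (0, 1]

    # planted supporting SNPs overwrite background rows
    support_plan: dict[str, list[int]] = {}
    cursor = 0
    order = rng.permutation(n)
    for i, gid_ in enumerate(planted_genes):
        k = config.planted_support[i % len(config.planted_support)]
        rows = [int(order[cursor + j]) for j in range(k)]
        cursor += k
        support_plan[gid_] = rows
        g = gene_by_id[gid_]
        for row in rows:
            chrom_idx[row] = int(g.chrom[3:])
            positions[row] = max(1, g.tss + int(rng.integers(-5_000, 5_001)) + 1)
            p_values[row] = config.alpha * (0.05 + 0.9 * rng.random())
            magnitude = abs(rng.normal(config.planted_log_or_mean, config.planted_log_or_sd)) + 0.02
            log_or[row] = magnitude * (1 if rng.random() < 0.5 else -1)

    gwas = [
        GwasSnp(
            snp_id=snp_ids[i],
            chrom=f"chr{chrom_idx[i]}",
            pos=int(positions[i]),
            effect_allele=str(eff[i]),
            other_allele=str(oth[i]),
            odds_ratio=float(np.exp(log_or[i])),
            p_value=float(p_values[i]),
        )
        for i in range(n)
    ]
    gwas_by_id = {s.snp_id: s for s in gwas}

    def _eqtl_for(snp: GwasSnp, gid_: str, tissue: str, eqtl_p: float) -> EqtlRecord:
        """Direction coherent with the gene's latent risk relationship."""
        d_gene = latent_by_gene[gid_]
        risk_is_effect = snp.odds_ratio > 1
        direction = d_gene if risk_is_effect else -d_gene
        if rng.random() < config.direction_noise:
            direction = -direction
        allele = snp.effect_allele
        if rng.random() < config.allele_flip_rate:
            allele = snp.other_allele
            direction = -direction
        return EqtlRecord(
            snp_id=snp.snp_id,
            gene_id=gid_,
            tissue=tissue,
            direction=int(direction),
            eqtl_p=float(eqtl_p),
            effect_allele=allele,
        )

    eqtls: list[EqtlRecord] = []
    cns_list = list(config.tissues)
    other_list = sorted(NON_CNS_TISSUES)
    for gid_ in planted_genes:
        for row in support_plan[gid_]:
            snp = gwas[row]
            tissue = str(rng.choice(cns_list))
            eqtls.append(_eqtl_for(snp, gid_, tissue, 10 ** rng.uniform(-8, -4)))
    bg_eqtl_mask = rng.random(n) < config.bg_eqtl_rate
    n_bg_eqtl = 0
    for i in np.flatnonzero(bg_eqtl_mask):
        snp = gwas[i]
        gid_ = gene_ids[int(rng.integers(0, config.n_genes))]
        if rng.random() < config.cns_fraction:
            tissue = str(rng.choice(cns_list))
        else:
            tissue = str(rng.choice(other_list))
        eqtls.append(_eqtl_for(snp, gid_, tissue, 1.0 - rng.random()))
        n_bg_eqtl += 1

    # --- drug-gene interactions ------------------------------------------
    dgi: list[DrugGeneInteraction] = []
    drug_names: dict[str, str] = {}
    for gid_ in planted_genes:
        name = f"drug-{gid_.lower()}"
        drug_names[gid_] = name
        dgi.append(DrugGeneInteraction(gid_, name, required[gid_], approved=True))
    n_bg_drug = 0
    for i, gid_ in enumerate(gene_ids):
        if gid_ in planted_set:
            continue
        if rng.random() < config.bg_drug_rate:
            dgi.append(
                DrugGeneInteraction(
                    gid_,
                    f"cmpd{n_bg_drug:04d}",
                    str(rng.choice(("inhibitor", "activator", "other"))),
                    approved=bool(rng.random() < 0.5),
                )
            )
            n_bg_drug += 1

    # --- orthologs --------------------------------------------------------
    orthologs: list[OrthologPair] = []
    identity_by_gene: dict[str, float] = {}
    for gid_ in planted_genes:
        ident = float(rng.uniform(config.min_identity + 15, 90.0))
        identity_by_gene[gid_] = ident
        orthologs.append(OrthologPair(gid_, f"ce-{gid_.lower()}", ident, "synthetic"))
    n_bg_orth = 0
    for gid_ in gene_ids:
        if gid_ in planted_set:
            continue
        if rng.random() < config.bg_ortholog_rate:
            orthologs.append(
                OrthologPair(
                    gid_, f"ce-{gid_.lower()}", float(rng.uniform(20.0, 90.0)), "synthetic"
                )
            )
            n_bg_orth += 1

    truth = PlantedTruth(
        candidates=[
            PlantedCandidate(
                gene_id=gid_,
                required_action=required[gid_],
                supporting_snps=[gwas[row].snp_id for row in support_plan[gid_]],
                drug_name=drug_names[gid_],
                model_gene=f"ce-{gid_.lower()}",
                percent_identity=identity_by_gene[gid_],
            )
            for gid_ in planted_genes
        ],
        background={
            "n_snps": n,
            "n_genes": config.n_genes,
            "n_background_eqtls": n_bg_eqtl,
            "n_background_drug_rows": n_bg_drug,
            "n_background_orthologs": n_bg_orth,
        },
    )

    bundle = Bundle(
        gwas=gwas,
        genes=genes,
        eqtls=eqtls,
        dgi=dgi,
        orthologs=orthologs,
        truth=truth,
        config=config,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def verify_planted_truth(bundle: Bundle, config: Optional[GeneratorConfig] = None) -> set[str]:
    """Re-derive, from the raw tables alone, the set of genes that pass
    every funnel predicate.

    Deliberately naive — plain loops over the tables, independent of the
    funnel module's machinery — so it can serve as a ground-truth
    checker for both the generator and the funnel.
    """
    cfg = config or bundle.config
    tissues = set(cfg.tissues)
    sig = {s.snp_id: s for s in bundle.gwas if s.p_value < cfg.alpha}
    actions_by_gene: dict[str, set[str]] = {}
    for e in bundle.eqtls:
        if e.tissue not in tissues or e.snp_id not in sig:
            continue
        snp = sig[e.snp_id]
        if snp.odds_ratio == 1:
            continue
        direction = e.direction
        if e.effect_allele is not None and e.effect_allele == snp.other_allele:
            direction = -direction
        risk_dir = direction if snp.odds_ratio > 1 else -direction
        action = INHIBITOR if risk_dir == 1 else ACTIVATOR
        actions_by_gene.setdefault(e.gene_id, set()).add(action)
    passing: set[str] = set()
    for gid_, actions in actions_by_gene.items():
        if len(actions) != 1:
            continue  # discordant
        (action,) = actions
        has_drug = any(
            d.gene_id == gid_ and d.action == action and d.approved for d in bundle.dgi
        )
        if not has_drug:
            continue
        has_orth = any(
            o.human_gene == gid_ and o.percent_identity >= cfg.min_identity
            for o in bundle.orthologs
        )
        if has_orth:
            passing.add(gid_)
    return passing


def generate_events(
    n_per_group: int,
    hazard_ratio: float,
    seed: int = 0,
    groups: tuple[str, str] = ("control", "treated"),
    censor_time: float = 24.0,
    baseline_median: float = 8.0,
    interval: float = 2.0,
) -> EventTable:
    """Synthetic paralysis-assay event table for two groups.

    Event times are exponential; the first group has hazard
    ln(2)/``baseline_median`` and the second group's hazard is that
    divided by ``hazard_ratio`` (ratio > 1 means the second group is
    protected).  Times are observed on an inspection grid of
    ``interval`` hours — each event is recorded at the right endpoint
    of the interval in which it occurred — and subjects still moving at
    ``censor_time`` are censored there.
    """
    if n_per_group <= 0:
        raise ValidationError("n_per_group must be positive")
    if hazard_ratio <= 0 or baseline_median <= 0 or censor_time <= 0 or interval <= 0:
        raise ValidationError("hazard_ratio, baseline_median, censor_time and interval must be positive")
    rng = np.random.default_rng(seed)
    lam0 = math.log(2) / baseline_median
    rows = []
    for gi, group in enumerate(groups):
        lam = lam0 if gi == 0 else lam0 / hazard_ratio
        raw = rng.exponential(1.0 / lam, size=n_per_group)
        for j, t in enumerate(raw):
            observed = math.ceil(t / interval) * interval
            if t > censor_time or observed > censor_time:
                rows.append(
                    {
                        "subject_id": f"{group}-{j:03d}",
                        "group": group,
                        "time": float(censor_time),
                        "event": 0,
                    }
                )
            else:
                rows.append(
                    {
                        "subject_id": f"{group}-{j:03d}",
                        "group": group,
                        "time": float(max(observed, interval)),
                        "event": 1,
                    }
                )
    return EventTable(pd.DataFrame(rows, columns=list(EventTable.COLUMNS)))
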