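"""Typed records and strict readers/writers for every table the pipeline touches.

All tables are tab-separated UTF-8 text with a mandatory header row;
``#``-prefixed lines are comments.  Gene models use BED conventions
(0-based, half-open); GWAS and eQTL positions are 1-based points.  The
1-based/0-based conversion is centralized in :func:`to_zero_based` /
:func:`to_one_based` so that no other module does coordinate arithmetic
on raw integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The 13 central-nervous-system tissues used to restrict the eQTL
#: intersection (GTEx brain/spinal tissue panel).
CNS_TISSUES = frozenset(
    {
        "Amygdala",
        "Anterior Cingulate Cortex BA24",
        "Caudate basal ganglia",
        "Cerebellar Hemisphere",
        "Cerebellum",
        "Cortex",
        "Frontal Cortex",
        "Hippocampus",
        "Hypothalamus",
        "Nucleus accumbens",
        "Putamen",
        "Spinal cord",
        "Substantia nigra",
    }
)

#: Non-CNS tissues accepted by the default vocabulary.  Records in these
#: tissues are valid input but are removed by the CNS filter.
NON_CNS_TISSUES = frozenset(
    {
        "Adipose Subcutaneous",
        "Heart Left Ventricle",
        "Liver",
        "Lung",
        "Pancreas",
        "Skeletal Muscle",
        "Skin",
        "Spleen",
        "Thyroid",
        "Whole Blood",
    }
)

TISSUE_VOCABULARY = CNS_TISSUES | NON_CNS_TISSUES

DRUG_ACTIONS = ("inhibitor", "activator", "other")

_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """A record or table violates a schema invariant."""


class SchemaError(ValidationError):
    """A file lacks a required column or is structurally malformed."""


def to_zero_based(pos_1based: int) -> int:
    """Convert a 1-based point coordinate to 0-based (BED-style)."""
    return int(pos_1based) - 1


def to_one_based(pos_0based: int) -> int:
    """Convert a 0-based point coordinate back to 1-based."""
    return int(pos_0based) + 1


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GwasSnp:
    """One GWAS summary-statistic record.

    ``odds_ratio`` is the per-effect-allele odds ratio for case status;
    ``p_value`` the association p-value.  ``pos`` is a 1-based point.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    odds_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be nonempty")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if len(a) != 1 or a not in _BASES:
                raise ValidationError(f"{self.snp_id}: {name} must be a single base in ACGT, got {a!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.odds_ratio > 0:
            raise ValidationError(f"{self.snp_id}: odds_ratio must be > 0, got {self.odds_ratio}")
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"{self.snp_id}: p_value must be in (0, 1], got {self.p_value}")

    @property
    def pos0(self) -> int:
        """SNP coordinate in the 0-based system shared with gene models."""
        return to_zero_based(self.pos)


@dataclass(frozen=True)
class GeneModel:
    """A gene body span in BED coordinates (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be nonempty")
        if self.start < 0 or not self.start < self.end:
            raise ValidationError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based point, inside [start, end))."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class EqtlRecord:
    """A SNP-to-gene expression association in one tissue.

    ``direction`` is the sign of expression change per copy of
    ``effect_allele``.  A record with no effect allele is accepted but
    flagged unharmonized; downstream mechanism calls then depend on the
    harmonization policy.
    """

    snp_id: str
    gene_id: str
    tissue: str
    direction: int
    eqtl_p: float
    effect_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValidationError(
                f"{self.snp_id}/{self.gene_id}: direction must be +1 or -1, got {self.direction}"
            )
        if not (0 < self.eqtl_p <= 1):
            raise ValidationError(
                f"{self.snp_id}/{self.gene_id}: eqtl_p must be in (0, 1], got {self.eqtl_p}"
            )
        if self.effect_allele is not None and (
            len(self.effect_allele) != 1 or self.effect_allele not in _BASES
        ):
            raise ValidationError(
                f"{self.snp_id}/{self.gene_id}: effect_allele must be a single base, got {self.effect_allele!r}"
            )

    @property
    def harmonized(self) -> bool:
        return self.effect_allele is not None


@dataclass(frozen=True)
class DrugGeneInteraction:
    gene_id: str
    drug_name: str
    action: str
    approved: bool

    def __post_init__(self) -> None:
        if self.action not in DRUG_ACTIONS:
            raise ValidationError(
                f"{self.gene_id}/{self.drug_name}: action must be one of {DRUG_ACTIONS}, got {self.action!r}"
            )


@dataclass(frozen=True)
class OrthologPair:
    human_gene: str
    model_gene: str
    percent_identity: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValidationError(
                f"{self.human_gene}/{self.model_gene}: percent_identity must be in [0, 100], "
                f"got {self.percent_identity}"
            )


@dataclass
class EventTable:
    """Per-subject time-to-event observations (e.g. worm time to paralysis).

    Wraps a DataFrame with columns ``subject_id, group, time, event``
    where ``event`` is 1 for an observed event (paralysis) and 0 for a
    censored subject, and ``time`` is in hours.
    """

    frame: pd.DataFrame

    COLUMNS = ("subject_id", "group", "time", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"event table missing column(s): {', '.join(missing)}")
        f = self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        f["time"] = f["time"].astype(float)
        f["event"] = f["event"].astype(int)
        if (f["time"] < 0).any():
            bad = f.index[f["time"] < 0][0]
            raise ValidationError(f"event table row {bad + 1}: time must be >= 0")
        if ~f["event"].isin((0, 1)).all():
            bad = f.index[~f["event"].isin((0, 1))][0]
            raise ValidationError(f"event table row {bad + 1}: event must be 0 or 1")

    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def subset(self, group: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == group]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# low-level TSV plumbing
# ---------------------------------------------------------------------------


def _read_rows(path: str | Path, required: Sequence[str]) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a commented TSV, returning the header and (line_number, fields) rows.

    Line numbers are 1-based positions in the physical file so that
    validation errors point at the offending line even when comment
    lines are interspersed.
    """
    path = Path(path)
    header: Optional[list[str]] = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if header is None:
                header = fields
                continue
            rows.append((lineno, fields))
    if header is None:
        raise SchemaError(f"{path}: empty file (header row required)")
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return header, rows


def _row_dict(header: list[str], fields: list[str], path: Path, lineno: int) -> dict[str, str]:
    if len(fields) != len(header):
        raise SchemaError(
            f"{path}, line {lineno}: expected {len(header)} fields, found {len(fields)}"
        )
    return dict(zip(header, fields))


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

GWAS_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "or", "p")


def read_gwas(path: str | Path) -> list[GwasSnp]:
    """Read a GWAS summary-statistic TSV into validated records.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (citing the file line) for a bad row.
    Duplicated snp_ids are a hard error: downstream joins are by snp_id
    and would be ambiguous.
    """
    path = Path(path)
    header, rows = _read_rows(path, GWAS_COLUMNS)
    out: list[GwasSnp] = []
    for lineno, fields in rows:
        rec = _row_dict(header, fields, path, lineno)
        try:
            out.append(
                GwasSnp(
                    snp_id=rec["snp_id"],
                    chrom=rec["chrom"],
                    pos=int(rec["pos"]),
                    effect_allele=rec["effect_allele"],
                    other_allele=rec["other_allele"],
                    odds_ratio=float(rec["or"]),
                    p_value=float(rec["p"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    seen: dict[str, str] = {}
    keys = set()
    for snp in out:
        if snp.snp_id in seen:
            where = "across chromosomes" if seen[snp.snp_id] != snp.chrom else "within a chromosome"
            raise ValidationError(f"{path}: duplicate snp_id {snp.snp_id} {where}")
        seen[snp.snp_id] = snp.chrom
        keys.add((snp.chrom, snp.pos, snp.snp_id))
    logger.info("read %d GWAS records from %s", len(out), path)
    return out


def write_gwas(records: Sequence[GwasSnp], path: str | Path) -> None:
    _write_tsv(
        path,
        GWAS_COLUMNS,
        (
            (s.snp_id, s.chrom, s.pos, s.effect_allele, s.other_allele,
             repr(s.odds_ratio), repr(s.p_value))
            for s in records
        ),
    )


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene bodies from a 6-column BED file (0-based, half-open)."""
    path = Path(path)
    out: list[GeneModel] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if len(fields) < 6:
                raise SchemaError(
                    f"{path}, line {lineno}: BED gene records need 6 columns "
                    f"(chrom start end name score strand), found {len(fields)}"
                )
            try:
                out.append(
                    GeneModel(
                        gene_id=fields[3],
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        strand=fields[5],
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    dup = {g.gene_id for g in out if sum(h.gene_id == g.gene_id for h in out) > 1}
    if dup:
        raise ValidationError(f"{path}: duplicate gene_id(s): {', '.join(sorted(dup))}")
    logger.info("read %d gene models from %s", len(out), path)
    return out


def write_genes(records: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in records:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


EQTL_COLUMNS = ("snp_id", "gene_id", "tissue", "direction", "eqtl_p", "effect_allele")


def read_eqtls(path: str | Path, tissues: Optional[frozenset[str]] = None) -> list[EqtlRecord]:
    """Read eQTL records; ``tissues`` is the accepted vocabulary (default
    the CNS panel plus the common non-CNS tissue names)."""
    path = Path(path)
    vocab = TISSUE_VOCABULARY if tissues is None else frozenset(tissues)
    header, rows = _read_rows(path, EQTL_COLUMNS)
    out: list[EqtlRecord] = []
    for lineno, fields in rows:
        rec = _row_dict(header, fields, path, lineno)
        if rec["tissue"] not in vocab:
            raise ValidationError(
                f"{path}, line {lineno}: unknown tissue {rec['tissue']!r}; "
                f"allowed: {', '.join(sorted(vocab))}"
            )
        allele = rec["effect_allele"].strip()
        try:
            out.append(
                EqtlRecord(
                    snp_id=rec["snp_id"],
                    gene_id=rec["gene_id"],
                    tissue=rec["tissue"],
                    direction=int(rec["direction"]),
                    eqtl_p=float(rec["eqtl_p"]),
                    effect_allele=None if allele in ("", ".") else allele,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    logger.info("read %d eQTL records from %s", len(out), path)
    return out


def write_eqtls(records: Sequence[EqtlRecord], path: str | Path) -> None:
    _write_tsv(
        path,
        EQTL_COLUMNS,
        (
            (e.snp_id, e.gene_id, e.tissue, f"{e.direction:+d}", repr(e.eqtl_p),
             e.effect_allele if e.effect_allele is not None else ".")
            for e in records
        ),
    )


DGI_COLUMNS = ("gene_id", "drug_name", "action", "approved")


def read_dgi(path: str | Path) -> list[DrugGeneInteraction]:
    path = Path(path)
    header, rows = _read_rows(path, DGI_COLUMNS)
    out: list[DrugGeneInteraction] = []
    for lineno, fields in rows:
        rec = _row_dict(header, fields, path, lineno)
        approved = rec["approved"].strip().lower()
        if approved not in ("true", "false", "1", "0"):
            raise ValidationError(
                f"{path}, line {lineno}: approved must be true/false, got {rec['approved']!r}"
            )
        try:
            out.append(
                DrugGeneInteraction(
                    gene_id=rec["gene_id"],
                    drug_name=rec["drug_name"],
                    action=rec["action"],
                    approved=approved in ("true", "1"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    logger.info("read %d drug-gene interactions from %s", len(out), path)
    return out


def write_dgi(records: Sequence[DrugGeneInteraction], path: str | Path) -> None:
    _write_tsv(
        path,
        DGI_COLUMNS,
        ((d.gene_id, d.drug_name, d.action, "true" if d.approved else "false") for d in records),
    )


ORTHOLOG_COLUMNS = ("human_gene", "model_gene", "percent_identity", "source")


def read_orthologs(path: str | Path) -> list[OrthologPair]:
    path = Path(path)
    header, rows = _read_rows(path, ORTHOLOG_COLUMNS)
    out: list[OrthologPair] = []
    for lineno, fields in rows:
        rec = _row_dict(header, fields, path, lineno)
        try:
            out.append(
                OrthologPair(
                    human_gene=rec["human_gene"],
                    model_gene=rec["model_gene"],
                    percent_identity=float(rec["percent_identity"]),
                    source=rec["source"],
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    logger.info("read %d ortholog pairs from %s", len(out), path)
    return out


def write_orthologs(records: Sequence[OrthologPair], path: str | Path) -> None:
    _write_tsv(
        path,
        ORTHOLOG_COLUMNS,
        ((o.human_gene, o.model_gene, repr(o.percent_identity), o.source) for o in records),
    )


EVENT_COLUMNS = EventTable.COLUMNS


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    header, rows = _read_rows(path, EVENT_COLUMNS)
    recs = []
    for lineno, fields in rows:
        rec = _row_dict(header, fields, path, lineno)
        try:
            recs.append(
                {
                    "subject_id": rec["subject_id"],
                    "group": rec["group"],
                    "time": float(rec["time"]),
                    "event": int(rec["event"]),
                }
            )
        except ValueError as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    try:
        table = EventTable(pd.DataFrame(recs, columns=list(EVENT_COLUMNS)))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    logger.info("read %d event observations from %s", len(table), path)
    return table


def write_events(table: EventTable, path: str | Path) -> None:
    _write_tsv(
        path,
        EVENT_COLUMNS,
        (
            (r.subject_id, r.group, repr(float(r.time)), int(r.event))
            for r in table.frame.itertuples(index=False)
        ),
    )
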