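"""Characterization statistics for the significant-SNP set.

Covers the descriptive comparisons run alongside the funnel: drawing
random control SNP sets, comparing intragenic fractions between the
significant and control sets (two-proportion chi-square), comparing
mean odds ratios between intragenic and intergenic significant SNPs
(t-test), and measuring overlap of the implicated genes with a list of
previously disease-associated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import INTRAGENIC, SnpAnnotation, annotate_all
from .funnel import select_significant
from .io_formats import GeneModel, GwasSnp, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProportionTest:
    x1: int
    n1: int
    x2: int
    n2: int
    statistic: float
    p_value: float
    correction: bool


@dataclass(frozen=True)
class MeanComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t_statistic: float
    p_value: float
    variant: str


def _round_half_up(value: float, ndigits: int) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


def sample_control_snps(
    all_snps: Sequence[GwasSnp], n: int, seed: int
) -> list[GwasSnp]:
    """Simple random sample of ``n`` SNPs without replacement, deterministic per seed."""
    if n > len(all_snps):
        raise ValidationError(f"cannot sample {n} SNPs from {len(all_snps)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_snps), size=n, replace=False)
    return [all_snps[i] for i in idx]


def two_proportion_chisq(
    x1: int, n1: int, x2: int, n2: int, correction: bool = False
) -> ProportionTest:
    """Pearson chi-square on the 2x2 table (x1, n1-x1; x2, n2-x2), 1 df,
    two-sided; Yates continuity correction applied iff ``correction``.

    A zero margin (all successes or all failures pooled) yields
    statistic 0 / p 1 with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("need 0 <= x <= n in both groups")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        logger.warning("two_proportion_chisq: zero margin, returning p = 1")
        return ProportionTest(x1, n1, x2, n2, 0.0, 1.0, correction)
    res = stats.chi2_contingency(table, correction=correction)
    return ProportionTest(x1, n1, x2, n2, float(res.statistic), float(res.pvalue), correction)


def mean_comparison_ttest(
    sample1: Sequence[float], sample2: Sequence[float], variant: str = "student"
) -> MeanComparison:
    """Two-sided two-sample t-test; 'student' pools variances, 'welch' does not."""
    if variant not in ("student", "welch"):
        raise ValidationError(f"variant must be student|welch, got {variant!r}")
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return MeanComparison(
        mean1=float(a.mean()),
        sd1=float(a.std(ddof=1)),
        n1=len(a),
        mean2=float(b.mean()),
        sd2=float(b.std(ddof=1)),
        n2=len(b),
        t_statistic=float(t),
        p_value=float(p),
        variant=variant,
    )


def overlap_with_known(
    candidate_genes: set[str], known_genes: set[str]
) -> tuple[int, float]:
    """Count and percentage (of candidates, half-up to 1 decimal) of
    candidate genes previously associated with the disease."""
    if not candidate_genes or not known_genes:
        raise ValidationError("both gene sets must be nonempty")
    count = len(candidate_genes & known_genes)
    percent = _round_half_up(100.0 * count / len(candidate_genes), 1)
    return count, percent


def intragenic_fraction(annotations: Sequence[SnpAnnotation]) -> tuple[int, float]:
    """Number and fraction of annotations classified intragenic."""
    count = sum(a.location_class == INTRAGENIC for a in annotations)
    fraction = count / len(annotations) if annotations else 0.0
    return count, fraction


def characterize_gwas(
    snps: Sequence[GwasSnp],
    genes: Sequence[GeneModel],
    known_genes: Optional[set[str]] = None,
    alpha: float = 1e-3,
    n_draws: int = 1,
    seed: int = 0,
    correction: bool = False,
    variant: str = "student",
) -> dict:
    """The full characterization block around the significance filter.

    Selects SNPs at ``alpha``, annotates them, and reports: the
    intragenic fraction; for each of ``n_draws`` random control sets of
    the same size, the control intragenic fraction and a two-proportion
    chi-square against the significant set; the mean-odds-ratio
    comparison between intragenic and intergenic significant SNPs; and,
    when ``known_genes`` is given, the overlap of host genes of
    intragenic significant SNPs with that list.  Returns a
    JSON-serializable dict.
    """
    selected = select_significant(snps, alpha)
    ann = annotate_all(selected, genes)
    x_sig, frac_sig = intragenic_fraction(ann)
    out: dict = {
        "alpha": alpha,
        "n_total": len(snps),
        "n_significant": len(selected),
        "intragenic": {
            "count": x_sig,
            "percent": _round_half_up(100.0 * frac_sig, 2) if ann else 0.0,
        },
        "control_draws": [],
    }
    for d in range(n_draws):
        control = sample_control_snps(snps, len(selected), seed + d)
        ann_c = annotate_all(control, genes)
        x_c, frac_c = intragenic_fraction(ann_c)
        test = two_proportion_chisq(x_sig, len(ann), x_c, len(ann_c), correction=correction)
        out["control_draws"].append(
            {
                "seed": seed + d,
                "count": x_c,
                "percent": _round_half_up(100.0 * frac_c, 2) if ann_c else 0.0,
                "chisq_statistic": test.statistic,
                "chisq_p": test.p_value,
            }
        )
    intra_or = [s.odds_ratio for s, a in zip(selected, ann) if a.location_class == INTRAGENIC]
    inter_or = [s.odds_ratio for s, a in zip(selected, ann) if a.location_class != INTRAGENIC]
    if len(intra_or) >= 2 and len(inter_or) >= 2:
        cmp = mean_comparison_ttest(intra_or, inter_or, variant=variant)
        out["or_comparison"] = {
            "intragenic_mean": cmp.mean1,
            "intragenic_sd": cmp.sd1,
            "intergenic_mean": cmp.mean2,
            "intergenic_sd": cmp.sd2,
            "t_statistic": cmp.t_statistic,
            "p_value": cmp.p_value,
            "variant": cmp.variant,
        }
    if known_genes:
        hosts = {a.host_gene for a in ann if a.location_class == INTRAGENIC}
        if hosts:
            count, percent = overlap_with_known(hosts, set(known_genes))
            out["known_gene_overlap"] = {
                "n_candidate_genes": len(hosts),
                "count": count,
                "percent": percent,
            }
    return out
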