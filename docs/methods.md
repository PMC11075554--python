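# Methods

## The prioritization model

The package reanalyzes case-control GWAS summary statistics to nominate
approved drugs for repurposing. The reasoning chain is: a variant associated
with disease risk that is also an expression quantitative trait locus (eQTL)
in a disease-relevant tissue ties the disease to the *direction* of a gene's
expression; a drug that pushes expression (or activity) the opposite way is a
mechanistically sensible candidate.

Formally, every association is first re-oriented to its **risk allele**. For
an odds ratio OR and an eQTL effect direction d ∈ {+1, −1} (sign of
expression change per effect-allele copy, harmonized to the same allele as
the OR):

- if OR < 1, replace (OR, d) by (1/OR, −d) — the unique involution that
  re-expresses the association against the opposite allele;
- the risk allele raising expression (d_risk = +1) calls for an **inhibitor**;
  lowering it (d_risk = −1), an **activator**;
- OR exactly 1 carries no risk direction and is an error at the call site
  (such pairs are dropped with a warning inside the full cascade).

The funnel applies, in order: (1) significance filter p < α on the GWAS
table; (2) annotation of surviving SNPs against gene bodies (intragenic =
inside a [start, end) span; intergenic SNPs are assigned the gene with the
nearest strand-aware TSS, ties to the smaller gene id); (3) intersection
with eQTL records restricted to a 13-name CNS tissue panel; (4) the
mechanism call above, per supporting (SNP, eQTL) pair, aggregated per gene;
(5) matching against a drug–gene interaction table on (gene, required
action, approved); (6) an ortholog filter for the model organism at ≥ 40%
identity (inclusive); (7) optionally, a blood–brain-barrier permeability
filter when a per-drug annotation is supplied (permeability is consumed as a
precomputed column, never computed here).

Final candidates are ranked by: number of supporting SNP–eQTL pairs
(descending), best supporting GWAS p-value (ascending), minimum distance
from a supporting SNP to the candidate's own promoter (ascending), gene id.
The ranking keys are this package's choice; distance to the candidate's own
TSS is used (not the SNP's globally nearest gene, which may be a different
gene and would be meaningless as a key for this candidate).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 1e-3 | GWAS significance threshold. The source analysis states both p < 0.01 and χ² p < 10⁻³ for the same SNP count; the stricter value is the default and the key is required configuration, so the choice is always explicit. |
| `tissues` | 13 CNS names | Amygdala … Substantia nigra panel; the eQTL intersection is vacuous without a tissue restriction, so an empty set is an error. |
| `min_identity` | 40.0 (%) | Ortholog filter, inclusive at the boundary. |
| `approved_only` | true | Repurposing targets approved drugs. |
| `harmonization` | strict | OR and eQTL direction must refer to the same allele. An eQTL record naming the GWAS other allele has its direction negated; a record with no allele is an error in strict mode and assumed pre-harmonized in `assume` mode. |
| `discordant_policy` | exclude | A gene whose supporting SNPs imply conflicting mechanisms is dropped; `majority` keeps the majority call (exact ties dropped). |

Coordinates: gene models are BED (0-based half-open); GWAS/eQTL positions
are 1-based points; conversion is centralized in one pair of functions.
The genome build is opaque — all inputs are assumed to share one coordinate
system, and no liftover is performed.

## Statistical routines

- Two-proportion comparisons: Pearson χ² on the 2×2 table, 1 df, two-sided,
  Yates correction off by default (exposed as a flag; the printed values the
  package is checked against cannot adjudicate the flavor from rounded
  inputs). Zero margins return p = 1 with a warning.
- Mean comparisons: two-sample t, pooled ("student", the default, taking the
  source's "Student t-test" at its word) or Welch.
- Mann–Whitney U: exact enumeration of the permutation null (midranks, so
  ties are handled) for total n ≤ 12; otherwise the normal approximation
  with tie and continuity correction. The two-sided exact p is
  2·min(P(U ≤ u), P(U ≥ u)), capped at 1.
- Kruskal–Wallis H with tie correction, χ² approximation, df = groups − 1;
  an all-identical input returns (0, 1) rather than an error.
- Survival: Kaplan–Meier product-limit curves per group (lifelines), reported
  at every distinct observed time with risk-set sizes, and the two-group
  log-rank test (χ², 1 df). With no censoring the KM curve equals the
  empirical survival function exactly.
- Fold change: ratio rounded half-up to 2 decimals; "magnitude" orientation
  (max/min) is the default because the group labels in the source's ATP
  figures appear inconsistent, and magnitude is label-proof. All printed
  percentages are rounded half-up to match the source's style.

## What the synthetic generator emulates

A bundle contains all five tables plus the planted truth. Background
association p-values are uniform on (0, 1]; background log odds ratios are
N(0, 0.03), landing background ORs in the ~1.02–1.04 band of a modest
case-control study. Planted candidate genes get 1–3 supporting SNPs placed
within 5 kb of their TSS with p-values strictly below α and |log OR|
inflated (~0.2), an eQTL record in a CNS tissue whose direction encodes the
drawn required mechanism, an approved drug of that action, and an ortholog
comfortably above the identity threshold. Background tables carry eQTL
records at a per-SNP rate (half CNS by default), drug rows at a per-gene
rate with random action/approval, and orthologs with identity uniform on
(20, 90). With the defaults, the probability that a background gene jointly
passes every stage is of order 10⁻⁵ per bundle-gene (≈ a few ×10⁻³ per
bundle), so the final candidate set equals the planted set for almost every
seed; an independent checker (plain loops over the raw tables, sharing no
code with the funnel) re-derives the passing set per seed.

eQTL directions follow a **per-gene latent expression-risk sign**: each gene
carries one sign for the expression change associated with the risk allele,
and every record for that gene is written consistently with it given each
SNP's risk orientation (a `direction_noise` rate can corrupt this). This is
the causal model the mechanism rule presumes, and it makes threshold
relaxation (larger α, more tissues, lower identity cutoff) provably
monotone: a gene's mechanism call cannot flip when more of its SNPs become
significant. Under per-record random directions that guarantee disappears —
a newly significant conflicting SNP can discord a gene out of the funnel —
which is a real phenomenon in real data and a documented limitation, not
something the generator's defaults exercise.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, genotype-level data, population structure,
correlated eQTL effects across tissues, or overlapping genes (available via
`gene_overlap=True` for stress-testing tie-breaks). Passing tests therefore
demonstrate the correctness of the filtering logic and statistics under
clean planted signal, not robustness to LD-driven confounding.

The paralysis-assay generator draws exponential event times (control median
8 h), applies the configured hazard ratio to the treated arm, records each
event at the right endpoint of a 2 h inspection interval (observations are
made every 2–3 h in the emulated assay design, and interval-censored
likelihoods are out of scope), and censors at 24 h. Ninety subjects per arm
reproduces the assay's design size; at hazard ratio 4 the log-rank p falls
below 10⁻⁴ in ≈99% of seeds, consistent with the strongly separated motility
curves the design is meant to mirror.

## Numerical choices and degenerate inputs

- Strict inequality at the significance threshold (p < α), inclusive at the
  ortholog threshold (≥); both covered by boundary tests.
- All tie-breaks are lexicographic on ids and documented at each operation.
- α = 0 is allowed and yields an empty funnel; α = 1 keeps everything with
  p < 1.
- Stage counts mix units the way the source funnel does (SNPs, then genes);
  monotonicity is enforced within the SNP stages and within the gene-counted
  stages. A one-SNP/many-genes eQTL pattern can make the first gene count
  exceed the significant-SNP count; that is a property of the data, not a
  bug.
- Problem sizes used by the shipped checks (50 bundles of 10,000 SNPs × 500
  genes; 1,000 small randomized funnel cases; 5,000-draw null calibrations;
  200-seed power runs) were chosen to give tight Monte-Carlo bands while
  keeping a full run comfortably fast on one core.

## Known limitations

- The funnel consumes summary statistics only; no LD clumping,
  colocalization, or Mendelian randomization — one eQTL SNP is treated as one
  independent piece of support.
- "Promoter" is a TSS point (an optional upstream window exists but is off
  by default); exon-level or regulatory annotation is out of scope.
- Mechanism discordance handling is a policy, not an inference; conflicting
  support is dropped (or majority-voted), never modeled.
- The exact Mann–Whitney branch enumerates C(n, n1) subsets and is
  intentionally capped at n = 12.
- Real cross-database joins (GTEx archives, PLINK binaries, DGIdb API) are
  out of scope; the readers accept the minimal TSV/BED supersets documented
  in the module.
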