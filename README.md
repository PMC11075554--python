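# gwasfunnel

Prioritize drug-repurposing candidates from GWAS summary statistics by a
direction-of-effect funnel, and analyze the model-organism assays used to
validate them.

## The problem

A case-control GWAS yields thousands of sub-genome-wide association signals
that are individually uninterpretable. When one of those variants is also an
expression quantitative trait locus (eQTL) in a disease-relevant tissue, the
pair ties disease risk to the *direction* of a gene's expression — and
therefore to a pharmacological strategy: if the risk allele (odds ratio
OR > 1, after re-orienting OR < 1 records via OR → 1/OR with the eQTL sign
flipped) is associated with **higher** target mRNA, the gene calls for an
**inhibitor**; with **lower** mRNA, an **activator**. Crossing those
mechanism calls with approved drug–gene interactions and a model-organism
ortholog filter yields a short, testable candidate list. This package
implements that cascade as a typed, reproducible pipeline:

```
GWAS SNPs --p<α--> significant SNPs --CNS eQTL--> genes --mechanism-->
  inhibitor/activator calls --approved drugs--> druggable genes
  --ortholog ≥40% id--> candidates [--BBB permeable--> candidates]
```

together with the surrounding characterization statistics (control-SNP
draws, intragenic-fraction χ², odds-ratio t-tests, known-gene overlap) and
the validation-assay statistics (Kaplan–Meier paralysis curves, log-rank,
fold changes, Mann–Whitney, Kruskal–Wallis). A synthetic-data module
generates complete schema-valid input bundles with planted ground-truth
candidates, so the whole pipeline is testable without any external download.

It is written for bioinformaticians who want to rerun or adapt this style of
repurposing screen, and for skeptics who want to audit one.

## Worked example

Generate a synthetic bundle with one planted candidate and run the funnel:

```bash
$ gwasfunnel simulate --seed 3 --out-dir bundle
wrote bundle with 10000 SNPs, 500 genes, 1 planted candidate(s) to bundle
$ gwasfunnel funnel --gwas bundle/gwas.tsv --genes bundle/genes.bed \
    --eqtls bundle/eqtls.tsv --dgi bundle/dgi.tsv \
    --orthologs bundle/orthologs.tsv --out-prefix run/out
total_snps: 10000
significant_snps: 12
cns_eqtl_genes: 1
mechanism_genes: 1
drug_matched_genes: 1
ortholog_genes: 1
```

Of 10,000 SNPs, 12 pass the default α = 10⁻³ (≈10 expected by chance plus
the planted signal); exactly one of them is a CNS eQTL, and that gene
survives mechanism, drug, and ortholog filters. `run/out.candidates.tsv`
holds the ranked table:

```
rank  gene_id   required_action  risk_or   n_support  matched_drugs      model_ortholog  ...
1     GENE0329  inhibitor        1.282395  1          drug-gene0329      ce-gene0329
```

i.e. the risk allele of the supporting SNP raises GENE0329 expression
(risk OR 1.28), so an approved inhibitor of it is the repurposing
candidate — which is exactly the gene the generator planted
(`bundle/truth.json`). `run/out.report.json` carries the stage counts and
configuration echo; `manifest.json` records input digests and the seed.

The assay statistics work the same way from Python:

```python
>>> from gwasfunnel import fold_change, generate_events, logrank_test
>>> fold_change(1165, 384.9)        # ATP content, treated vs untreated
3.03
>>> ev = generate_events(90, 4.0, seed=2)   # 90 worms/arm, hazard ratio 4
>>> logrank_test(ev, "control", "treated")
(57.11337402990974, 4.1139849239556134e-14)
```

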