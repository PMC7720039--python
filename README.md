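# panproteo

Downstream analysis of pan-cancer DIA (data-independent acquisition)
proteome quantification matrices. The package takes a proteins × samples
intensity matrix (the product of a DIA search/quantification engine), sample
metadata over 16 tissue types with tumor / NAT / normal disease states, and
plain-TSV annotation tables, and carries them through the full
characterization workflow used in pan-cancer tissue proteomics:

1. **Sample QC** — replicate-injection CV/correlation checks, and a
   per-sample qualification decision: a sample enters the analysis if it
   meets at least 3 of 5 criteria (≥50% of the cohort's proteins quantified;
   similar median; mean within-tissue Pearson r > 0.6; similar intensity
   distribution; grouping with its tissue in PCA), evaluated independently
   per cancer type.
2. **Quantifiability filter + imputation** — keep proteins quantified in
   ≥40% of at least one cancer cohort; fill missing values with a two-branch
   left-censoring rule: 5% of the sample's smallest intensity above 100 when
   the protein is seen in <50% of same-tissue samples, otherwise the tissue
   mean − 2·SD.
3. **Housekeeping proteins** — proteins observed (pre-imputation) in >90% of
   tumor samples *and* >90% of normal samples, with reference-list overlap
   and an across-tissue stability score.
4. **Tissue enrichment** — pairwise tissue t tests (tumor+normal pooled per
   tissue, log2 scale, BH-adjusted per tissue pair); a protein is enriched
   in a tissue when it beats ≥70% of the other tissues (>4-fold, adjusted
   p < 0.05) — at 16 tissues that is 11 of 15 comparisons. Multiplicity
   (1/2/3/4+ tissues) and anatomic tissue-group enrichment (digestive /
   urinary / gynecologic) included.
5. **Differential analysis** — per-cancer tumor-vs-normal Welch t tests with
   BH adjustment; calls require fold change > 2 at adjusted p < 0.05.
   Cross-cancer aggregation (up in >40% of analysed cancers), unique-cancer
   calls, and Ward hierarchical clustering of Z-scored profiles into four
   protein groups (PG-1..PG-4).
6. **Annotation joins** — druggable candidates (FDA-approved drug target ∩
   up in ≥1 cancer), cancer/testis antigen detection/elevation calls, and
   the cancer-associated × driver-gene overlap.

Because real cohorts of this design are not freely redistributable, the
package ships a first-class synthetic cohort generator
(`panproteo.simulate`) that emulates the assumed statistical structure —
log-normal intensities, intensity-dependent dropout, planted housekeeping /
tissue-enriched / tumor-regulated proteins and planted low-quality outlier
samples — with machine-readable ground truth, so every stage can be
validated against a known answer.

Statistical core, in the usual notation: for protein *i* and groups *a*, *b*
of log2 intensities,
log2FC = x̄ₐ − x̄_b, Welch's t = log2FC / √(s²ₐ/nₐ + s²_b/n_b) with
Satterthwaite degrees of freedom, two-sided p-values adjusted per family by
the Benjamini–Hochberg step-up rule p₍ₖ₎ → minⱼ≥ₖ (m·p₍ⱼ₎/j). CV = 100·s/x̄
on the raw intensity scale.

## Worked example

```python
from panproteo import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir="results/demo", seed=1)
summary = run_pipeline(config)
print(summary["stages"]["qc"]["n_disqualified"],
      summary["stages"]["quant_filter"]["n_retained"],
      summary["stages"]["housekeeping"]["n_housekeeping"],
      summary["stages"]["enrichment"]["n_enriched"])
```

prints

```
4 1988 1440 100
```

— on the default simulated cohort (2000 proteins; 16 tissue types sized like
a real pan-cancer design, 246 samples; 4 planted outlier samples) the four
planted outliers are the only disqualified samples, 1988 proteins pass the
40% quantifiability rule, 1440 are universal in both arms (the 200 planted
housekeeping proteins plus high-abundance proteins that dropout rarely
touches — the rule counts presence, not planting), and 100 proteins come out
tissue-enriched. The same run writes per-stage TSVs (`qc_report.tsv`,
`imputed.tsv`, `enrichment.tsv`, `differential.tsv`, ...) and a
`run_summary.json` that is byte-identical across runs with the same seed.

The same stages are available as subcommands of the `panproteo` console
script (`simulate`, `qc`, `filter-impute`, `housekeeping`, `enrich`,
`diffexp`, `aggregate`, `cluster`, `annotate`, `run-all`), e.g.

```
panproteo simulate --out cohort/ --seed 1
panproteo qc --matrix cohort/matrix.tsv --metadata cohort/metadata.tsv --out qc.tsv
```

### Annotation table contract

Tab-delimited with a `protein_id` column plus any of the boolean columns
`is_drug_target`, `is_fda_approved_target`, `is_ct_antigen`,
`is_driver_gene`, `is_hpa_housekeeping` and an optional free-text `drugs`
column. Ids must live in the quantification matrix's id space; gene-symbol
mapping is up to the caller.

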