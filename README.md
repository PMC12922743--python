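# enzfam

Pan-cancer **enzyme-family driver analysis**: are somatic mutations enriched
in particular enzyme families (helicases, nucleases, kinases, …) beyond what
gene number and gene length predict — and which genes drive cancer through
*hemizygous* loss of an essential gene rather than classical two-hit
inactivation?

The package is aimed at cancer-genomics analysts working with cohort-level
somatic calls (mutation tables, copy-number segments, SVs, signature
exposures, dependency screens).  It provides, as a tested library plus CLI:

- **Family enrichment** — per cancer type, the number of genes in a family
  recurrently mutated (deleterious variant in ≥2 patients) versus a null of
  gene sets matched in count and within ±5% of total genomic coverage
  (10,000 permutations).  Effect size SMD = (obs − μ_null)/σ_null, empirical
  p = (r+1)/(n+1), Fisher combination X = −2Σln p ~ χ²(2k) across cancer
  types, 5th/95th SMD percentiles as the effect range.
- **Curveball randomization** of the patient×gene binary matrix — uniform
  over matrices with fixed row/column sums, as a background model for
  co-mutation analyses.
- **Mutant status** — three-rule gene annotation (nonsynonymous SNV;
  copy-number loss over ≥50% of the gene body; SV breakend in the gene),
  zygosity calls, genotype-group assignment, co-occurrence tests.
- **Genome instability** — WGII (per-chromosome aberrant fraction, averaged
  across chromosomes) in allele-specific and logR dialects, plus
  CNA-burden categories.
- **SV/indel features** — deletion/duplication size spectra, breakpoint
  homology bins, indel classes (1 / 2–4 / 5+ nt), exposure normalization,
  and group-association regression.
- **Hemizygous-driver classifier** — essential (dependency < −1) ×
  recurrently focally mutated × depleted for biallelic inactivation, with
  quadrant summaries and family enrichment among drivers.
- **Screen scoring** — per-plate γH2AX positivity thresholds, SSMD effect
  sizes, replicate-combined hit calling.
- **Expression–mutation model** — hurdle regression of length-normalized
  deleterious mutation rate on expression, BH-adjusted per gene class.
- **Synthetic cohorts** — seeded generators for every input with planted
  effects, so each stage is testable against a known truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Plant a 5× deleterious-mutation-rate multiplier on helicases in a synthetic
cohort of 1000 genes × 200 patients, then ask which family is enriched:

```python
import numpy as np
from enzfam.simulate import CohortSpec, simulate_gene_universe, simulate_mutations
from enzfam.enrichment import family_enrichment_analysis

spec = CohortSpec(n_genes=1000, n_patients=200, seed=7,
                  planted_family="helicase", rate_multiplier=5.0)
universe = simulate_gene_universe(spec)
events = simulate_mutations(universe, spec)

summaries = family_enrichment_analysis(
    {"cohort": events}, universe, np.random.default_rng(7), n_perm=1000
)
for s in sorted(summaries, key=lambda s: s.combined_p)[:4]:
    r = s.per_type[0]
    print(f"{s.family:<18} observed={r.observed_count:>3}  "
          f"null={r.perm_mean:5.2f}±{r.perm_sd:4.2f}  "
          f"SMD={s.mean_smd:6.2f}  p={s.combined_p:.4g}")
```

```
helicase           observed= 34  null= 7.00±2.37  SMD= 11.39  p=0.000999
glycosidase        observed= 13  null=10.22±2.62  SMD=  1.06  p=0.1978
oxidoreductase     observed=  9  null= 7.69±2.34  SMD=  0.56  p=0.3586
kinase             observed=  7  null= 7.43±2.40  SMD= -0.18  p=0.6334
```

34 helicase genes are recurrently mutated where coverage-matched random gene
sets average 7.0 ± 2.4 — an SMD of 11.4, with the empirical p at its floor
(1/1001, nothing in 1000 permutations reached the observed count).  The
unplanted families sit where the null puts them.

The same analysis runs from the shell on TSV inputs:

```bash
enzfam enrich --mutations mutations.tsv --genes genes.tsv \
              --n-perm 10000 --seed 7 --out families.tsv
```

and `enzfam run --config config.yaml --out-dir out/` drives the full
simulate → enrich → status → wgii → svfeat → classify → screen pipeline with
a manifest of every seed and threshold used.

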