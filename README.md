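# biphase

Phase-aware compound-heterozygosity analysis for phased cohort data.

Two damaging variants in one gene disrupt both gene copies only when they
sit on opposite haplotypes (*in trans*, compound heterozygous) — the same
pair *in cis* leaves one intact copy. Analyses that ignore phase cannot
tell these apart, and most recessive-acting bi-allelic carriers in an
outbred population are compound heterozygotes whose constituent variants
are individually rare. `biphase` is a pipeline for researchers who have
statistically phased genotypes (with per-genotype phasing-confidence
scores) and want to go from there to phase-aware gene-trait association:

- **Phasing QC** — trio transmission phasing, switch-error rates (SER) by
  minor-allele-count bin with Wilson confidence intervals, pairwise phase
  concordance between independent phase assignments.
- **Carrier calling** — per (sample, gene) classification into
  WT / het / multi-hit *cis* / CH / homozygous under consequence masks
  (pLoF, damaging missense) with MAF ≤ 5% and phasing confidence
  PP ≥ 0.9 filters; recessive 0/2 and additive 0/1/2 encodings,
  serializable as pseudo-variant VCFs.
- **Association** — covariate-adjusted logistic score test with a
  conditional saddlepoint tail correction for extreme case-control
  imbalance; recessive and additive scans with carrier-count floors
  (≥5 bi-allelic carriers, ≥10 disrupted haplotypes) and Bonferroni
  thresholds; conditioning on polygenic scores, iteratively selected
  nearby common variants, and rare/ultra-rare burden.
- **Phase permutation** — the empirical null obtained by shuffling CH/cis
  labels among multi-variant carriers:
  `p = (1/n) Σ I(t_i ≥ t_observed)`.
- **Age at onset** — Cox proportional-hazards contrasts of carrier classes
  with left truncation, and Kaplan-Meier curves.
- **Enrichment & power** — Poisson regression of per-gene bi-allelic
  counts on gene-set membership with a mutation-rate covariate; analytic
  and Monte-Carlo expected CH/homozygote counts under Hardy-Weinberg;
  down-sampling curves; minimal detectable odds ratio at a target power.
- **Synthetic cohorts** — a generator for phased diploid cohorts with
  trios, MAC-dependent planted phase errors carrying PP scores, and
  liability-threshold phenotypes with spike-and-slab recessive gene
  effects (`y_i = Σ_j B_ij θ_j + ε_i`, causal genes with probability π_θ).

## Worked example

Simulate a phased cohort of 2,000 samples over 40 genes, plant phase
errors at a 32.4% singleton switch rate, and measure what survives the
PP ≥ 0.9 filter:

```python
import biphase as bp
from biphase.phase_eval import switch_error_rate

cfg = bp.CohortConfig(n_samples=2000, n_genes=40, n_trios=20, seed=7)
truth = bp.simulate_haplotypes(cfg)
noisy = bp.inject_phase_errors(
    truth, ser_by_mac={"1": 0.324, "2-5": 0.02, "6-10": 0.005, "11+": 0.002},
    seed=8,
)
ser = switch_error_rate(
    noisy.haplotypes, noisy.truth_haplotypes,
    noisy.variants["mac"].to_numpy(), pp=noisy.pp, pp_threshold=0.9,
)
print(ser.to_string(index=False))
```

```
mac_bin  n_switches  n_comparisons      ser   ci_low  ci_high
      1           4             85 0.047059 0.018450 0.114837
    2-5           2            946 0.002114 0.000580 0.007676
   6-10           0            674 0.000000 0.000000 0.005667
    11+          13          21896 0.000594 0.000347 0.001016
    all          19          23601 0.000805 0.000515 0.001257
```

Filtering at PP ≥ 0.9 removed most planted singleton errors (4.7%
residual SER against 32.4% injected). Classify carriers and run the
recessive scan on a liability-threshold trait driven by bi-allelic
carriers:

```python
import pandas as pd

mask = bp.VariantMask()  # pLoF + damaging missense, MAF <= 5%, PP >= 0.9
carriers = bp.classify_carriers(noisy, mask)
cm = bp.CarrierMatrix.from_binary(carriers.biallelic().astype(int),
                                  genes=carriers.genes)
sim = bp.simulate_liability_phenotype(
    cm, bp.LiabilityConfig(h2=0.05, b=2.0, pi_theta=0.25,
                           prevalence=0.10, seed=10),
)
enc = bp.encode(carriers)
pheno = pd.DataFrame({"sample_id": noisy.samples["sample_id"],
                      "trait_1": sim["phenotype"]})
res = bp.run_recessive_scan(enc, pheno, ["trait_1"])
print(res.nsmallest(3, "p_value")[
    ["gene", "trait", "p_value", "n_biallelic_cases", "n_biallelic_controls"]
].to_string(index=False))
```

```
    gene   trait      p_value  n_biallelic_cases  n_biallelic_controls
GENE0013 trait_1 3.118424e-07                  6                     0
GENE0017 trait_1 3.840282e-06                  5                     0
GENE0021 trait_1 4.590174e-01                  0                     6
```

The two top genes are planted causal genes (the simulation drew
`GENE0008`, `GENE0013`, `GENE0017` as causal); `GENE0013` reaches
6 bi-allelic carriers, all cases, and its saddlepoint-corrected p-value
(3.1×10⁻⁷) sits far below the grid's Bonferroni threshold of 0.01
(0.05 / 5 eligible genes × 1 trait).

A full end-to-end run on a bundled synthetic cohort — phased VCF out,
carrier calling, both scans, phase permutation and Cox contrasts back —
is available from the shell:

```sh
chpipe demo --seed 7 --out demo/
```

`chpipe call`, `chpipe assoc`, `chpipe trio-ser`, `chpipe perm`,
`chpipe enrich` and `chpipe surv` expose the individual stages over the
same plain-text interfaces; `chpipe run --config run.yaml` drives them
from a config file.

## Layout

```
src/biphase/
  cohort.py        synthetic phased cohorts, phase errors, phenotypes
  phase_eval.py    trio phasing, switch errors, concordance
  caller.py        carrier classification and encodings
  assoc.py         score test, saddlepoint, scans, conditioning
  permutation.py   phase-label permutation null
  enrichment.py    gene-set enrichment, expectations, power
  survival.py      Cox contrasts and Kaplan-Meier
  vcfio.py         phased VCF / TSV / pedigree interchange
  pipeline.py      stage orchestration and the bundled demo
  cli.py           the `chpipe` command line
docs/methods.md    model assumptions, parameter choices, limitations
```
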