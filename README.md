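# ewaskit

A longitudinal epigenome-wide association (EWAS) pipeline for DNA
methylation arrays, built around the analysis design of case-control
psychiatric-epigenetics studies with treatment follow-up: patients with
anxiety disorders sampled at baseline (T0), post-treatment (T1) and
6-month follow-up (T2) against a matched healthy control group, with
treatment response defined as a ≥ 50% decrease in the Hamilton Anxiety
Rating Scale (HAM-A) score.

Because raw cohort data of such studies is rarely deposited, `ewaskit`
ships a first-class synthetic-data generator that emulates an EPIC-like
array cohort with known ground truth — beta-distributed methylation,
six-cell-type leukocyte mixtures, batch and per-array technical structure
expressed in control probes, sex-chromosome signal, spiked effects for
every association design, HAM-A trajectories with a responder
subpopulation, and deliberately planted quality-control violators — so
the entire pipeline is testable end to end.

## What it does

1. **Sample QC** — exclude samples with probe call rate < 0.95, ≥ 5% of
   probes lacking signal, reported/predicted sex mismatch, or per-class
   control-probe outliers (median ± 4 robust SDs).
2. **Probe filtering** — drop CpGs with a SNP within 5 bp at
   MAF ≥ 0.01, cross-reactive probes, and control probes; the surviving
   count sets the Bonferroni threshold `α / n` (0.05 over 780,145 probes
   gives the canonical 6.409E−08).
3. **Adjustment** — beta → M values (`M = log2(β/(1−β))`, clipped), the
   first ten principal components of the control probes plus
   Houseman-style constrained-projection cell fractions
   (CD8T/CD4T/NK/B/Mono/Gran) as technical covariates, residualized per
   probe.
4. **Association designs** — (a) baseline case-control Welch t-test on
   adjusted M values with Δβ effect sizes and a post-hoc comorbid
   depression adjustment; (b) logistic treatment-response prediction
   from baseline methylation (plus a continuous %-HAM-A-change variant);
   (c) within-patient longitudinal change tested by a one-sample t-test,
   stratified by responder status; (d) a robust (Huber) smoking EWAS on
   beta values inside the patient group, with a hypergeometric overlap
   test against the case-control hits.
5. **Diagnostics & reporting** — genomic inflation factor λ, QQ-plot
   data, significant (`p ≤ α/n`) / suggestive (`p < 1E−5`) tiers,
   nearest-gene annotation, Manhattan-plot tables, and a run summary
   with content hashes.

## Worked example

```python
from ewaskit.pipeline import RunConfig, run_pipeline
from ewaskit.data import EffectSpec
from ewaskit.synthdata import generate_manifest, spikeable_probes
from ewaskit.pipeline import stage_seed, STAGE_SIMULATE_MANIFEST

man = generate_manifest(5000, 300, 100, 0.02, 0.05,
                        seed=stage_seed(2, STAGE_SIMULATE_MANIFEST))
targets = spikeable_probes(man, 5)   # filter-safe autosomal probes
cfg = RunConfig(seed=2, n_probes=5000, n_patients=100, n_controls=100,
                effects=EffectSpec(cc_spiked=[(t, 0.10) for t in targets]),
                designs=("case_control",))
summary = run_pipeline(cfg, "runs/demo")
print(summary["n_evaluated_probes"], summary["bonferroni_threshold"])
print(summary["designs"]["case_control"])
```

prints

```
4650 1.0752688172043012e-05
{'n_used': 200, 'n_probes': 4650, 'lambda': 1.0211217514783484,
 'n_significant': 5, 'n_suggestive': 0, 'n_flagged': 0,
 'posthoc_remained_significant': 5}
```

i.e. 4,650 CpGs survive probe filtering, so genome-wide significance for
this run is `0.05/4650 ≈ 1.08E−05`; exactly the five probes spiked with a
0.10 beta-value group difference reach it (and survive the post-hoc
depression adjustment), the genomic inflation factor of the remaining
null background is ≈ 1.03, and no sample failed QC.

The same run from a shell:

```sh
ewaskit run-all --seed 2 --out runs/demo        # or --config cfg.yaml
ewaskit report --run runs/demo --table ewas_case_control
```

Stage-by-stage commands (`simulate`, `qc`, `filter`, `preprocess`,
`ewas --design …`, `report`) operate on the same run directory; the
configuration is a flat YAML file mirroring `RunConfig` (see
`runs/demo/config.yaml` for the echoed dialect).

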