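# megapath

Integrated literature-network + expression **mega-analysis** for connecting a
driver gene to a disease. The motivating application is the protective role
of the transcription factor PPARG in myocardial infarction (MI): candidate
genes linking PPARG to MI are mined from a literature-derived relation
network, their expression change is pooled across eight independent
case/control microarray cohorts, and the surviving polarity-consistent genes
are profiled by gene-set over-representation.

The package is a library first (`import megapath`), with narrative scripts
under `examples/` and a thin `megapath` CLI for configured end-to-end runs.

## What it computes

**Per-study effect size.** For gene *g* in study *i*, the log2 fold-change
*y<sub>gi</sub>* = mean(case) − mean(control) on the log2 scale, with
Welch-style sampling variance *v<sub>gi</sub>* = s²₁/n₁ + s²₂/n₂.

**Pooling with model selection.** With inverse-variance weights
*w<sub>i</sub>* = 1/*v<sub>i</sub>*:

- fixed effects: ŷ<sub>F</sub> = Σw<sub>i</sub>y<sub>i</sub> / Σw<sub>i</sub>, se = (Σw<sub>i</sub>)^(−1/2);
- heterogeneity: Q = Σw<sub>i</sub>(y<sub>i</sub> − ŷ<sub>F</sub>)², df = k−1,
  I² = max(0, 100·(Q − df)/Q), p<sub>Q</sub> from χ²(df);
- random effects (DerSimonian–Laird): τ² = max(0, (Q − df)/(Σw − Σw²/Σw)),
  re-weighting by 1/(v<sub>i</sub> + τ²).

When Q ≤ df (equivalently I² = 0) the fixed-effects model is selected,
otherwise the random-effects model; two-sided p-values use z = ŷ/se. A
significance-based alternative rule (fixed iff p<sub>Q</sub> > threshold) is
available via `het_p_threshold`.

**Network filtering.** Literature edges give two candidate sets: genes
promoted by the driver that inhibit the disease, and genes regulated
contra-directionally by driver and disease. A candidate survives iff its
pooled p < α (default 0.05) and its sign matches the literature polarity
(promoted inhibitors and contra-down genes must fall, contra-up genes must
rise).

**Covariate influence.** Per gene, the study-level effects are regressed on
total sample size, study age and country (dummy-coded); partial F-tests give
one p-value per factor, with automatic model reduction when the handful of
studies cannot support the full design.

**Enrichment.** Hypergeometric upper-tail p against a GMT collection,
Benjamini–Hochberg q across all sets, and Jaccard similarity
|A∩B| / |A∪B| between query and set.

## Worked example

```python
from megapath import candidate_sets, classify_network
from megapath.synthetic import DRIVER, DISEASE, generate_relations, table_meta_results

cands = candidate_sets(generate_relations(), DRIVER, DISEASE)
network = classify_network(cands, table_meta_results(), alpha=0.05)
for n in network:
    print(f"{n.gene:8s} {n.category.value:24s} {n.lfc:+.2f} {n.p_value:.2g}")
```

prints

```
ACADM    contra_down              -0.32 0.0034
ADIPOR2  contra_down              -0.16 0.031
ALB      contra_down              -1.35 0.005
CAV1     promoted_inhibitor_down  -0.24 0.005
MYD88    contra_up                +0.23 0.047
POU5F1   promoted_inhibitor_down  -0.23 0.041
RELA     contra_up                +0.28 0.008
SOD1     promoted_inhibitor_down  -0.28 0.048
```

— the eight genes connecting PPARG to MI: three MI inhibitors promoted by
PPARG and down-regulated in patients, three PPARG-promoted / MI-suppressed
targets that fall with the driver, and two PPARG-suppressed targets that rise
in disease. Decoy candidates are dropped for failing significance, pointing
the wrong way, or never being measured. See `examples/` for pooling,
simulation-and-recovery, enrichment and full-pipeline walk-throughs.

### CLI

```bash
megapath simulate --seed 5 --out bundle/          # synthetic 8-study bundle
megapath run --config run.yaml                    # ingest → ... → enrichment
megapath enrich --query genes.txt --gmt sets.gmt  # one-off over-representation
```

`megapath run` writes `effects.tsv`, `meta.tsv`, `network.tsv`,
`influence.tsv`, `enrichment.tsv` and a `run_manifest.json` that fully
determines the run; reruns are byte-identical.

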