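# transportome

Compositional and energetic analysis of cellular transportomes — the full
complement of membrane transporter proteins encoded by a genome — across
the domains of life.

Membrane transporters fall into three functional classes with very
different running costs: **ATP-dependent (primary active) transporters**
(ADT; the ABC superfamily, P-type ATPases, protein translocases) hydrolyse
roughly 2 ATP per substrate translocated, **secondary transporters** (ST;
carriers driven by ion electrochemical gradients or simple facilitated
diffusion) dissipate gradients worth at most ≈ 0.5 ATP equivalents per
event, and **ion channels** (IC) translocate for free. The composition of
a transportome therefore fixes an average price per transport event — the
**energy-usage efficiency**

```
EUE = (2 · %ADT + 0.5 · %ST + 0 · %IC) / 100        [ATP per transport event]
```

and comparing group means gives the inter-group matrix

```
ΔEUE(row, col) = EUE_row − EUE_col
```

where negative entries mean the row group runs the cheaper transportome.
EUE is a property of composition only: expression and flux do not enter,
so it is immune to spatiotemporal variation. The F/V/A-type ATPases and
ATP synthases are excluded from the ADT tally throughout — they *generate*
the ATP and membrane potential the other transporters spend.

The package is aimed at comparative genomicists working from per-species
transporter annotation tables (TransportDB-style output). It provides:

* **ingest** — deterministic re-implementations of the standard curation
  steps: drop proteins < 100 aa, resolve multi-prediction hits and
  alternative isoforms, and collapse operon-encoded multi-subunit
  ATP-dependent systems (prokaryotic ABC importers) into single
  transporters;
* **composition** — per-species class fractions and intra-genomic
  frequencies (class count / total genes), group means with t-based 99%
  confidence intervals, Student's t-tests with an arcsin-√ robustness
  check, Pearson correlations;
* **eue** — the EUE statistic and the ΔEUE matrix, with configurable cost
  coefficients;
* **family_sets** — family × group presence/absence matrices,
  prokaryote/eukaryote specificity partitions (families lost or newly
  emerged across the prokaryote→eukaryote transition) and single-family
  marker screens (e.g. scanning prokaryotes for mitochondrial carrier /
  SLC25 homologues, candidate relatives of the mitochondrial ancestor);
* **synthetic** — a seeded generator producing study-like six-group
  datasets with planted ground truth (Dirichlet class compositions,
  group-restricted family pools, injected annotation artifacts), plus
  analytic recovery tolerances and a recovery report.

## Worked example

Simulate a six-group dataset (10 species per group, annotation artifacts
injected) and run the full analysis:

```python
from transportome import RunConfig, paper_like_specs, run_pipeline, simulate_dataset

ds = simulate_dataset(paper_like_specs(n_species=10), seed=4)
res = run_pipeline(RunConfig(annotations="", metadata="", out_dir="demo"),
                   annotations=ds.annotations, metadata=ds.metadata)
for g, v in res.eue_result.group_mean_eue.items():
    s = next(x for x in res.summaries if x.group_label == g)
    print(f"{g:22s} ADT {s.mean['adt']:5.1f}%  ST {s.mean['st']:5.1f}%  "
          f"IC {s.mean['ic']:5.1f}%   EUE {v:.3f}")
```

prints (36,793 raw records → 60 curated transportomes):

```
bacteria               ADT  29.4%  ST  64.7%  IC   5.8%   EUE 0.912
archaea                ADT  29.0%  ST  62.9%  IC   8.1%   EUE 0.894
primitive_eukaryotes   ADT  20.9%  ST  65.8%  IC  13.3%   EUE 0.746
algae_plants           ADT  14.0%  ST  72.9%  IC  13.0%   EUE 0.645
fungi                  ADT   9.9%  ST  81.6%  IC   8.4%   EUE 0.607
animals                ADT   5.2%  ST  65.1%  IC  29.7%   EUE 0.430
```

The ATP-dependent share shrinks from ~29% in prokaryotes to ~5% in
animals while channels grow to ~30%: per transport event, the animal
transportome costs about 0.48 ATP less than the bacterial one, as the
written `eue_matrix.tsv` shows (`demo/` also receives the composition
tables, group summaries, t-tests, presence matrix, specificity partitions,
marker screen, audit log and a JSON summary):

```
                      bacteria  archaea  prim_euk  algae_plants  fungi  animals
bacteria                  0.00
archaea                  -0.02     0.00
primitive_eukaryotes     -0.17    -0.15      0.00
algae_plants             -0.27    -0.25     -0.10        0.00
fungi                    -0.31    -0.29     -0.14       -0.04    0.00
animals                  -0.48    -0.46     -0.32       -0.21   -0.18     0.00
```

The secondary-transporter specificity partition recovers the planted
family sets exactly (8 prokaryote-only, 6 eukaryote-only, 12 shared), and
the marker screen returns exactly the bacterial species carrying the
planted mitochondrial-carrier homologues.

The same analysis is available from the shell:

```bash
transportome simulate --out data --seed 4 --species-per-group 10
transportome run --annotations data/annotations.tsv \
                 --metadata data/species_meta.tsv --out demo
```

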