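# tmegraph

Bi-level graph analysis of the tumor microenvironment (TME) for spatial
single-cell data (IMC, CODEX, MIBI, mIHC).  Given per-cell tables with
positions and phenotypes, `tmegraph` discovers recurring local cellular
patterns, stratifies patients into subgroups with distinct prognoses, and
projects external cohorts onto the discovered structure — all without using
survival labels during discovery.

## The model

**Cellular graph.**  Each patient's tissue is a complete weighted graph over
their cells.  The edge weight between cells *v<sub>i</sub>*, *v<sub>j</sub>*
at Euclidean centroid distance *d* (µm) is a Gaussian kernel

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>ij</sub>* = exp(−α · d(v<sub>i</sub>, v<sub>j</sub>)²),&nbsp;&nbsp; α = 0.01,

so cells within 3 µm connect strongly (*w* > 0.9) and cells beyond 22 µm
only weakly (*w* < 0.01).  Multiple tissue cores of one patient enter as
disconnected components.

**Soft-WL subtree kernel.**  Every cell roots a depth-*h* subtree summarized
by *h* graph-convolution sweeps of the one-hot phenotype matrix,
*x(h)* = A<sup>h</sup> *x(0)* (self-loops of weight 1; default *h* = 2).
Subtrees pooled over the discovery cohort are clustered PhenoGraph-style
(exact *k*-NN graph with *k* = 100, Jaccard edge reweighting, Louvain) into
TME patterns; each pattern's signature S(c) is the mean embedding of its
members, and is categorized as a tumor / immune / stromal / interface niche.
A patient is the histogram φ(G) of pattern memberships over their cells, and
patient similarity is the cosine

&nbsp;&nbsp;&nbsp;&nbsp;κ(G<sub>i</sub>, G<sub>j</sub>) = ⟨φ(G<sub>i</sub>), φ(G<sub>j</sub>)⟩ / (‖φ(G<sub>i</sub>)‖₂ ‖φ(G<sub>j</sub>)‖₂) ∈ [0, 1].

**Population graph and subgroups.**  The kernel matrix is preprocessed by
replacing each edge with the intersection-over-union of the endpoints'
*k*★-NN sets (*k*★ = 30), then Louvain community detection yields patient
subgroups.  Per subgroup, a Cox proportional-hazards fit of the in/out
indicator gives a hazard ratio against the rest of the cohort; survival
curves are compared by the G-sample log-rank test.  Patterns whose
Hodges-Lehmann statistic (median of all pairwise in-group minus out-group
proportion differences) exceeds half the subgroup maximum are reported as
*characteristic* of that subgroup; a 1 % proportion threshold stratifies
patients as positive/negative for any pattern.

**Cohort mapping.**  External cohorts are projected at three levels:
cells to the nearest discovery phenotype centroid over shared antigens,
subtrees to the nearest pattern signature, and patients to subgroups by a
similarity-weighted vote among their 3 most similar discovery patients.

Comparator representations (phenotype abundance, mean pairwise phenotype
proximity, niche-category abundance, and the classic WL subtree kernel on
graphs binarized at weight 0.01 ≈ 21 µm) share the identical downstream
pipeline.

## Worked example

The package ships a synthetic-cohort generator that plants niche
archetypes, subgroup mixture profiles, and subgroup-linked exponential
survival, so the full pipeline runs without any downloads:

```python
from tmegraph import RunConfig, SimConfig, fit_discovery, simulate_cohort

sim = simulate_cohort(SimConfig(seed=0))          # 60 patients, 3 subgroups
fit = fit_discovery(sim.cells, sim.clinical,
                    RunConfig(min_cells=1, random_seed=0))

print(f"patterns discovered: {fit.model.n_patterns}")
print(f"subgroup sizes:      {fit.subgroups.value_counts().sort_index().to_dict()}")
chi2, df, p = fit.logrank
print(f"log-rank: chi2={chi2:.2f}, df={df}, p={p:.2e}")
print(fit.survival_report[["n", "hr", "ci_low", "ci_high", "p"]].round(3))
```

prints

```
patterns discovered: 10
subgroup sizes:      {1: 20, 2: 20, 3: 20}
log-rank: chi2=17.72, df=2, p=1.42e-04
           n     hr  ci_low  ci_high      p
subgroup
1         20  3.046   1.583    5.863  0.001
2         20  1.257   0.649    2.437  0.502
3         20  0.204   0.083    0.501  0.000
```

The ten discovered patterns are the three planted niche archetypes plus the
isolated-background cells (one low-mass pattern per phenotype).  The three
detected subgroups match the planted ones (adjusted Rand index 0.90 here),
and their hazard ratios recover the planted risk ordering: subgroup 1
(hazard 0.08/month) is high-risk (hr ≈ 3.0), subgroup 3 (hazard
0.01/month) is protective (hr ≈ 0.2), and the log-rank test rejects equal
survival at p ≈ 1.4 × 10⁻⁴.

The same workflow is available from the shell:

```bash
tmegraph simulate --seed 0 --out cohort/
tmegraph fit --cells cohort/cells.csv --clinical cohort/clinical.csv \
             --vocabulary cohort/vocabulary.tsv --min-cells 1 --seed 0 --out model/
tmegraph map --cells external.csv --model model/ --out mapped/
tmegraph compare --cells cohort/cells.csv --scheme cell_abundance --out abundance/
```

Real cohorts are read with `read_cell_table` / `read_clinical_table`
(CSV/TSV, configurable column names); the default 500-cell patient filter
then applies.

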