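# multicom

Multilayer network community detection with a resolution sweep,
persistence-module extraction, and randomization-based significance
testing — a reusable pipeline for explaining phenotypic severity in
small, deeply phenotyped rare-disease cohorts.

## The problem

A cohort of patients shares one causal mutation but differs widely in
disease severity. A natural hypothesis is that additional variant genes
(compound-heterozygous hits, copy-number variants) modify the phenotype
through the molecular neighborhood of the known causal genes. To test
this, gene relations from several sources — protein–protein
interactions, shared pathway membership, shared reaction metabolites —
are stacked as layers of a **multilayer network** over the union of their
node sets, and clustered with a single common partition.

## The model

A partition $P$ of the node universe is scored by the sum over layers of
resolution-parametrized Newman–Girvan modularity:

$$Q(P;\gamma)\;=\;\sum_{\ell=1}^{L}\sum_{c\in P}\left[\frac{w_c^{(\ell)}}{W_\ell}\;-\;\gamma\left(\frac{d_c^{(\ell)}}{2W_\ell}\right)^{2}\right]$$

where $w_c^{(\ell)}$ is the intra-community edge weight of community $c$
in layer $\ell$, $d_c^{(\ell)}$ the total degree of its nodes there, and
$W_\ell$ the layer's total edge weight. $Q$ is maximized by a seeded
generalized Louvain algorithm (local moving from singletons, then
condensation, repeated to convergence). The resolution $\gamma$ scales
the null term: larger $\gamma$ yields smaller communities.

Because no single $\gamma$ is privileged, the pipeline sweeps a grid of
resolutions (default: 8 values covering $(0,4]$) and asks which genes of
interest are *persistently* co-clustered. A **module** is a connected
component (of size ≥ 2) of the graph connecting gene pairs co-clustered
at ≥ *n* of the grid values; at *n* = 8 its genes share a community over
the entire range. Its **persistent core** is the set of all network
nodes (not only genes of interest) that stay in the module's community
at every resolution.

Significance comes from two permutation procedures:

* **catalog validation** — are disease-associated gene sets co-clustered
  more than size-matched random sets ("balanced" randomizations)?
  Scored by a size-stratified one-sided rank-sum test per resolution.
* **severity-label shuffling** — severity labels are permuted among
  patients (class sizes preserved), group-private gene sets rebuilt, and
  the size of the largest causal-anchored module recorded. Add-one
  permutation p-values per candidate size, Benjamini–Hochberg adjusted,
  give the minimum module size not expected at random.

Clinical/treatment variables are scanned with two-tailed Fisher exact
tests, BH-adjusted.

## Worked example

Everything runs on synthetic data with planted structure — no downloads.
Generate a workspace (3 layers over 90 genes in 3 planted communities;
a 20-patient cohort, 8 severe / 12 not-severe, whose severe patients
carry community-coherent private variant genes) and run the pipeline:

```bash
multicom simulate --outdir ws --seed 1 --k-background 0
cat > config.yaml <<'YAML'
layers:
  - {name: layer0, path: ws/layer0.tsv, nodes: ws/layer0.nodes.txt}
  - {name: layer1, path: ws/layer1.tsv, nodes: ws/layer1.nodes.txt}
  - {name: layer2, path: ws/layer2.tsv, nodes: ws/layer2.nodes.txt}
causal_genes: ws/causal_genes.txt
cohort: ws/cohort.tsv
outdir: out
seed: 1
n: 4            # persistence threshold (grid values a pair must share)
shuffle_R: 1000
YAML
multicom run config.yaml
```

`out/significance.json` then reports (actual output of this run):

```
observed largest anchored module size:  severe 24, not_severe 3
severe k_min: 15   (p_adjusted: 15 -> 0.0299, 14 -> 0.0501, 13 -> 0.0766)
```

The severe group's private variant genes form a 24-gene module anchored
on the known causal genes; under 1000 severity-label shuffles, 15 is the
minimum module size not expected at random at α = 0.05 — the planted
severe-specific signal is recovered and sized. The sweep manifest
(`out/sweep/manifest.json`) records per-resolution modularity and
community counts (here 3 communities and ARI 1.0 versus the planted
truth for γ ≤ 2, with communities splitting at higher resolution as
modularity maximization dictates). Adding `catalog: ws/catalog.gmt`
validates a disease→genes catalog: with fully community-coherent sets
the per-resolution stratified rank-sum p-values fall below 1e-20.

The same operations are available as library functions
(`multicom.sweep`, `multicom.extract_modules`,
`multicom.label_shuffle_null`, ...) and as CLI subcommands (`simulate`,
`detect`, `sweep`, `modules`, `validate-catalog`, `validate-cohort`,
`assoc`, `similarity`, `run`).

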