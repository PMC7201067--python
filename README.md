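# atlasrules

Tissue-specific marker-gene selection and expression-rule induction for
single-cell transcriptomic atlas data.

## The problem

Given a cell × gene expression matrix in which every cell carries a
tissue label (the motivating dataset is a mouse atlas of 53,760 cells
from 18 tissues, 23,433 genes), find the genes whose expression patterns
distinguish the tissues, and distill those patterns into human-readable
IF–THEN rules.  The package implements the full multi-stage cascade:

1. **MI screen** — every gene is scored by the plug-in mutual
   information *I(x; y)* between its discretised expression *x*
   (equal-frequency bins) and the tissue label *y*; genes with
   *I* > 0.02 bits survive.
2. **Boruta** — all-relevant selection: each gene competes against
   "shadow" copies of all genes (values permuted across cells) inside a
   random-forest importance; genes that repeatedly beat the best shadow
   are confirmed, resolved by binomial tests on hit counts.
3. **Two rankings** of the confirmed pool:
   * **mRMR** (difference form): greedily append the gene maximising
     MI(gene; label) − mean MI(gene; already-selected) — the list *F_m*;
   * **MCFS**: grow *m*×*t* decision trees on bootstrap × random-subset
     combinations and rank genes by relative importance
     RI_f = Σ_τ (wAcc)^u · IG(n_f(τ)) · (no. in n_f(τ) / no. in τ)^v —
     the list *F_M*.
4. **IFS** — incremental feature selection: evaluate top-*k* prefixes
   (k = 5, 10, …) of a ranking with a classifier under stratified
   10-fold cross-validation and pick the *k* maximising the multiclass
   Matthews correlation coefficient (the R_K correlation form).
5. **PART** — rule learning by repeated partial C4.5 trees and
   separate-and-conquer, producing an ordered rule set such as
   `IF Lgals7 > 2.5 AND Krt5 <= 1.2 THEN Skin`.
6. **Overlap statistics** — a hypergeometric upper-tail test of whether
   the two rankings' optimum gene sets agree more than chance.

A synthetic-atlas generator with planted, per-tissue marker genes (plus
dropout and a large uninformative background) provides ground truth for
recovery experiments; real data can be supplied as MatrixMarket or CSV.

## Worked example

```python
import atlasrules as ar
from atlasrules.mcfs import MCFSParams

# synthetic 18-tissue atlas at 2% of the published per-tissue sizes:
# 1,085 cells, 90 planted markers (5 per tissue) + 400 noise genes
spec = ar.scaled_atlas_spec(scale=0.02, seed=101)
ds, truth = ar.generate_dataset(spec)

mi = ar.mi_screen(ds, threshold=0.02, bins=5)
boruta = ar.run_boruta(ds, features=mi.surviving, max_iter=50, seed=202)
ranking = ar.run_mcfs(ds, features=boruta.confirmed,
                      params=MCFSParams(seed=303))
curve = ar.run_ifs(ds, ranking, ar.ClassifierSpec(seed=404),
                   step=5, max_k=len(ranking), folds=10, seed=404)

print(len(mi.surviving), boruta.confirmed.size,
      curve.optimum_k, round(curve.optimum_mcc, 3))
```

prints

```
389 89 80 0.694
```

meaning: 389 of 490 genes pass the MI screen, Boruta confirms 89 genes
(these turn out to be 89 of the 90 planted markers and zero noise
genes), and the IFS curve with a random forest peaks at the top 80 genes
with a cross-validated multiclass MCC of 0.694.  For reference, a forest
given all 90 true markers measures the same MCC (0.694) on this dataset
— the pipeline recovers essentially all of the signal the scaled-down
data contain; the residual gap to a full-size atlas comes from tissues
that keep only ~18–20 cells at this scale.

A complete configured run (both rankings, both classifiers, rule files,
overlap report, plots) is available via the CLI:

```sh
atlasrules pipeline run config.yaml
atlasrules pipeline report rundir/
```

with a YAML config such as

```yaml
out_dir: rundir
seed: 1
synthetic: {scale: 0.02}
ifs: {step: 5, max_k: 200, folds: 10}
```

Individual stages are also exposed (`atlasrules synth`, `mi-filter`,
`boruta`, `mrmr`, `mcfs`, `ifs`, `part`, `overlap`).

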