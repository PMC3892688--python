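# flystage

Automated developmental-stage annotation for standardized *Drosophila
melanogaster* embryo gene-expression images.

High-throughput in situ hybridization pipelines image embryos by the
hundred thousand, but the images are typically labelled only with coarse
stage *ranges* (e.g. 4–6), while comparative analysis of spatial
expression patterns is only meaningful between embryos at similar
developmental time.  `flystage` assigns each standardized image

* a specific stage **S ∈ {3,…,17}** (stages 1–3 collapse to one class —
  they differ only in nucleus count, invisible in whole-mount imagery),
* an early/late sub-stage **E/L** for stages 4–16,
* a continuous **stage score SS ∈ [S−½, S+½]** that orders embryos within
  a sub-stage, and a/b/c thirds derived from it,

and aggregates same-stage images into normalized expression-map
composites (GEMs) that visualize global gene activity across
developmental time.

## Method

Images (128 × 320, lateral view, anterior left) are filtered with a
log-Gabor bank — 4 scales × 6 orientations, transfer functions

&nbsp;&nbsp;&nbsp;&nbsp;G(r, θ) = exp(−log²(r/f₀) / 2 log²σ_f) · exp(−Δθ² / 2 σ_θ²)

— and each of the 24 response magnitudes is reduced by 8 × 8 block means
to 640 region values, giving a 15 360-dimensional texture feature vector
in which every image region owns a natural group of 24 features.

On these features a **pool of diverse linear classifiers** is trained:
7 algorithms (linear SVM; lasso, group lasso and sparse group lasso with
least-square and logistic losses, the group structure being the image
regions) × 5 training ratios (50–90%) × 30 stratified random partitions =
1050 one-vs-rest models, each solved by monotone FISTA (proximal gradient)
or dual coordinate descent (SVM).  Each member votes for one stage,
weighted by its validation accuracy aⁱ, producing a histogram H over
stages.  Then

* S = argmax H,
* sub-stage E iff H(S−1) > H(S+1),
* SS = S + ½·(H(S+1) − H(S−1)) / (H(S−1) + H(S+1)).

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

The package ships a synthetic-embryo generator whose texture frequency and
expression-band position both move monotonically with a latent
developmental time t, so the whole pipeline can be exercised without
external data:

```python
from flystage import synthetic, model
from flystage.ensemble import PoolSpec
from flystage.learners import SolverConfig

corpus = synthetic.generate(synthetic.SyntheticSpec(n_per_stage=8, seed=3))
spec = PoolSpec(training_ratios=(0.6, 0.8), n_partitions=2, master_seed=0)
m = model.StageAnnotationModel.from_images(
    corpus.images, corpus.stages, pool_spec=spec,
    solver_config=SolverConfig(max_iter=80, tol=1e-5))
res = m.fit()
print(res.summary())
```

```
Stage annotation ensemble
============================================================
pool members (active/planned) : 28/28
stage classes                 : 3..17 (15)
feature dimension             : 15360
training ratios               : 0.6, 0.8
partitions per ratio          : 2
master seed                   : 0
------------------------------------------------------------
algorithm                members   mean conf      sd
svm_hinge_l2                   4       0.839   0.009
lasso_ls                       4       0.812   0.033
lasso_logistic                 4       0.833   0.044
group_ls                       4       0.854   0.047
group_logistic                 4       0.859   0.027
sparse_group_ls                4       0.839   0.009
sparse_group_logistic          4       0.849   0.045
------------------------------------------------------------
pool overall                  28       0.841   0.037
```

Each row is one algorithm's members with their mean validation accuracy —
the confidence that weights their votes.  Annotating five mid-corpus
images (`res.annotate(...)`) prints

```
          image  stage substage stage_score third top3_stages                  top3_votes
embryo_0052.png      9        L    9.000000     b       9;3;4 23.541667;0.000000;0.000000
embryo_0053.png      9        L    9.500000     c      9;10;3 21.083333;2.458333;0.000000
embryo_0054.png      9        L    9.500000     c      9;10;3 22.770833;0.770833;0.000000
embryo_0055.png      9        L    9.000000     b       9;3;4 23.541667;0.000000;0.000000
embryo_0056.png     10        E    9.500000     a      10;9;3 17.750000;5.791667;0.000000
```

(the true stages are 9, 9, 9, 9, 10).  `embryo_0056` is called stage 10
with the stage-9 neighbour out-voting stage 11, hence sub-stage **10E**
with score 9.5 — an embryo just past the 9/10 boundary.  The pool's
algorithm disagreement rate on shared validation splits here is 0.181;
diversity among algorithms is what the confidence-weighted vote exploits.

The same pipeline is available from the shell:

```bash
flystage simulate   --out corpus --n-per-stage 20 --seed 7
flystage featurize  --images corpus --out feat
flystage train-pool --features feat --out pool --ratios 0.7,0.9 --partitions 3
flystage annotate   --pool pool --features feat --out annotations.csv
flystage evaluate   --features feat --out eval --holdout 0.3
flystage gem        --images corpus --annotations annotations.csv --out gems
```

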