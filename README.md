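# cnasubtype

Discriminating the two major non-small cell lung cancer subtypes —
adenocarcinoma (ACA) and squamous cell carcinoma (SCC) — from genome-wide
copy-number alteration (CNA) profiles measured on SNP arrays.  The package
implements the complete feature-selection-and-classification pipeline as a
tested, reusable library with a command-line interface, for computational
biologists who want to rank CNA probes by discriminative power, pick an
optimal probe panel, and interpret it through gene-set enrichment.

## The method

Given a samples × probes copy-number matrix with a binary class label per
sample (ACA = positive, SCC = negative), the pipeline runs five stages:

1. **Discretization.** Each probe is reduced to three states around its own
   mean: −1 below μ − ασ, +1 above μ + ασ, 0 between (sample sd, α = 1 by
   default), giving the discrete densities needed for mutual information
   I(X;Y) = Σ p(x,y) log₂ [p(x,y) / (p(x)p(y))].
2. **mRMR ranking.** Probes are ranked greedily by maximum relevance,
   minimum redundancy: round m+1 selects the unselected probe maximizing
   D − R, where D = I(probe; class) and R is the mean mutual information
   with the m probes already selected.  A pure-relevance MaxRel ranking is
   produced alongside.
3. **Incremental feature selection (IFS).** For every prefix of the mRMR
   list (sizes 1..N) a nearest-neighbor classifier with the cosine nearness
   measure, near(x, y) = 1 − x·y ⁄ (‖x‖‖y‖), is evaluated by jackknife
   (leave-one-out) cross-validation; each prefix yields sensitivity
   Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy, and the Matthews
   correlation coefficient
   MCC = (TP·TN − FP·FN) ⁄ √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
   The optimal panel is the smallest prefix with maximum MCC.
4. **Probe → gene mapping.** Probes map to genes whose span, extended 2 kb
   up- and downstream, contains the probe position (0-based half-open).
5. **Enrichment.** The panel's genes are tested for over-representation in
   gene-set collections (KEGG pathways, GO terms, cytobands) with a
   one-sided Fisher exact test — the hypergeometric upper tail P(X ≥ a) on
   the 2×2 table of list/genome × with/without annotation.

A synthetic-cohort generator with planted class-informative probes,
redundant correlated probe blocks, and a null background provides ground
truth for every stage, so the whole pipeline is testable without array data.

## Worked example

```python
import cnasubtype as cs

# 60 ACA vs 40 SCC samples, 500 probes; 10 planted informative probes
# (effect size 2 sd) each with 4 highly correlated redundant partners
spec = cs.SyntheticSpec(n_pos=60, n_neg=40, p_total=500,
                        informative=tuple(range(10)), effect_size=2.0,
                        block_size=4, noise_sd=0.3, seed=7)
matrix, truth = cs.generate(spec)

d = cs.discretize(matrix, alpha=1.0)
ranked = cs.mrmr_rank(d, matrix, top_n=100)
table = cs.run_ifs(matrix, ranked, max_n=100)
best = cs.select_optimal(table, ranked)
m = best.metrics
print("top 5 mRMR probes:", ranked.probe_ids[:5])
print(f"optimum: {best.size} probes, Sn={m.sensitivity:.4f} "
      f"Sp={m.specificity:.4f} Acc={m.accuracy:.4f} MCC={m.mcc:.4f}")

probes, genes = cs.generate_annotation(spec)
gene_list = cs.genes_of_subset(best, cs.map_probes_to_genes(probes, genes))
sets, universe = cs.generate_genesets(truth, n_null_sets=50, set_size=20, seed=7)
res = cs.enrich(gene_list, sets, universe=universe)
print(f"top enrichment: {res[0].set_id} a={res[0].table.a} p={res[0].p_value:.3g}")
```

prints

```
top 5 mRMR probes: ['P000042', 'P000039', 'P000021', 'P000049', 'P000032']
optimum: 5 probes, Sn=1.0000 Sp=1.0000 Acc=1.0000 MCC=1.0000
top enrichment: PLANTED a=5 p=8.3e-06
```

Five probes suffice for a perfect leave-one-out classification of this
cohort.  All five belong to planted redundancy blocks (here each is a
redundant partner of a planted parent — interchangeable carriers of the
same signal), and the planted gene set is by far the most enriched
annotation of the panel's genes, with the 50 random null sets far behind
(runner-up p = 0.014).

The same run from the shell:

```bash
cnasubtype simulate --out work --seed 7 --n-pos 60 --n-neg 40 --p-total 500
cnasubtype rank work/matrix.tsv --top-n 100 --out work
cnasubtype ifs work/matrix.tsv --ranking work/mrmr.tsv --out work
```

or end to end from a YAML config with `cnasubtype run --config cfg.yaml`.

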