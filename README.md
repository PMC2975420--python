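# airnet

Inference of gene regulatory networks from *unsynchronized* expression
samples.  Instead of correlating absolute expression values, airnet
discretizes each gene's profile into activation levels and correlates the
*changes* in level across every pair of samples — so plain replicate or
perturbation arrays work without any time-series assumptions.

The pipeline:

1. **discretize** — each gene's profile is clustered on its own into `k`
   levels with an exact (dynamic-programming) 1-D k-means; levels are
   ordered by cluster mean.
2. **influence** — for every gene pair and every pair of samples, the two
   level changes cast a vote: equal non-zero changes support promotion,
   equal-magnitude opposing changes support inhibition, jointly-zero
   changes count as positive evidence, anything else abstains.  The signed
   influence value `v = (p + q − n) / total` lies in `[−1, 1]`.
3. **netbuild** — candidate edges get weight `w = 1 − |v|` and are pruned
   by a thresholded Kruskal pass: edges are taken in decreasing `|v|`,
   stopping below the threshold, optionally skipping cycle-closing edges
   (spanning-forest mode).
4. **evaluate** — ranked predictions are scored against an undirected gold
   standard with AUROC/AUPR, empirical p-values from random same-size
   rankings, and the combined score `−log10(auroc_p · aupr_p) / 2`.
5. **compare** — two inferred networks (e.g. diseased vs normal) are
   diffed into shared/exclusive edges with strength deltas and sign-flip
   flags.
6. **simulate** — synthetic ground-truth networks plus wild-type /
   knockout / knockdown expression data for end-to-end testing.

## CLI

All subcommands write a `<output>.manifest.json` (config, input digests,
version) next to their output and accept `--config file` with flat
`key=value` defaults.

```sh
# discretize an expression TSV (genes in rows, header = sample ids)
airnet discretize --input expr.tsv --k 2 --output disc.tsv

# full inference: expression -> pruned network (edge-list TSV / SIF / DOT)
airnet infer --input expr.tsv --k 2 --threshold 0.8 --mode forest --output net.tsv

# score against a DREAM-style three-column gold standard
airnet eval --pred net.tsv --gold gold.tsv --nulls 10000 --seed 17 --report eval.json

# diff two condition-specific networks
airnet compare netA.tsv netB.tsv --labels euploid,trisomic --out diff.tsv --dot diff.dot

# generate a synthetic study (expression + gold standard)
airnet simulate --genes 10 --edges 10 --design null-mutant --coupling 0.8 \
    --noise 0.01 --seed 7 --out-prefix sim_
```

Key flags: `--pair-mode {unordered,ordered}` (the two provably give
identical influence values), `--zero-votes {on,off}` (whether jointly-zero
changes enter the numerator), `--match {strict,sign}` (exact vs sign-only
change matching, relevant for `k > 2`).

## Notes

- The exact 1-D k-means solver is deterministic; one cell of the published
  two-level worked example corresponds to a *local* optimum of Lloyd-style
  k-means and is intentionally not reproduced (the solver's partition has
  strictly lower within-cluster SSE; see `tests/test_discretize.py`).
- Forest mode follows Kruskal strictly and is acyclic; threshold mode keeps
  every edge at or above the cutoff.
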