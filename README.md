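# geowave

Consensus (ensemble) clustering for flow and mass cytometry, built on
geometric medians and distance-weighted voting.

## The problem

Single-cell cytometry produces an events × markers matrix — often millions
of cells in 10–40 dimensions. Unsupervised clustering (FlowSOM, SPADE,
Phenograph, …) is the standard route to cell populations, but results vary
with the algorithm and its hyperparameters. Consensus clustering reduces
that variance by combining several *base partitions* of the same events
into one partition. The classical co-association approach needs an N × N
matrix and is intractable at cytometry scale; graph heuristics scale but
discard the marker space entirely.

This package implements a marker-space heuristic instead:

1. **Pool** every cluster from every base partition (m clusters in total).
2. **Summarise** each pooled cluster c by its geometric median

   û(c) = argmin_x Σ_{x_i ∈ c} ‖x − x_i‖₂,

   computed by Weiszfeld iteration — a robust multivariate centre that
   handles negative (arcsinh-transformed) values and is not constrained to
   be a data point.
3. **Meta-cluster** the m × d median matrix (agglomerative, k-means,
   affinity propagation or mean shift) into K consensus clusters; K can be
   chosen from a range by consensus resampling (minimum PAC, the
   proportion of ambiguous co-clustering).
4. **Vote**: an event t whose base clusters point at several consensus
   clusters is scored against each candidate C by

   p(C, t) = Σ_{c ∈ C} ‖t − û(c)‖₁ / |C|,    score(C, t) = |C| / p(C, t),

   and assigned to the consensus with the maximum score — many supporting
   clusters whose medians sit close to the event. Only ambiguous events
   are scored, in fixed-size chunks that can be distributed over workers
   without changing the result; no N × N structure is ever built.

The package also ships the standard preprocessing (arcsinh with cofactor
5 for mass cytometry / 150 for flow, down-sampling to a 300 000-event
working set), FCS 3.0/3.1 and CSV readers, external evaluation metrics
(ARI, AMI, FMI, Hungarian-matched per-population precision/recall/F1),
a seeded synthetic benchmark generator, and the exact co-association
consensus as a small-N reference.

## Worked example

```python
import geowave as gw

# 10 Gaussian clouds in 15 dimensions, moderate overlap
events, truth = gw.make_blobs(gw.BlobSpec(n_events=20_000, sd=2.0, seed=1))

# four k-means base runs stand in for external clustering tools
partitions = gw.builtin_base_partitions(events, [8, 10, 12, 15], [1, 2, 3, 4])

model = gw.GeoWaVe(events, partitions, meta_method="agglomerative", k=10)
res = model.fit(n_workers=2)
print(res)
print(res.summary().to_string(index=False))
print({k: round(v, 4) for k, v in res.evaluate(truth).items()})
```

Output:

```
<GeoWaVeResults: 10 consensus clusters, N=20000, ambiguous=0.203>
 consensus  n_events  fraction  n_voted  median_winning_score
         0      3405   0.17025     1409              0.150761
         1      2043   0.10215       56              0.123397
         2      2037   0.10185       38              0.175855
         3      2030   0.10150       30              0.117097
         4      2012   0.10060       40              0.131753
         5      2009   0.10045       13              0.142616
         6      2003   0.10015        8              0.155594
         7      1999   0.09995        1              0.110262
         8      1952   0.09760     1952              0.167320
         9       510   0.02550      510              0.156062
{'ari': 0.8878, 'ami': 0.9277, 'fmi': 0.9007, 'average_f1': 0.9083, 'sd_f1': 0.1836}
```

20.3% of events received conflicting consensus candidates from the four
base runs and were resolved by the weighted vote (`n_voted` per cluster);
the consensus recovers the generating populations with ARI 0.89 despite
none of the base runs using the true cluster count. Labels are ordered by
decreasing size; `median_winning_score` summarises how tightly voted
events sit to their winning consensus. With `k_range=range(2, 15)` instead
of `k=10`, `fit()` chooses K by PAC minimisation and records the per-k
statistics in `res.k_stats`.

The same pipeline is scriptable from a shell:

```bash
geowave synth --n-events 20000 --sd 2 --seed 1 --out data/
geowave cluster --input data/events.csv \
    --labels data/partition_0.csv --labels data/partition_1.csv \
    --labels data/partition_2.csv --labels data/partition_3.csv \
    --meta agglomerative --k 10 --seed 1 --out run/
geowave evaluate --result run/consensus_labels.csv \
    --truth data/truth.csv --out eval/
```

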