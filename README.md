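# netact

Top-down stratification of tumor expression cohorts by **signaling-network
module activity**.

Instead of clustering samples on thousands of genes or on a cancer-specific
discriminatory signature, `netact` scores each sample against a curated
module-based signaling network: genes are grouped into functional modules
(Ligand, RTK/Receptor, Adaptor, Downstream, CoActivator/CoInhibitor,
Inhibitor, TranscriptionFactor) of the major growth-factor pathways (PDGFR,
INSR, MAPK, NFkB, AP1, ...), and the activity of module *m* in sample *s* is
the median expression of the module's measured genes,

```
a_{m,s} = median{ x_{g,s} : g in genes(m), g measured }.
```

Samples are then clustered on the modules-by-samples activity matrix with
correlation distance `d(i,j) = 1 − r(i,j)` (Pearson by default): complete-
linkage hierarchical bi-clustering for ordered-heatmap export and subcluster
selection, and k-means (k chosen by average silhouette width) for quantitative
evaluation — each clustering is scored against clinical annotations (ER/HER2
status, grade, tumor type, stage) by a chi-square test on the cluster-by-
category contingency table (Yates-corrected for 2×2). Differentially
activated modules between a subcluster and all other samples are ranked by
`score = log2 |mean_A − mean_B|` and the top 15% per dataset is selected; a
module is *cross-dataset consistent* when it is selected in two independent
cohorts with the same direction.

The package is aimed at computational biologists who want a reproducible,
scriptable version of this analysis for their own expression matrices and
curated networks. It ships a small **reduced demonstration network**
(62 genes, 11 scored modules — clearly non-canonical); full curated networks
are supplied by the user as two TSVs (gene/module membership plus a signed
module edge list). A seeded synthetic-cohort generator with planted
module-activity shifts and label-concordant clinical annotations makes every
pipeline stage testable without any data download.

## Worked example

```python
import netact as na
from sklearn.metrics import adjusted_rand_score

net = na.fixture_network()
ds = na.simulate_dataset(na.default_scenario("ovarian_like"), seed=0)

act = na.compute_module_activity(ds.expr, net)     # modules x samples medians
std, _ = na.standardize(act.values)                # per-module mean 0 / sd 1

report = na.select_k(std, (2, 6), seed=0)          # silhouette-based k
km = na.kmeans_correlation(std, report.chosen_k, seed=0)
print(adjusted_rand_score(ds.groups.values, km.assignments.values))

evaluation = na.evaluate_clustering(km.assignments, ds.annotations,
                                    ["type", "stage", "grade"])

cmp = na.GroupComparison.from_labels(ds.groups, "lmp", "LMP-vs-rest")
table = na.top_fraction(na.differential_scores(act.values, cmp))
print(table.threshold, table.selected_items)
```

prints (exact output of this session):

```
fixture network: 62 genes, 13 modules, 12 edges
cohort: 62 genes x 83 samples
silhouette-selected k = 2
ARI vs planted groups = 1.00
chi-square p (type) = 2.46E-14
chi-square p (stage) = 2.68E-07
chi-square p (grade) = 1.04E-02
top-15% threshold = 8.286 (log2 units)
selected: MAPK-Inhibitor (up, score 8.42)
selected: AP1 (up, score 8.29)
```

Reading: the silhouette scan finds two clusters, k-means recovers the planted
LMP-like group perfectly (ARI 1.0), the group-defining annotation ("type")
has by far the smallest chi-square p-value, and the two modules planted with
the strongest activity shift (AP1 and MAPK-Inhibitor, both higher in the LMP
group) are exactly the top-15% differential set.

The same analysis is available from the shell via the `netact` CLI
(`simulate`, `normalize`, `activity`, `cluster`, `kselect`, `evaluate`,
`diff`, `crossdiff`, `overlap`, and `run` for an end-to-end configured
pipeline); see `netact --help`.

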