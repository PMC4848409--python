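# oncotrees

Oncogenetic tree inference from binary copy-number alteration (CNA)
matrices. Given a tumors × events 0/1 table, the package fits two
complementary progression models:

* **Branching tree** — every event is a node with a single parent; the tree
  is the maximum-weight arborescence rooted at the normal (alteration-free)
  state under pairwise co-occurrence weights
  `w(i→j) = 2·log p_ij − log(p_i+p_j) − log p_i − log p_j`
  (root treated as an always-present event, so `w(root→j) = log[p_j/(1+p_j)]`).
  Edges carry conditional probabilities `p_ij / p_i`, and an exact
  likelihood layer adds shared false-positive / false-negative observation
  rates, estimated by bounded multistart maximum likelihood.
* **Distance-based tree** — events sit at the leaves below hidden internal
  nodes. Under the latent firing model (each edge fires independently with
  probability `p_e`; an event is present iff its whole root path fired), the
  branch lengths `−log p_e` make
  `D_ij = log p_i + log p_j − 2·log p_ij` (leaf–leaf) and `r_i = −log p_i`
  (root–leaf) an additive tree metric: the shared prefix of two root paths
  has length `(r_i + r_j − D_ij)/2`, so neighbor joining over the events
  plus a root pseudo-leaf recovers the generating topology exactly on
  model-consistent inputs. Edge probabilities can be re-estimated by exact
  maximum likelihood (latent-state enumeration up to 16 edges).

Both fitters plug into a nonparametric bootstrap over tumors with topology
tallying, frequent-tree ranking, and a strict `> threshold` split consensus
(default 10%). A cohort simulator and deterministic count-matched fixtures
replace private cohort data.

Raw frequencies are clamped into `[1/(2n), 1 − 1/(2n)]` (joints re-capped at
`min(p_i, p_j)`), so every log-weight stays finite even on bootstrap
resamples that lose an event entirely.

## Library quick start

```python
import oncotrees as ot

# deterministic 963-tumor cohort matching the published per-gene counts
m = ot.fixture_from_counts(
    963,
    {"PIK3CA": 51, "AKT2": 22, "KRAS": 25, "PTEN": 55, "ErbB2": 121, "CCND1": 153},
    any_altered=342,
)
ot.frequency_summary(m).to_dict()       # counts + integer percents

btree = ot.fit_branching_tree(m)        # arborescence + conditional probs
dtree = ot.fit_distance_tree(m)         # NJ tree, Newick via .to_newick()

res = ot.bootstrap(m, "branching", B=1000, seed=0)
ot.frequent_trees(res, 5)               # ranked (topology, count)
ot.consensus_report(res, 0.10)          # splits with support > 10%

spec = ot.paper_tree_fixture(n=5000, seed=1)   # generative 6-gene tree
cohort = ot.simulate_cohort(spec)
```

## CLI

```sh
oncotrees fixture --out cohort.tsv                       # count-matched fixture
oncotrees simulate --n 963 --seed 1 --out sim.tsv        # simulated cohort
oncotrees freq --input cohort.tsv
oncotrees branching --input cohort.tsv --dot tree.dot
oncotrees disttree  --input cohort.tsv --newick tree.nwk
oncotrees bootstrap --input cohort.tsv -B 1000 --seed 0 --out bs.json
oncotrees run --input cohort.tsv --method both -B 1000 --seed 0 --out report/
```

`run` writes a deterministic bundle (frequencies JSON, branching DOT+JSON,
distance Newick+JSON, bootstrap JSON, consensus tables, markdown report);
reruns with the same inputs are byte-identical. GISTIC-style thresholded
call tables (integer calls −2..2, genes × samples) are read with
`--dialect gistic_thresholded`; an entry maps to 1 iff `|call| ≥ 2`
(configurable). User errors exit with status 2 and a message.

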