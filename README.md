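# grnseg

Segregating EM-reconstructed gustatory axons into taste-modality groups
from morphology and synaptic connectivity.

## The problem

In the adult *Drosophila* gustatory system, ~90–100 gustatory receptor
neurons (GRNs) per labellum project through a common nerve tract into the
subesophageal zone, where axons of different taste modalities (sugar,
bitter, water, low salt, high salt) terminate in discrete zones and
synapse heavily onto axons of their own kind. Given dense EM
reconstructions of these axons and their chemical synapses, the analysis
question is: can the modality classes be recovered *de novo* from anatomy
and connectivity alone, and how strongly is the synapse graph segregated
by modality?

`grnseg` implements that analysis as a tested, reusable pipeline for
connectomics researchers:

1. **Dotprops** — each SWC skeleton is resampled to points ~1 µm apart
   along the cable; each point gets a unit tangent **u** from the first
   principal axis of its 5 nearest neighbours.
2. **NBLAST similarity** — a query cloud *Q* is scored against a target
   *T* as S(Q,T) = Σᵢ f(dᵢ, |uᵢ·vⱼ₍ᵢ₎|) over nearest-neighbour matches,
   with the kernel f(d, a) = a·e^(−d/σ) (σ = 3 µm) or a trained log-odds
   score table. Scores are self-normalised (S(Q,T)/S(Q,Q)) and
   symmetrised by averaging both directions, giving the all-by-all
   similarity matrix **S** with diag(S) = 1.
3. **Feature merge + scaling** — **S** is concatenated row-wise with the
   directed synapse-count matrix **C** (Cᵢⱼ = synapses from neuron i onto
   j) and min–max scaled into [0, 1] (per block by default).
4. **Ward clustering** — agglomeration minimising the increase in
   within-cluster sum of squares; the joining cost of merging A and B is
   ΔESS = |A||B|/(|A|+|B|)·‖c_A − c_B‖². The group count k* is chosen at
   the elbow of the joining-cost profile J(k): the argmax of the relative
   differential (J(k−1) − J(k))/J(k).
5. **Modality assignment** — each group's composite point cloud is
   NBLAST-scored against a labelled template library (one or more
   reference projection patterns per taste class); the group is named by
   its top hit.
6. **Connectivity accounting** — per-neuron synapse statistics (site
   totals, fraction of input received from other cohort neurons) and
   k×k within/between-group synapse block sums, optionally restricted to
   high-confidence connections of ≥5 synapses.

A bundled synthetic-cohort generator (`grnseg.synthetic`) grows branched
axon arbors in group-specific zones and samples a planted block-structured
synapse graph, so every stage is testable end to end with known ground
truth and no data download.

## Worked example

```python
import grnseg as g
from sklearn.metrics import adjusted_rand_score

data = g.generate(g.preset_labellar(seed=1))     # 87 axons, 6 planted groups
ids  = [s.neuron_id for s in data.skeletons]
dps  = [g.to_dotprops(s) for s in data.skeletons]
conn = g.build_matrix(data.synapses, ids)
res  = g.cluster_cohort(dps, conn)

print("selected k =", res.k)
truth = data.truth.labels_for(res.assignment.neuron_ids)
print("ARI vs ground truth =", adjusted_rand_score(truth, res.assignment.labels))
for t in (1, 5):
    s = g.group_block_sums(g.threshold_edges(conn, t), res.assignment)
    print(f"threshold {t}: within {s.within_fraction:.1%}, between {s.between_fraction:.1%}")
```

prints

```
selected k = 6
ARI vs ground truth = 1.0
threshold 1: within 78.9%, between 21.1%
threshold 5: within 98.4%, between 1.6%
```

— the pipeline recovers exactly the six planted groups; ~79% of all
GRN–GRN synapses are within-group, and restricting to high-confidence
(≥5-synapse) connections removes most between-group synapses. Adding the
template library names each recovered group after the class that
generated it:

```python
lib   = g.build_template_library(data.template_skeletons)
calls = g.assign_modalities(res.assignment, {d.neuron_id: d for d in dps}, lib)
# group 1: water      (top hit template_water,      mean NBLAST score 0.448)
# group 3: sugar      (top hit template_sugar,      mean NBLAST score 0.486)
# ...
```

The same pipeline is available from the shell:

```sh
grnseg simulate --preset labellar --seed 1 --out cohort/
grnseg run --skeletons cohort/skeletons --synapses cohort/synapses.csv \
           --totals cohort/totals.csv --templates cohort/templates --out results/
```

which writes the similarity/connectivity/merged matrices (CSV), the Ward
dendrogram (Newick), the joining-cost profile, group assignments,
modality calls, per-neuron statistics, group block-sum summaries at each
threshold, and a run manifest with parameters and input checksums.

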