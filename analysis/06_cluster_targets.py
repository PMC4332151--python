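"""Cluster synthetic multi-condition diurnal profiles and test enrichment.

Generates a 200-gene matrix with three planted clusters of PIF-driven shapes
(in-phase, antiphase, 6-h shifted) across six conditions, recovers them with
affinity propagation, filters for large coherent clusters, and tests the
overlap of each cluster with a synthetic "bound-gene" reference set.

Writes results/cluster_assignments.tsv and results/cluster_summary.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

import photoclock as pc

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 11
m, truth, info = pc.gen_cluster_matrix(200, noise_sd=0.5, seed=SEED)
mp = pc.preprocess(m)
S = pc.similarity(mp)
raw = pc.affinity_propagation(S, genes=mp.genes)
res = pc.filter_coherent(raw, S, min_size=20, min_coherence=0.6)

mask = truth >= 0
ari = adjusted_rand_score(truth[mask], raw.labels[mask])
print(f"Affinity propagation: {len(raw.sizes)} clusters "
      f"({len(res.sizes)} pass size>=20 & coherence>=0.6); "
      f"ARI vs planted truth = {ari:.3f}")

pd.DataFrame({"gene": res.genes, "cluster": res.labels,
              "planted": truth}).to_csv(
    OUT / "cluster_assignments.tsv", sep="\t", index=False)

# synthetic reference set: two thirds of planted cluster 0 plus random genes,
# standing in for an independently measured bound-gene list
rng = np.random.default_rng(SEED)
cluster0 = [g for g, t in zip(m.genes, truth) if t == 0]
others = [g for g, t in zip(m.genes, truth) if t != 0]
reference = (list(rng.choice(cluster0, size=2 * len(cluster0) // 3,
                             replace=False))
             + list(rng.choice(others, size=10, replace=False)))

rows = []
universe = set(res.genes)
for cid in sorted(res.sizes):
    members = res.members(cid)
    pval = pc.overlap_enrichment(members, set(reference) & universe, universe)
    rows.append({"cluster": cid, "size": res.sizes[cid],
                 "coherence": round(res.coherence[cid], 3),
                 "overlap_p": pval})
    print(f"cluster {cid}: size={res.sizes[cid]} "
          f"coherence={res.coherence[cid]:.3f} overlap P={pval:.2e}")
pd.DataFrame(rows).to_csv(OUT / "cluster_summary.tsv", sep="\t", index=False)
print("The cluster carrying the reference genes shows strong hypergeometric "
      "enrichment; the others do not.")
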