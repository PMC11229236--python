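"""Sample structure: variable genes, clustering, PCA, developmental order.

Reproduces the structure analyses of a bud time-course: hierarchical
clustering of samples at 1 - Pearson distance, PCA with PC-factor ANOVA,
and the one-dimensional developmental ordering of groups along PC1.
"""

import peachbud as pb
from peachbud import simulate as sim
from peachbud import structure as st

d = sim.simulate_all(seed=1)
logcpm = pb.cpm_log_transform(d["counts"])
md = d["metadata"]

hv = st.top_variable_genes(logcpm, n=2000)
clus = st.hierarchical_clusters(logcpm.loc[hv], k=6)
print("clusters at k=6 (replicates of one position x timepoint should agree):")
print(clus.labels.groupby(md["position"] + "_" + md["timepoint"]).unique())

res = st.pca(logcpm, k=2)
print(f"\nPC1+PC2 variance explained: {100 * res.variance_fractions[:2].sum():.1f}%")
for factor in ("timepoint", "position"):
    p = st.pc_factor_association(res, md, factor)
    print(f"ANOVA p of {factor}: PC1 = {p['PC1']:.2e}, PC2 = {p['PC2']:.2e}")

print("\ndevelopmental ordering along PC1 (T5 anchored to the right):")
print(st.developmental_ordering(res, md).round(2))
# Time should load on PC1 and bud position on PC2; groups then order along
# PC1 from the earliest to the most advanced developmental state.
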