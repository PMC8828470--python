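"""Ligand-receptor permutation test with a planted sender-receiver pair.

Gene g0 (ligand) is elevated in cluster c0 and g1 (receptor) in cluster c1;
the (c0, c1) cluster pair should come out significant, other pairs should
not.
"""

import spomics as spm

ds = spm.simulate_points(
    spm.SimulationSpec(
        n_points=300, n_labels=3, n_genes=10,
        expression_model="planted-ligrec",
        ligrec_pairs=((0, 1, 0, 1),),  # ligand g0 in c0 -> receptor g1 in c1
        ligrec_effect=3.0, seed=4,
    )
)
interactions = spm.InteractionTable(sources=[("g0",)], targets=[("g1",)])
res = spm.ligrec_test(ds, "cluster", interactions, n_perms=1000, seed=0)

print("sender -> receiver   mean   p-value  p_adj")
for _, row in res.iterrows():
    mark = "  <- planted" if (row.sender, row.receiver) == ("c0", "c1") else ""
    print(f"{row.sender} -> {row.receiver}        {row['mean']:.2f}   "
          f"{row.pvalue:.4f}  {row.pvalue_adj:.4f}{mark}")
print("-> the planted (c0, c1) pair has the largest joint mean.  Every pair "
      "involving the elevated ligand cluster (sender c0) or receptor cluster "
      "(receiver c1) beats the shuffled null on one side of the statistic; "
      "pairs touching neither are at p = 1.")
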