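"""The full validation experiment at quick scale: do the utility metrics
rank the synthesizers the way the prediction workload does?

For each utility metric, the three methods are grouped H/M/L per dataset
by their replicate-averaged metric values; each group member is replaced
by its workload difference, ranked within the dataset, and the exact Page
trend test asks whether differences increase from H to L.  A footrule
aggregate ranking over five metrics is tested the same way.
"""

from synthutil import ExperimentConfig, export_boxplot_data, leave_one_out_aggregate, run_experiment

cfg = ExperimentConfig(n_datasets=10, n_rows=500, replicates=5, base_seed=11)
res = run_experiment(cfg)

cols = ["metric", "workload", "L", "n", "p_value", "significant"]
print(res.page_tests[cols].to_string(index=False))
n = res.page_tests["n"].iloc[0]
print(f"\nL ranges over [10n, 14n] = [{10*n}, {14*n}]; larger = stronger trend.")

long_table = export_boxplot_data(res.cells, "hellinger")
med = long_table[long_table.workload == "auroc_diff"].groupby("group")["value"].median()
print("\nmedian AUROC difference by Hellinger group "
      f"(H best): H={med['H']:.3f}  M={med['M']:.3f}  L={med['L']:.3f}")

loo = leave_one_out_aggregate(res.cells, cfg)
print("\nleave-one-out aggregate (drop one metric, retest):")
print(loo.to_string(index=False))
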