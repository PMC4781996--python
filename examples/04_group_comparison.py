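"""Permutation test for group differences in network metrics.

Group B is generated with stronger within-block covariance than group A,
so its networks are more clustered. The permutation test rebuilds the full
pipeline under random relabelings of the subjects to decide whether the
observed clustering/path-length differences exceed chance.
"""

from scnet import (
    CohortSpec,
    betweenness_difference_map,
    generate_cohort,
    permutation_test,
)

cohort = generate_cohort(
    CohortSpec(
        n_subjects_per_group=36, n_regions=40, n_blocks=4,
        r_in=0.3, group_r_in=0.7, seed=21,
    )
)

results = permutation_test(
    cohort, sparsities=(0.11, 0.15), metrics=("C_p", "L_p"),
    n_perm=200, seed=3,
)
for r in results:
    flag = "increase" if r.significant_increase else (
        "decrease" if r.significant_decrease else "n.s."
    )
    print(
        f"{r.metric} @ s={r.sparsity:.2f}: observed diff (A-B) = "
        f"{r.observed:+.4f}, null 5-95% = [{r.crit_low:+.4f}, "
        f"{r.crit_high:+.4f}] -> {flag}"
    )

# Nodal analysis: which regions' betweenness differs at 15% sparsity?
bc_results = permutation_test(
    cohort, sparsities=(0.15,), metrics=("bc",), n_perm=200, seed=3
)
table = betweenness_difference_map(bc_results, 0.15)
flagged = table[table["direction"] != "none"]
print(f"\nregions with betweenness differences: {len(flagged)} of {len(table)}")
print(flagged.to_string(index=False))

# A 'decrease' in C_p means group B (higher within-block correlation) is
# more clustered than A. Nodal flags without multiplicity correction carry
# about 5% false positives per tail by construction.
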