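"""Benchmark classifier families on all vs selected features.

Runs stratified 5-fold cross-validation on the frequency-domain features
of an effect dataset, before and after the significance screen, and prints
one row per family (its best preset variant).
"""

from mifeatlab import (
    EffectSpec,
    build_feature_matrix,
    generate_dataset,
    run_cv,
    significance_filter,
)

effect = EffectSpec(class_id=1, channels=(8, 12), band=(8.0, 13.0), power_ratio=4.0)
ds = generate_dataset(1, 288, [effect], seed=7)
fm = build_feature_matrix(ds, domains=("F",))
sel = significance_filter(fm)

families = ("DT", "DA", "SVM", "kNN", "EL")
for label, matrix in [("all features", fm),
                      ("selected features", fm.select_columns(sel.mask))]:
    report = run_cv(matrix, families, seed=7)
    print(f"\n{label} ({matrix.n_features} columns), chance = 0.25:")
    for fam in report.families.values():
        print(f"  {fam.family:4s} {fam.mean_accuracy:.3f}  ({fam.best_variant})")
print("\n-> only class 1 carries signal, so ~0.5 is the ceiling here: the")
print("   effect class is separated and the other three remain at chance.")
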