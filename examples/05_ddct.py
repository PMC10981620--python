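"""Relative quantitation of qPCR measurements by the 2^-ddCt method.

Each sample contributes dCt = Ct_target - Ct_reference; the fold change
of treatment relative to control is 2^-(mean dCt difference).
"""

import mirimmune as mi

treatment = [
    mi.CtRecord("t1", 24.1, 20.0, "treatment"),
    mi.CtRecord("t2", 23.8, 19.9, "treatment"),
    mi.CtRecord("t3", 24.0, 20.1, "treatment"),
]
control = [
    mi.CtRecord("c1", 26.9, 20.0, "control"),
    mi.CtRecord("c2", 27.2, 20.2, "control"),
    mi.CtRecord("c3", 27.0, 19.9, "control"),
]

fold = mi.relative_quantity(treatment, control)
print(f"fold change (2^-ddCt): {fold:.2f}")
print("per-sample folds:", {
    k: round(v, 2) for k, v in mi.per_sample_fold_changes(treatment, control).items()
})
# Treatment reaches threshold ~3 cycles earlier relative to the
# reference gene, i.e. roughly 2^3 = 8-fold more target transcript.
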