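"""Mechanism-of-action classification of a drug panel.

Trains a multinomial logistic regression on labelled metabolomic profiles
(five mechanism classes), evaluates it by leave-one-out cross-validation and
reports which class the antifolate-like query profile lands in.
"""

import numpy as np

from offtarget import mechml, synthio

cfg = synthio.SynthConfig(seed=11)
table, labels = synthio.simulate_metabolomics(cfg)

profiles = mechml.profiles_from_abundance(table, labels)
filtered = mechml.filter_profiles(
    profiles, table.metabolite_meta["annotation_score"], score_threshold=50)

model = mechml.train_mechanism_model(filtered)
confusion, accuracy = mechml.evaluate_loocv(filtered)
proba = mechml.predict_mechanism(model, filtered)

print("LOOCV per-class accuracy:")
print(accuracy.round(3).to_string())
print("\npredicted class probabilities for the antifolate profile:")
print(proba.loc["antifolate"].round(3).to_string())

importance = mechml.feature_importance(model, "antifolate")
print("\ntop metabolites driving the antifolate signature:")
print(importance.head(5).to_string(index=False))

residual = mechml.residual_signature(
    model, filtered.features.loc["antifolate"], "antifolate")
w = model.weights[model.classes.index("antifolate")]
print(f"\nresidual signature is orthogonal to the class weights "
      f"(<r,w> = {float(residual.to_numpy() @ w):.2e}); it is the part of "
      "the response the class signature cannot explain.")
assert np.allclose(proba.sum(axis=1), 1.0)
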