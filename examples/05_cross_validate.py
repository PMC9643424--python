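"""Generalization: tenfold cross-validated Q^2 vs in-sample R^2.

Preprocessing (PCA rotation, min-max ranges, target squash) is re-fitted
inside every fold from that fold's training rows only, so Q^2 measures
out-of-sample prediction honestly.
"""

import qclreg as q

dataset = q.generate()
config = q.ModelConfig(ansatz="mera", optimizer="sgd", shots=q.EXACT,
                       n_steps=200, seed=0, eval_r2_every=50)

model = q.fit(dataset, config)
r2 = q.r_squared(dataset.y, q.predict(model, dataset.X))
cv = q.cross_validate(dataset, config, k=10, seed=0)

print(f"in-sample R^2 (fit on all 86): {r2:+.3f}")
print(f"tenfold CV Q^2:                {cv.q2:+.3f}")
print()
print("Q^2 pools each sample's out-of-fold prediction; it is lower than")
print("R^2 and can go negative when the model generalizes worse than the")
print("mean predictor — the standard overfitting diagnostic in QSPR.")
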