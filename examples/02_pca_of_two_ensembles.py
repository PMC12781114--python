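"""Pooled PCA of a closed-gate and an open-gate ensemble.

Both systems are superposed to one common reference and a single
covariance is fitted over their pooled frames, so the two systems can be
compared in the same principal-component space — the closed and open
ensembles separate along the leading component.
"""

import numpy as np

from nqogate import pca, synthetic, trajectory

common = dict(n_frames=400, p_closed_to_open=0.0, p_open_to_closed=0.0)
_, closed = synthetic.simulate_gate_ensemble(synthetic.EnsembleSpec(
    start_state="closed", fluctuation_sd=1.4, rng_seed=11, **common))
_, open_ = synthetic.simulate_gate_ensemble(synthetic.EnsembleSpec(
    start_state="open", fluctuation_sd=2.9, rng_seed=12, **common))

sel = trajectory.select_atoms(closed.topology, "name CA")
model = pca.fit_pca([closed, open_], sel)
cum = pca.scree(model)
n_dim = len(model.eigenvalues)
print(f"PC1 captures {100 * model.variance_fractions[0]:.1f}% of the pooled "
      f"variance — {model.variance_fractions[0] * n_dim:.0f}x the "
      f"{100 / n_dim:.2f}% an average of the {n_dim} coordinates would carry")
print("  (the rest is isotropic thermal jitter spread thinly over the "
      "remaining components)")

projs = [pca.project(t, model, sel, 2, system_label=lab)
         for t, lab in ((closed, "closed"), (open_, "open"))]
maps = pca.density2d(projs, bins=40)
sep = abs(projs[0].scores[:, 0].mean() - projs[1].scores[:, 0].mean())
print(f"mean PC1 separation between systems: {sep:.1f} A")
print(f"density overlap: {pca.overlap_coefficient(*maps):.3f} "
      "(well-separated states -> near 0)")
for proj, dmap in zip(projs, maps):
    idx = pca.most_probable_frame(proj, dmap)
    print(f"most probable frame of the {proj.system_label} system: {idx} "
          f"at PC1 = {proj.scores[idx, 0]:.1f} A")
print("  -> the gate opening dominates PC1; each system's most probable")
print("     conformation sits at its own density mode")
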