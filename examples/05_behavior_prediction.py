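"""Predict behavioral scores from parcellation topography.

Sixty synthetic subjects with topography-linked scores; kernel ridge
regression with the mean-Dice similarity as kernel, 5-fold cross-validated
penalty, evaluated on 20 held-out subjects, plus a permutation null.
"""

from msgcn import SyntheticCohortConfig, run_behavior_study

results = run_behavior_study(
    n_subjects=60, n_train=40,
    config=SyntheticCohortConfig(seed=11, behavior_noise=0.0),
    seed=0,
)
print(f"chosen ridge penalty:     {results.ridge_lambda:g}")
print(f"held-out prediction r:    {results.r_heldout:.3f} "
      f"(p = {results.p_heldout:.2g})")
# Subjects with similar parcellation topography get similar predicted
# scores; with noise-free scores the relation is recovered almost exactly.
print(f"permutation null |r|:     {results.permuted_abs_r_mean:.3f}")
# Re-correlating the predictions against randomly permuted scores gives a
# near-zero association - the prediction rests on the subject-score link,
# not on any artifact of the kernel.
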