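"""De-attenuate an observed AUC with the probit correction.

A biomarker measured with error looks less discriminative than it is:
if the assay's error variance equals the biomarker variance (ratio
lambda^2 = 1), an observed AUC of 0.75 corresponds to a true AUC of
about 0.83.
"""

from snroc import attenuate_auc, correct_auc

observed = 0.75
for ratio in (0.0, 0.5, 1.0, 2.0):
    true_auc = correct_auc(observed, ratio)
    print(f"lambda^2 = {ratio:3.1f}: observed AUC {observed:.3f} -> true AUC {true_auc:.4f}")

# the map is the exact inverse of the attenuation the error induces
round_trip = correct_auc(attenuate_auc(0.7946, 1.0), 1.0)
print(f"\nattenuate then correct 0.7946 at ratio 1 -> {round_trip:.6f} (identity)")
print(
    "\nEach corrected value is the AUC a noise-free assay would attain; the "
    "larger the error/signal variance ratio, the more the observed AUC "
    "understates it."
)
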