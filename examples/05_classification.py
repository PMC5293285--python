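"""Classifying communities by NRAD shape alone.

Two synthetic families of communities share identical abundance laws except
inside a middle band of ranks.  A random forest with NRAD ranks as
predictors recovers the class labels (evaluated by threefold cross-validated
accuracy and the chance-corrected kappa statistic), and the out-of-bag
permutation importance localizes the discriminative signal to the planted
band — the same analysis used to tell countries of origin apart from gut
microbiome NRADs.
"""

import numpy as np

from radnorm import classify_nrads, generate_labeled_nrad_set, middle_band_shapes

band = (40, 160)
shapes = middle_band_shapes(richness=300, band=band)
nrads, labels = generate_labeled_nrad_set(40, shapes, R=250, rng=0)
report = classify_nrads(nrads, labels, seed=0, n_trees=300)

print(f"{len(nrads)} NRADs, two classes, threefold cross-validation:")
print(f"  ACC   = {report.acc:.3f} +/- {report.acc_se:.3f}")
print(f"  kappa = {report.kappa:.3f} +/- {report.kappa_se:.3f}   (1 = perfect, 0 = guessing)")

imp = report.importance
inside = imp[band[0]:band[1]].mean()
outside = np.r_[imp[:band[0]], imp[band[1]:]].mean()
print(f"  importance peaks at rank {imp.argmax() + 1} "
      f"(planted band: ranks {band[0] + 1}-{band[1]})")
print(f"  mean importance inside band {inside:.4f} vs outside {outside:.4f}")
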