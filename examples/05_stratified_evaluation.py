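"""Binned stratified test splitting and the metric report, piece by piece.

Counting archives are right-skewed, so a uniform random test set would
contain almost no high-count images.  Binning the labels and sampling a
fixed number per bin yields a test set that covers the whole count range.
"""

import numpy as np

import countreg as cr

dataset = cr.make_dataset(cr.DotSceneSpec(), n_images=400, seed=9)
binned = cr.assign_bins(dataset, n_bins=8)
for b in range(8):
    members = binned.labels[binned.label_bins == b]
    print(f"bin {b}: {len(members):3d} images, labels {members.min()}-{members.max()}")

test, remainder = cr.stratified_test_split(binned, cr.SplitSpec(n_bins=8, per_bin=5, seed=0))
print(f"\ntest set: {len(test)} images (5 per bin), remainder {len(remainder)}")
print("test label histogram:", np.bincount(test.labels, minlength=31).tolist())

train, val = cr.train_val_split(remainder, train_fraction=0.8, seed=1)
print(f"train/validation: {len(train)}/{len(val)}")

# Metrics on a deliberately biased predictor: R^2 is the coefficient of
# determination, so systematic undercounting costs both R^2 and totals.
labels = test.labels
biased = labels * 0.7
report = cr.compute_metrics(labels, biased)
print(f"\nbiased predictor: R^2 {report.r_squared:.3f}, RMSE {report.rmse:.2f}, "
      f"MAE {report.mae:.2f}, totals {report.totals_percent:.1f}%")
print(f"underestimate: {cr.totals_underestimate(report):.1f}%")
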