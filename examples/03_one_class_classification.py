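"""One-class classification of normal vs synthesized-abnormal patches.

The trained U-Net is reused as a feature extractor: per-pixel activations
at the last decoder ReLU are averaged over the network's own epidermis and
dermis pixels and concatenated into a 32-dimensional predictor.  A
one-class SVM (outlier fraction 8%) trained only on normal features scores
each patch: positive = normal tissue, negative = abnormal.  Expect the
normal test patches to score mostly positive and the DEJ-disrupted ones to
score strongly negative.
"""

import numpy as np

from octoneclass import (PhantomParams, SegmentationMask, generate_dataset,
                         TrainConfig, build_unet, train_unet,
                         split_into_patches, FeatureGroup, featurize_patches,
                         build_anomaly_dataset, OneClassSVMConfig,
                         train_ocsvm, predict_scores, split_train_test)


def pairs(data):
    out = []
    for img, msk in data:
        for p in split_into_patches(img):
            sub = msk.labels[:, p.lateral_offset:p.lateral_offset + 32]
            out.append((p, SegmentationMask(labels=sub)))
    return out


all_pairs = pairs(generate_dataset(PhantomParams(image_width=1024), 6,
                                   seed=5))
train_pairs, test_pairs = split_train_test(all_pairs, 0.5, seed=6)

model = build_unet(seed=0)
train_unet(model, [p for p, _ in train_pairs[:16]],
           [m for _, m in train_pairs[:16]],
           TrainConfig(mini_batch=8, epochs=12, seed=0))

group = FeatureGroup.EPIDERMIS_AND_DERMIS
X_train, _ = featurize_patches(model, [p for p, _ in train_pairs], group)
ocsvm = train_ocsvm(X_train, OneClassSVMConfig(outlier_fraction=0.08,
                                               feature_group=group))
print(f"one-class SVM trained on {X_train.shape[0]} normal patches "
      f"({X_train.shape[1]}-dim features, nu=0.08)")

test_set = build_anomaly_dataset(test_pairs, seed=7)
X_test, kept = featurize_patches(model, [lp.image for lp in test_set], group)
scores = predict_scores(ocsvm, X_test)
for cls in ("normal", "bcc", "scc", "dej"):
    sel = np.array([test_set[i].class_label == cls for i in kept])
    called_normal = np.mean(scores[sel] > 0)
    print(f"  {cls:6s}: mean score {scores[sel].mean():+6.2f}, "
          f"called normal {called_normal * 100:5.1f}%")
print("(positive scores mean the classifier considers the patch normal; "
      "abnormal classes should trend negative)")
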