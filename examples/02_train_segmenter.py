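"""Train the 4-class U-Net on phantom patches and segment held-out data.

The network labels each pixel of a 256 x 32 patch as air, stratum corneum,
epidermis or dermis.  This fixture-scale run (16 patches, 10 epochs) takes
a couple of minutes on one CPU and should reach ~95% held-out pixel
accuracy; the per-epoch loss should fall steadily.
"""

import numpy as np

from octoneclass import (PhantomParams, SegmentationMask, generate_dataset,
                         TrainConfig, build_unet, train_unet, segment,
                         split_into_patches, pixel_accuracy)


def pairs(data):
    out = []
    for img, msk in data:
        for p in split_into_patches(img):
            sub = msk.labels[:, p.lateral_offset:p.lateral_offset + 32]
            out.append((p, SegmentationMask(labels=sub)))
    return out


train_pairs = pairs(generate_dataset(PhantomParams(image_width=256), 2,
                                     seed=1))
model = build_unet(seed=0)
train_unet(model, [p for p, _ in train_pairs], [m for _, m in train_pairs],
           TrainConfig(mini_batch=8, epochs=10, seed=0))
print("per-epoch training loss:",
      " ".join(f"{l:.3f}" for l in model.train_log))

test_pairs = pairs(generate_dataset(PhantomParams(image_width=256), 1,
                                    seed=99))
accs = [pixel_accuracy(segment(model, p), m) for p, m in test_pairs]
print(f"held-out pixel accuracy over {len(accs)} patches: "
      f"{np.mean(accs):.3f}")
print("(fraction of pixels assigned the correct skin layer)")

model.save("segmenter_example.npz")
print("checkpoint written to segmenter_example.npz")
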