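"""Train the width-reduced network on synthetic scenes (CPU, ~1 minute).

Optimises the Dice + cross-entropy objective with Adam (lr 0.001) on 60
seeded scenes and reports held-out mIOU per epoch.  The score should
climb well above the 0.5 an uninformed predictor would struggle to
reach, showing the multiplicative-fusion architecture learns the
bright-blob segmentation task.
"""

import mbffnet as mb

spec = mb.SyntheticSceneSpec(side=64)
train_set = mb.generate_dataset(spec, 60, seed=101)
held_out = mb.generate_dataset(spec, 16, seed=909)

model = mb.MBFFNet(mb.tiny_config(64, seed=0))
before = mb.evaluate(model, held_out)["mean"]["miou"]
log = mb.train(
    model,
    train_set,
    held_out,
    mb.TrainConfig(epochs=4, batch_size=8, seed=0, augmentation=None),
)

print(f"untrained held-out mIOU: {before:.3f}")
for i, (loss, miou) in enumerate(zip(log["train_loss"], log["val_miou"]), 1):
    print(f"epoch {i}: train loss {loss:.3f}, held-out mIOU {miou:.3f}")
print("\nmIOU averages polyp and background IoU; 1.0 is a perfect mask.")
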