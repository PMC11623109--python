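"""Train a reduced network on easy phantoms and score the held-out set.

A 10-epoch run of the desk-scale setup: 64x64 high-contrast phantoms,
filter schedule 8-128, BCE/Adam at learning rate 1e-3, batch size 8,
reduce-on-plateau. Takes a minute or two on one CPU. For the full
30-epoch benchmark use ultraseg.run_learning_surrogate.
"""

import ultraseg as us

train_set = us.surrogate_phantoms(32, seed=100)
val_set = us.surrogate_phantoms(4, seed=200)
test_set = us.surrogate_phantoms(8, seed=300)

config = us.ModelConfig(input_height=64, input_width=64,
                        filter_schedule=(8, 16, 32, 64, 128), seed=0)
hp = us.Hyperparams(epochs=10, batch_size=8, seed=0)

net, history = us.fit(us.build_network(config), train_set, val_set, hp)
print("epoch  train_loss  val_loss  val_dice      lr")
for row in history.to_rows():
    print(f"{row['epoch']:5d}  {row['train_loss']:10.4f}  "
          f"{row['val_loss']:8.4f}  {row['val_dice']:8.4f}  "
          f"{row['lr']:.2e}")

report = us.evaluate(net, test_set)
print(f"\nheld-out: Dice={report.dice:.4f} SEN={report.sen:.4f} "
      f"SPE={report.spe:.4f} AUC={report.auc:.4f}")
print("Dice is the overlap between predicted and true lesion masks; "
      "sensitivity/specificity are the pixel-wise true-positive and "
      "true-negative rates.")
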