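"""Train the desk-scale reduced model on synthetic data (about a minute on CPU).

Uses the width-reduced 13-block profile at 32x32 input with the standard
recipe (Adam, cosine annealing, label smoothing 0.1) for 20 epochs and
prints the loss/accuracy trajectory and the learned regularisation state.
For the full 30-epoch run used in the acceptance suite, raise `epochs`.
"""

from enetcaem.datapipe import stratified_split
from enetcaem.network import ArchitectureConfig, build_enet_caem
from enetcaem.synthetic import SynthSpec, generate_dataset
from enetcaem.training import TrainConfig, train

ds = generate_dataset(SynthSpec(n_per_class=40, image_size=32, seed=7))
tr, va, te = stratified_split(ds, seed=7)
print(f"train/val/test: {len(tr)}/{len(va)}/{len(te)} images at 32x32")

net = build_enet_caem(ArchitectureConfig.enet_caem_small(), seed=7)
cfg = TrainConfig(epochs=20, batch_size=32, lr_max=5e-3, seed=7)
best_state, hist = train(net, tr, va, cfg)

for e, (tl, vl, va_) in enumerate(zip(hist.train_loss, hist.val_loss, hist.val_accuracy)):
    print(f"epoch {e:2d}: train loss {tl:.3f}  val loss {vl:.3f}  val acc {va_:.2f}")
print(f"best val accuracy: {max(hist.val_accuracy):.2f}")
print(f"mixed-pool lambda after training: {hist.mixed_pool_lambda[-1]:.3f}")
print("(at 32x32 input the head feature map is 1x1, where max pooling equals")
print(" average pooling, so lambda stays at its 0.5 initialisation; train at")
print(" >= 64x64 input to see it move)")
print(f"per-block drop probabilities: {[round(p, 3) for p in hist.drop_probs[-1]]}")
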