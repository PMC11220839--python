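"""Train a reduced segmentation U-net on synthetic maps and segment a
held-out map.

Uses a small network (base filters 4) and very few windows so the script
finishes in a couple of minutes on one CPU; accuracies are correspondingly
modest compared with a full training run.
"""

from mapseg import (
    DatasetRanges,
    SyntheticSpec,
    TrainConfig,
    UNetConfig,
    build_unet,
    compute_metrics,
    generate_dataset,
    generate_structure,
    segment_map,
    simulate_phasing_map,
    train,
    true_mask_for,
)
from mapseg.solvent import expected_solvent

ranges = DatasetRanges(cell_edge=(48.0, 52.0), solvent_fraction=(0.45, 0.65),
                       phase_error_deg=(10.0, 30.0))
pairs, _ = generate_dataset(2, ranges, seed=1)

model = build_unet(UNetConfig(base_filters=4), seed=1)
cfg = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=4,
                  train_windows=64, val_windows=8, seed=1)
model, history = train(model, pairs, cfg)
for h in history:
    print(f"epoch {h['epoch']}: loss {h['loss']:.3f} "
          f"val accuracy {h['val_accuracy']:.3f}")

spec = SyntheticSpec(cell_edge=50.0, solvent_fraction=0.55,
                     phase_error_deg=25.0, seed=99)
sm = generate_structure(spec)
truth = true_mask_for(sm, spec)
grid = simulate_phasing_map(sm, spec)
probs, mask = segment_map(model, grid)
metrics = compute_metrics(mask, truth)

print(f"held-out voxel accuracy {metrics.accuracy:.3f}, "
      f"F1 {metrics.f1:.3f}" if metrics.f1 else "F1 undefined")
print(f"expected solvent content {expected_solvent(probs):.3f} "
      f"(true {truth.solvent_fraction:.3f})")
# The per-voxel mean of the solvent probabilities estimates the crystal's
# solvent content directly from the segmentation.
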