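"""Grad-CAM saliency: where does the classifier look?

Trains a quick model, then computes the elastography-branch saliency map of
one correctly classified test pair and quantifies how much of its mass
falls inside the tumor ROI.
"""

from pathlib import Path

import swecaf
from swecaf.train import TrainConfig, predict_records

cfg = swecaf.separable_cohort_config(n_tumors=24, image_size_px=48, seed=9)
cohort = swecaf.generate_cohort(cfg)
manifest = swecaf.label_and_split(cohort.records, swecaf.LabelingConfig(seed=9))
sets = {s: swecaf.dataset_from_cohort(cohort, manifest, s, 48) for s in ("train", "val", "test")}

spec = swecaf.ModelSpec(n_blocks=2, channels=(8, 16), input_hw=48)
model = swecaf.build_model(spec, "bimodal", seed=9)
swecaf.train(model, sets["train"], sets["val"], TrainConfig(learning_rate=1e-2, batch_size=16, epochs=10, seed=9))

test = sets["test"]
records = predict_records(model, test)
i = next(i for i, r in enumerate(records) if r.y == r.y_hat)
cls = "high" if test.y[i] == 1 else "low"
smap = swecaf.gradcam(model, test.grayscale[i], test.elastography[i], cls, "elastography")
mask = cohort.roi_masks[(test.tumor_ids[i], int(test.pair_indices[i]))]
print(f"pair {test.tumor_ids[i]}:{test.pair_indices[i]} predicted {cls!r} correctly")
print(f"mean saliency inside tumor ROI:  {smap.heatmap[mask].mean():.3f}")
print(f"mean saliency outside tumor ROI: {smap.heatmap[~mask].mean():.3f}")
print("higher inside means the stiffness signal in the tumor region drives the call")

out = Path("runs/example_gradcam.png")
out.parent.mkdir(exist_ok=True)
base = (test.elastography[i].transpose(1, 2, 0) * 255).astype("uint8")
swecaf.overlay(smap, base, out_path=out)
print(f"overlay written to {out}")
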