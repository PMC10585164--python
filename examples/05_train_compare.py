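"""Miniature five-loss comparison experiment.

Trains the same reduced U-Net under each loss on a small phantom cohort
(shared split and initialization, so differences isolate the loss),
evaluates the five metrics on the test subjects, and prints the summary
table. At this miniature scale (32x32, one epoch) the table demonstrates
the experiment's *shape*; meaningful metric values need the desk-scale
settings used by the acceptance script (and several minutes of CPU).
"""

from pathlib import Path
from tempfile import mkdtemp

from lobeseg.harness import ExperimentConfig, desk_scale_train_configs, run_experiment
from lobeseg.model import UNetConfig
from lobeseg.phantom import PhantomSpec

cfg = ExperimentConfig(
    phantom=PhantomSpec(image_size=(32, 32), n_subjects=10, slices_per_subject=2, seed=0),
    unet=UNetConfig((32, 32, 1), base_filters=2),
    train_configs=desk_scale_train_configs(epochs=1, seed=0),
    output_dir=Path(mkdtemp()) / "exp",
    seed=0,
)
results = run_experiment(cfg)
print((results.output_dir / "summary.csv").read_text())
print("Best value per column is flagged with '*' (highest, except lowest for HD).")
print(f"Artifacts (per-slice box-plot data, checkpoints, config snapshot) in "
      f"{results.output_dir}")
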