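"""Reproducible desk-scale experiments comparing SSFA with its supervised baseline.

One benchmark run generates the standard synthetic split (8 labeled / 32
unlabeled / 8 test 64x64 phantoms), trains a plain supervised UNet on the
labeled images (the baseline, also used to initialize FA maps), trains the
dual-network semi-supervised model with the same epoch budget, and evaluates
both on the held-out phantoms with the full metric panel.
"""

from __future__ import annotations

import numpy as np

from .famap import BINARIZE_THRESHOLD
from .metrics import evaluate_pair
from .synthetic import desk_dataset
from .training import TrainConfig, pretrain_supervised, ssfa_train, two_stage_inference


def run_desk_benchmark(seed: int, config: TrainConfig | None = None) -> dict:
    """Train baseline and SSFA from one seed; return mean test metrics.

    The seed drives the dataset, both network initializations and data
    shuffling, so a rerun is bit-identical.
    """
    data = desk_dataset(seed)
    if config is None:
        config = TrainConfig.desk_profile()
    config = TrainConfig(**{**config.__dict__,
                            "seed_net1": seed * 3 + 1,
                            "seed_net2": seed * 3 + 2,
                            "seed_data": seed * 3 + 3})
    labeled = [(p.image, p.mask) for p in data["labeled"]]
    unlabeled = [p.image for p in data["unlabeled"]]

    baseline, pre_hist = pretrain_supervised(labeled, config)
    state, history = ssfa_train(labeled, unlabeled, config,
                                init_predictor=baseline)

    rows = {"ssfa": [], "baseline": []}
    for ph in data["test"]:
        pred_ssfa = two_stage_inference(state, baseline, ph.image)
        pred_base = baseline.predict_mask(ph.image, threshold=BINARIZE_THRESHOLD)
        rows["ssfa"].append(evaluate_pair(pred_ssfa, ph.mask).as_dict())
        rows["baseline"].append(evaluate_pair(pred_base, ph.mask).as_dict())

    def mean_of(key, rs):
        return float(np.mean([r[key] for r in rs]))

    out = {"seed": int(seed), "n_test": len(data["test"]),
           "pretrain_loss": pre_hist, "val_dice": history["val_dice"][-1]}
    for model, rs in rows.items():
        out[model] = {k: mean_of(k, rs) for k in rs[0]}
    return out


def median_over_seeds(seeds, config: TrainConfig | None = None) -> dict:
    """Benchmark several seeds; report per-model median test FR and Dice."""
    runs = [run_desk_benchmark(s, config) for s in seeds]
    out = {"runs": runs}
    for model in ("ssfa", "baseline"):
        out[f"{model}_median_fr"] = float(np.median(
            [r[model]["fracture_rate"] for r in runs]))
        out[f"{model}_median_dice"] = float(np.median(
            [r[model]["dice"] for r in runs]))
    return out
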