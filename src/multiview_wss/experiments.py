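"""Self-contained reference experiments built from the library pieces.

The scaled recovery experiment is the package's standard end-to-end check:
a seeded synthetic cohort, curvature→stress view pairs, and a head-to-head
of the gated multi-view network, the plain UNet of equal base width, and a
constant-color baseline, all scored with the masked stress-normalized
metrics. Problem sizes default to a single-CPU budget: 40 geometries at
64×64 with a 90° view ring, and a compressed training schedule (small
batches at a large Adam step so both architectures reach convergence
within the 30-epoch cap).
"""

from __future__ import annotations

import logging
import time

from .evaluation import compare_models, constant_mean_predictor, evaluate_model
from .network import NetworkConfig, build_model
from .pipeline import RenderSettings, prepare_pairs, stage_seed
from .synthetic import build_dataset
from .training import TrainConfig, split_dataset, train

logger = logging.getLogger(__name__)

__all__ = ["scaled_recovery_experiment"]


def scaled_recovery_experiment(
    seed: int = 1,
    n_base: int = 8,
    variants_per_base: int = 4,
    n_synthetic_test: int = 10,
    resolution: int = 64,
    step_degrees: float = 90.0,
    mesh_resolution: tuple[int, int] = (48, 20),
    depth: int = 3,
    base_filters: int = 8,
    max_epochs: int = 30,
    patience: int = 5,
    learning_rate: float = 1e-3,
    batch_size: int = 4,
    modes: tuple[str, ...] = ("multiview", "vanilla_unet"),
) -> dict:
    """Train and evaluate the surrogate(s) on a fresh synthetic cohort.

    Returns a dictionary with one aggregate-metric block per trained mode,
    a ``constant`` block for the mean-color baseline, pair counts, and
    per-mode training history lengths. Every random draw derives from
    ``seed``.
    """
    t0 = time.time()
    manifest = build_dataset(n_base, variants_per_base,
                             seed=stage_seed(seed, "generate"))
    for rec in manifest:  # meshes need not outresolve the 64-px renders
        rec["params"]["axial_resolution"] = mesh_resolution[0]
        rec["params"]["circumferential_resolution"] = mesh_resolution[1]
    split = split_dataset(manifest, n_synthetic_test,
                          seed=stage_seed(seed, "split"))
    settings = RenderSettings(step_degrees=step_degrees,
                              capture_resolution=resolution,
                              output_resolution=resolution)
    train_pairs, test_pairs, codecs = prepare_pairs(manifest, split, settings)
    logger.info("rendered %d train / %d test pairs in %.0fs",
                len(train_pairs), len(test_pairs), time.time() - t0)

    tconf = TrainConfig(learning_rate=learning_rate, max_epochs=max_epochs,
                        early_stop_patience=patience, batch_size=batch_size,
                        seed=stage_seed(seed, "train"))
    out: dict = {
        "n_geometries": len(manifest),
        "n_train_pairs": len(train_pairs),
        "n_test_pairs": len(test_pairs),
        "resolution": resolution,
    }
    reports = []
    for mode in modes:
        config = NetworkConfig(depth=depth, base_filters=base_filters,
                               input_size=resolution, mode=mode)
        model = build_model(config, seed=stage_seed(seed, "init"))
        history = train(model, list(train_pairs), tconf)
        report = evaluate_model(model, test_pairs, codecs, label=mode)
        reports.append(report)
        out[mode] = report.aggregate
        out[f"{mode}_epochs"] = len(history["train_loss"])
        logger.info("%s: NMAE %.3f%% after %d epochs", mode,
                    report.aggregate["nmae_pct"], out[f"{mode}_epochs"])

    baseline = evaluate_model(constant_mean_predictor(train_pairs),
                              test_pairs, codecs, label="constant_mean")
    reports.append(baseline)
    out["constant"] = baseline.aggregate
    out["comparison"] = compare_models(reports).to_dict()
    out["wall_time_s"] = round(time.time() - t0, 1)
    return out
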