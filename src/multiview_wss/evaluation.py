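"""Effective (foreground-masked) image metrics on intensity and stress scales.

Predicted and target views are compared only over the pixels occupied by the
geometry. Differences are evaluated twice:

* on the **intensity scale** (images in [0, 1]), which feeds the effective
  peak signal-to-noise ratio EPSNR = 20·log10(MAX_I / √EMSE);
* on the **stress scale**, by decoding both images back to Pa through the
  colormap codec, which feeds the normalized errors
  NMAE = EMAE / max|S|, NMSE = EMSE / max|S|, NRMSE = ERMSE / max|S|,
  reported as percentages with max|S| the geometry's peak ground-truth
  stress (the codec's recorded range maximum).

NMSE divides a squared quantity by the first power of max|S| — the printed
convention of the source metric set; ``nmse_squared_norm=True`` switches to
the dimensionally consistent max|S|² normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .render import ColorMapCodec, ViewImage, MAX_INTENSITY
from .training import ViewPair, emse_loss

__all__ = [
    "MetricRow",
    "MetricReport",
    "effective_metrics",
    "evaluate_model",
    "compare_models",
    "constant_mean_predictor",
]

_METRIC_COLUMNS = ["nmae_pct", "nmse_pct", "nrmse_pct", "epsnr_db"]


@dataclass
class MetricRow:
    """Masked metrics for one predicted/target image pair."""

    geometry_id: str
    image_key: str
    n_pixels: int
    max_stress: float
    emae_pa: float
    emse_pa: float
    ermse_pa: float
    nmae_pct: float
    nmse_pct: float
    nrmse_pct: float
    emse_intensity: float
    epsnr_db: float


def effective_metrics(
    predicted: np.ndarray | ViewImage,
    target: np.ndarray | ViewImage,
    mask: np.ndarray | None = None,
    codec: ColorMapCodec | None = None,
    max_stress: float | None = None,
    nmse_squared_norm: bool = False,
    geometry_id: str = "",
    image_key: str = "",
) -> MetricRow:
    """Compute all effective metrics for one image pair.

    ``mask`` defaults to the target's own mask when views are passed. When a
    codec is given, stress values are recovered by decoding each masked
    pixel; otherwise intensities are treated as already stress-scaled (the
    toy-example path), with ``max_stress`` mandatory.
    """
    if isinstance(target, ViewImage):
        mask = target.mask if mask is None else mask
        target_px = target.pixels
    else:
        target_px = np.asarray(target, dtype=float)
    pred_px = predicted.pixels if isinstance(predicted, ViewImage) \
        else np.asarray(predicted, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_e = int(mask.sum())
    if n_e == 0:
        raise ValueError("empty mask")

    emse_intensity = emse_loss(pred_px, target_px, mask)

    if codec is not None:
        s_pred = codec.decode(pred_px[mask])
        s_true = codec.decode(target_px[mask])
        if max_stress is None:
            max_stress = float(max(abs(codec.range[0]), abs(codec.range[1])))
    else:
        # no codec: intensities are the stress scale; channels contribute
        # per-channel differences (each pixel's channel mean), matching the
        # loss convention
        if max_stress is None:
            raise ValueError("max_stress required when no codec is given")
        s_pred = pred_px[mask]
        s_true = target_px[mask]
    if max_stress <= 0:
        raise ValueError("max_stress must be positive")

    diff = s_pred - s_true
    emae = float(np.abs(diff).mean())
    emse = float((diff ** 2).mean())
    ermse = float(np.sqrt(emse))
    norm = max_stress ** 2 if nmse_squared_norm else max_stress
    epsnr = np.inf if emse_intensity == 0 else float(
        20.0 * np.log10(MAX_INTENSITY / np.sqrt(emse_intensity)))
    return MetricRow(
        geometry_id=geometry_id,
        image_key=image_key,
        n_pixels=n_e,
        max_stress=float(max_stress),
        emae_pa=emae,
        emse_pa=emse,
        ermse_pa=ermse,
        nmae_pct=100.0 * emae / max_stress,
        nmse_pct=100.0 * emse / norm,
        nrmse_pct=100.0 * ermse / max_stress,
        emse_intensity=emse_intensity,
        epsnr_db=epsnr,
    )


@dataclass
class MetricReport:
    """Per-image rows plus unweighted aggregate means over test images."""

    rows: list[MetricRow]
    label: str = "model"
    meta: dict = field(default_factory=dict)

    @property
    def aggregate(self) -> dict[str, float]:
        df = self.to_frame()
        return {c: float(df[c].mean()) for c in
                ["emae_pa", "ermse_pa", *_METRIC_COLUMNS]}

    def per_geometry(self) -> pd.DataFrame:
        df = self.to_frame()
        return df.groupby("geometry_id")[["emae_pa", *_METRIC_COLUMNS]].mean()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def save(self, path: str | Path) -> None:
        """CSV with per-image rows and one aggregate row, plus JSON."""
        path = Path(path)
        df = self.to_frame()
        agg = pd.DataFrame([{"geometry_id": "__aggregate__",
                             "image_key": "", **self.aggregate}])
        pd.concat([df, agg], ignore_index=True).to_csv(path, index=False)
        blob = {"label": self.label, "aggregate": self.aggregate,
                "n_images": len(self.rows),
                "n_geometries": int(df["geometry_id"].nunique()),
                "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(blob, indent=1))


def evaluate_model(
    model,
    test_pairs: list[ViewPair],
    codecs: dict[str, ColorMapCodec],
    label: str = "model",
    nmse_squared_norm: bool = False,
) -> MetricReport:
    """Run a predictor over test pairs and collect effective metrics.

    ``model`` is anything with a ``predict(batch)`` method or a callable on
    (B, H, W, 3) arrays; ``codecs`` maps geometry id to the codec its target
    views were rendered with (per-geometry stress range).
    """
    if not test_pairs:
        raise ValueError("empty test manifest")
    predictor = model.predict if hasattr(model, "predict") else model
    rows = []
    batch = 8
    for i in range(0, len(test_pairs), batch):
        chunk = test_pairs[i:i + batch]
        x = np.stack([p.input.pixels for p in chunk]).astype(np.float32)
        pred = np.asarray(predictor(x), dtype=float)
        for p, out in zip(chunk, pred):
            codec = codecs[p.geometry_id]
            rows.append(effective_metrics(
                out, p.target.pixels, p.input.mask, codec,
                nmse_squared_norm=nmse_squared_norm,
                geometry_id=p.geometry_id,
                image_key=f"{p.axis}{p.step:02d}"))
    return MetricReport(rows, label=label,
                        meta={"aggregation": "unweighted mean over images",
                              "nmse_squared_norm": nmse_squared_norm})


def compare_models(reports: list[MetricReport],
                   labels: list[str] | None = None) -> pd.DataFrame:
    """Side-by-side table (one row per model) of the aggregate metrics."""
    if not reports:
        raise ValueError("need at least one report")
    keys = [sorted((r.geometry_id, r.image_key) for r in rep.rows)
            for rep in reports]
    if any(k != keys[0] for k in keys[1:]):
        raise ValueError("reports evaluate different test manifests")
    labels = labels or [r.label for r in reports]
    rows = []
    for rep, lab in zip(reports, labels):
        agg = rep.aggregate
        rows.append({"model": lab, **{c: agg[c] for c in _METRIC_COLUMNS}})
    return pd.DataFrame(rows).set_index("model")


def comparison_text(table: pd.DataFrame) -> str:
    """Fixed-width rendering of a comparison table."""
    header = f"{'Model':<16}" + "".join(f"{c:>12}" for c in table.columns)
    lines = [header, "-" * len(header)]
    for name, row in table.iterrows():
        lines.append(f"{name:<16}" + "".join(f"{v:>12.4g}" for v in row.values))
    return "\n".join(lines)


def constant_mean_predictor(train_pairs: list[ViewPair]):
    """Baseline that always predicts the mean training foreground color.

    The weakest sensible predictor: any model that has learned geometry→
    stress structure must beat it by a wide margin.
    """
    total = np.zeros(3)
    count = 0
    for p in train_pairs:
        total += p.target.pixels[p.target.mask].sum(axis=0)
        count += int(p.target.mask.sum())
    mean_color = total / max(count, 1)

    def predict(batch: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(batch, dtype=float))
        out[...] = mean_color
        return out

    return predict
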