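"""File-format plumbing: PNG images, annotation/feature CSVs, report JSON.

All CSVs are comma-separated UTF-8 with a header row and "." decimals;
concentrations are always in ppm.  Images are written as 8-bit PNG.
Pixel coordinates in annotations are 0-based (row, col), origin top-left.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import RingblotError
from .simulate import SpotCrop, SyntheticMembrane

__all__ = [
    "to_uint8",
    "write_dataset",
    "read_annotations",
    "load_crops",
    "write_report",
    "save_scatter_plot",
]

logger = logging.getLogger("ringblot")

ANNOTATION_COLUMNS = [
    "membrane_id",
    "spot_id",
    "row",
    "col",
    "center_y_px",
    "center_x_px",
    "true_center_y_px",
    "true_center_x_px",
    "concentration_ppm",
    "replicate",
]


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a float image in [0, 1] to 8-bit."""
    return np.clip(np.round(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)


def write_dataset(
    membranes: list[SyntheticMembrane],
    crops: list[SpotCrop],
    out_dir: str | Path,
    config_dict: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write membrane and crop PNGs, the annotation CSV and a JSON manifest.

    The annotation CSV carries one row per spot; ``center_*_px`` are the
    nominal crop centers (what a reader of real photographs would know)
    while ``true_center_*_px`` record the simulator's ground truth.
    Returns the annotation CSV path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mem in membranes:
        iio.imwrite(out / f"membrane_{mem.membrane_id:02d}.png", to_uint8(mem.image))
    rows = []
    for crop in crops:
        iio.imwrite(out / f"spot_{crop.spot_id:03d}.png", to_uint8(crop.image))
        rows.append(
            {
                "membrane_id": crop.membrane_id,
                "spot_id": crop.spot_id,
                "row": -1,
                "col": -1,
                "center_y_px": crop.nominal_center[0],
                "center_x_px": crop.nominal_center[1],
                "true_center_y_px": crop.true_center[0],
                "true_center_x_px": crop.true_center[1],
                "concentration_ppm": crop.concentration,
                "replicate": crop.replicate,
            }
        )
    # recover grid positions from the membrane records
    pos = {s.spot_id: (s.grid_row, s.grid_col) for m in membranes for s in m.spots}
    for r in rows:
        r["row"], r["col"] = pos[r["spot_id"]]
    ann_path = out / "annotations.csv"
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(ann_path, index=False)
    manifest = {"seed": seed, "n_spots": len(crops), "n_membranes": len(membranes)}
    if config_dict is not None:
        manifest["config"] = config_dict
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    logger.info("wrote %d membranes and %d crops to %s", len(membranes), len(crops), out)
    return ann_path


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)


def load_crops(image_dir: str | Path, annotations: pd.DataFrame) -> list[SpotCrop]:
    """Load per-spot crops listed in an annotation table.

    Missing image files are a hard error listing the offending spot ids;
    unreadable (corrupted) files are logged and skipped so the remaining
    spots are still processed.
    """
    image_dir = Path(image_dir)
    missing = [
        int(row.spot_id)
        for row in annotations.itertuples()
        if not (image_dir / f"spot_{int(row.spot_id):03d}.png").exists()
    ]
    if missing:
        raise RingblotError(
            f"missing image files for annotated spots: {', '.join(map(str, missing))}"
        )
    crops: list[SpotCrop] = []
    for row in annotations.itertuples():
        spot_id = int(row.spot_id)
        path = image_dir / f"spot_{spot_id:03d}.png"
        try:
            img = np.asarray(iio.imread(path), dtype=float) / 255.0
        except Exception as exc:  # corrupted file: flag and continue
            logger.warning("skipping unreadable image %s: %s", path, exc)
            continue
        crops.append(
            SpotCrop(
                image=img,
                concentration=float(row.concentration_ppm),
                nominal_center=(int(row.center_y_px), int(row.center_x_px)),
                true_center=(float(row.true_center_y_px), float(row.true_center_x_px)),
                spot_id=spot_id,
                membrane_id=int(row.membrane_id),
                replicate=int(row.replicate),
            )
        )
    return crops


def write_report(result, out_dir: str | Path) -> Path:
    """Write report.json, predictions.csv and the predicted-vs-true scatter plot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    report_path.write_text(result.report_json())
    result.predictions_frame().to_csv(out / "predictions.csv", index=False)
    save_scatter_plot(result.report, out / "predicted_vs_true.png")
    return report_path


def save_scatter_plot(report, path: str | Path) -> None:
    """Predicted vs true concentration scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(report.labels, report.clean_predictions, s=25, alpha=0.8)
    lim = max(float(np.max(report.labels)), float(np.max(report.clean_predictions)), 1.0)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="identity")
    ax.set_xlabel("true concentration (ppm)")
    ax.set_ylabel("leave-one-out prediction (ppm)")
    ax.set_title(f"MAE {report.mae_overall:.2f} ppm over {len(report.labels)} spots")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
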