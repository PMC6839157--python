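"""Image/mask I/O, resizing, dataset manifests and run artifacts.

Conventions: grayscale images are float arrays in [0, 1]; masks are
{0, 1} arrays stored as 8-bit PNG with 255 = lesion, and any nonzero
pixel reads back as lesion (robust to external annotation tools that
store 1, 128 or 255).  Images resize bilinearly, masks nearest-
neighbour so labels stay binary.  Pixel coordinates are row-major and
0-based throughout.
"""

from __future__ import annotations

import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "load_and_resize",
    "read_image",
    "read_mask",
    "save_image_png",
    "save_mask_png",
    "write_dataset",
    "read_manifest",
    "write_run_artifacts",
]

MANIFEST_NAME = "manifest.csv"


def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF) as float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG; any nonzero pixel is lesion."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 0).astype(np.uint8)


def _resize(arr: np.ndarray, side: int, resample) -> np.ndarray:
    im = Image.fromarray(arr)
    return np.asarray(im.resize((side, side), resample=resample))


def load_and_resize(image_path, mask_path, side: int, center_crop: bool = False):
    """Load an image/mask pair and bring both to ``side`` x ``side``.

    The image is resized with bilinear interpolation and kept in
    [0, 1]; the mask with nearest neighbour, so the output is still
    binary.  ``center_crop`` first crops both to the centered square
    (for external clinical images with sidebars).
    """
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    image = read_image(image_path)
    mask = read_mask(mask_path)
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} shapes differ"
        )
    if mask.sum() == 0:
        raise ValueError(f"mask is empty: {mask_path}")
    if center_crop:
        h, w = image.shape
        s = min(h, w)
        top, left = (h - s) // 2, (w - s) // 2
        image = image[top : top + s, left : left + s]
        mask = mask[top : top + s, left : left + s]
    if image.shape != (side, side):
        image = _resize(image.astype(np.float32), side, Image.BILINEAR).astype(np.float64)
        mask = _resize(mask, side, Image.NEAREST)
    return np.clip(image, 0.0, 1.0), (mask > 0).astype(np.uint8)


def save_image_png(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)


def save_mask_png(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def write_dataset(items, out_dir, seeds=None, specs=None) -> pd.DataFrame:
    """Persist (image, mask, label) items as PNG pairs plus a manifest.

    Files follow ``img_%05d.png`` / ``msk_%05d.png``; the returned
    manifest (also written as CSV) records filenames, labels, seeds and
    lesion parameters when given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (image, mask, label) in enumerate(items):
        img_name, msk_name = f"img_{i:05d}.png", f"msk_{i:05d}.png"
        save_image_png(out_dir / img_name, image)
        save_mask_png(out_dir / msk_name, mask)
        row = {
            "image": img_name,
            "mask": msk_name,
            "label": label,
            "source": "simulated",
            "side": image.shape[0],
        }
        if seeds is not None:
            row["seed"] = seeds[i]
        if specs is not None:
            row.update({f"lesion_{k}": v for k, v in asdict(specs[i]).items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / MANIFEST_NAME, index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path)


def write_run_artifacts(run_dir, manifest=None, config=None, reports=None,
                        traces=None, seeds=None) -> Path:
    """Persist one run: manifest CSV, resolved config YAML, metric CSVs,
    loss-trace CSVs and a plain-text log with seeds and versions.

    Re-running with the same config and seeds reproduces every CSV.
    """
    run_dir = Path(run_dir)
    try:
        run_dir.mkdir(parents=True, exist_ok=True)
        probe = run_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"run directory not writable: {run_dir}") from exc
    if manifest is not None:
        manifest.to_csv(run_dir / MANIFEST_NAME, index=False)
    if config is not None:
        with open(run_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
    for name, df in (reports or {}).items():
        df.to_csv(run_dir / f"{name}.csv", index=True)
    for name, trace in (traces or {}).items():
        pd.DataFrame(
            {"iteration": trace.iterations, "loss": trace.losses}
        ).to_csv(run_dir / f"{name}_loss.csv", index=False)
    import busseg

    with open(run_dir / "run.log", "w") as fh:
        fh.write(f"busseg {busseg.__version__}\n")
        fh.write(f"python {platform.python_version()}\n")
        fh.write(f"numpy {np.__version__}\n")
        if seeds is not None:
            fh.write(f"seeds {seeds}\n")
    return run_dir
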