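"""Dataset folder layout and per-image output CSV.

The training layout is the standard classification-dataset tree::

    root/
      train/<class-label>/*.png
      test/<class-label>/*.png
      val/<class-label>/*.png

with a manifest CSV written beside each split. Class folder names are
the class labels with en-dashes replaced by ``-`` and spaces removed
(filesystem-portable). The per-image output CSV mirrors a batch
estimator's contract: image name, the 11 class confidences, and the
continuous FNU estimate — comma-separated UTF-8, header row, 6-decimal
confidences, 2-decimal FNU, byte-stable for identical inputs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from seston.binning import ClassScheme, DEFAULT_SCHEME
from seston.simulate import ImageRecord

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "test", "val")

APP_CSV_COLUMNS = ["image_name"] + [f"conf_{i}" for i in range(1, 12)] + ["fnu_estimate"]


@dataclass(frozen=True)
class AppOutputRow:
    """One row of the per-image output CSV."""

    image_name: str
    confidences: tuple  # 11 reals in [0, 1]
    fnu_estimate: float

    def validate(self) -> None:
        if len(self.confidences) != 11:
            raise ValueError("expected 11 confidences")
        if min(self.confidences) < 0.0 or max(self.confidences) > 1.0:
            raise ValueError("confidences outside [0, 1]")


def write_dataset_layout(
    manifests: dict[str, pd.DataFrame],
    records: list[ImageRecord],
    root_path,
    scheme: ClassScheme = DEFAULT_SCHEME,
    force: bool = False,
) -> Path:
    """Write images into the train/test/val class-folder tree.

    ``manifests`` maps split names to manifest frames (as produced by
    :func:`seston.binning.split_dataset`); every record referenced by a
    manifest must be present in ``records``. Refuses to write into an
    existing non-empty root unless ``force``.
    """
    root = Path(root_path)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"{root} exists and is not empty (use force=True)")
    by_id = {r.image_id: r for r in records}

    ids_seen: set[str] = set()
    for split, manifest in manifests.items():
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split name {split!r}")
        dup = ids_seen & set(manifest["image_id"])
        if dup:
            raise ValueError(f"image ids appear in multiple splits: {sorted(dup)[:5]}")
        ids_seen |= set(manifest["image_id"])

    for split in SPLIT_NAMES:
        manifest = manifests.get(split, pd.DataFrame(columns=["image_id"]))
        if manifest.empty:
            logger.warning("split %r is empty; creating empty class folders", split)
        for k in range(scheme.n_classes):
            (root / split / scheme.folder_name(k)).mkdir(parents=True, exist_ok=True)
        for _, row in manifest.iterrows():
            rec = by_id.get(row["image_id"])
            if rec is None:
                raise KeyError(f"manifest references unknown image_id {row['image_id']!r}")
            k = int(row["class_index"])
            out = root / split / scheme.folder_name(k) / f"{rec.image_id}.png"
            iio.imwrite(out, (np.clip(rec.pixels, 0, 1) * 255).round().astype(np.uint8))
        manifest.to_csv(root / f"{split}_manifest.csv", index=False)
    return root


def read_dataset_layout(
    root_path, scheme: ClassScheme = DEFAULT_SCHEME
) -> tuple[dict[str, pd.DataFrame], list[ImageRecord]]:
    """Rebuild manifests (and load images) from a layout tree.

    Class is inferred from the folder name; an unrecognized class folder
    raises. Prefers the manifest CSVs written beside the tree (they
    carry fnu_true); falls back to folder structure alone, in which case
    fnu_true is the class midpoint.
    """
    root = Path(root_path)
    folder_to_class = {scheme.folder_name(k): k for k in range(scheme.n_classes)}
    manifests: dict[str, pd.DataFrame] = {}
    records: list[ImageRecord] = []
    if not root.exists() or not any(root.iterdir()):
        logger.warning("dataset root %s is missing or empty", root)
        return {s: pd.DataFrame(columns=["image_id"]) for s in SPLIT_NAMES}, records

    for split in SPLIT_NAMES:
        split_dir = root / split
        manifest_csv = root / f"{split}_manifest.csv"
        stored = pd.read_csv(manifest_csv) if manifest_csv.exists() else None
        rows = []
        if split_dir.exists():
            for class_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
                if class_dir.name not in folder_to_class:
                    raise ValueError(f"unknown class folder name {class_dir.name!r}")
                k = folder_to_class[class_dir.name]
                for img_path in sorted(class_dir.glob("*.png")):
                    image_id = img_path.stem
                    pixels = np.asarray(iio.imread(img_path), dtype=float) / 255.0
                    if stored is not None and (stored["image_id"] == image_id).any():
                        fnu = float(
                            stored.loc[stored["image_id"] == image_id, "fnu_true"].iloc[0]
                        )
                    else:
                        fnu = scheme.midpoint(k)
                    records.append(
                        ImageRecord(image_id=image_id, pixels=pixels, fnu_true=fnu,
                                    metadata={"substrate": None, "secchi": None})
                    )
                    rows.append(
                        {
                            "image_id": image_id,
                            "fnu_true": fnu,
                            "class_index": k,
                            "class_label": scheme.labels[k],
                        }
                    )
        manifests[split] = (
            stored if stored is not None else pd.DataFrame(rows, columns=[
                "image_id", "fnu_true", "class_index", "class_label"])
        )
    return manifests, records


def write_app_csv(rows: list[AppOutputRow], path) -> Path:
    """Write the per-image output CSV (header always present).

    Byte-stable: fixed column order, 6-decimal confidences, 2-decimal
    FNU, ``\\n`` line endings.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(APP_CSV_COLUMNS)
        for row in rows:
            row.validate()
            writer.writerow(
                [row.image_name]
                + [f"{c:.6f}" for c in row.confidences]
                + [f"{row.fnu_estimate:.2f}"]
            )
    return path


def read_app_csv(path) -> list[AppOutputRow]:
    """Read back a per-image output CSV."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != APP_CSV_COLUMNS:
            raise ValueError(f"unexpected CSV columns: {reader.fieldnames}")
        for rec in reader:
            out.append(
                AppOutputRow(
                    image_name=rec["image_name"],
                    confidences=tuple(float(rec[f"conf_{i}"]) for i in range(1, 12)),
                    fnu_estimate=float(rec["fnu_estimate"]),
                )
            )
    return out
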