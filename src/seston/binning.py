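"""FNU class binning and stratified dataset splitting.

Turbidity in 0-55 FNU is discretized into 11 ordinal classes with narrow
bins at the clear end of the range (where small absolute changes matter
most) and progressively wider bins toward 55 FNU. Bins are half-open
``[lower_k, lower_{k+1})``; the final bin is closed at 55 so the scheme
covers the instrument range exhaustively. Printed class labels carry
two-decimal uppers (e.g. "0-0.49") that reflect rounding, not gaps: a
value such as 0.497 belongs to class 0 under the half-open convention,
and a value equal to a printed-next lower bound (0.5) belongs to the
higher class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: (lower, printed upper) of each FNU class, in class-index order.
_DEFAULT_BOUNDS = [
    (0.0, 0.49),
    (0.5, 0.99),
    (1.0, 2.49),
    (2.5, 4.99),
    (5.0, 9.99),
    (10.0, 14.99),
    (15.0, 20.99),
    (21.0, 28.99),
    (29.0, 36.99),
    (37.0, 44.99),
    (45.0, 55.0),
]


def _default_labels(bounds) -> list[str]:
    out = []
    for lo, hi in bounds:
        lo_s = f"{lo:g}"
        hi_s = f"{hi:g}"
        out.append(f"{lo_s}-{hi_s}")
    return out


@dataclass(frozen=True)
class ClassScheme:
    """Ordered FNU class intervals with labels.

    Parameters
    ----------
    boundaries : list of (lower, upper)
        Printed interval bounds in FNU, strictly increasing lowers,
        first lower 0, last upper 55.
    labels : list of str
        One label per class; used verbatim (with ``-`` separators) as
        dataset folder names.
    """

    boundaries: tuple = tuple(_DEFAULT_BOUNDS)
    labels: tuple = tuple(_default_labels(_DEFAULT_BOUNDS))

    def __post_init__(self):
        if len(self.boundaries) != 11:
            raise ValueError(f"expected 11 class intervals, got {len(self.boundaries)}")
        if len(self.labels) != len(self.boundaries):
            raise ValueError("labels and boundaries length mismatch")
        lowers = [b[0] for b in self.boundaries]
        if any(b >= a for a, b in zip(lowers[1:], lowers[:-1])):
            raise ValueError("class lower bounds must be strictly increasing")
        if lowers[0] != 0.0:
            raise ValueError("first class must start at 0 FNU")
        if self.boundaries[-1][1] != 55.0:
            raise ValueError("last class must end at 55 FNU")
        for (lo, hi) in self.boundaries:
            if hi <= lo:
                raise ValueError(f"empty class interval ({lo}, {hi})")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries)

    @property
    def lowers(self) -> np.ndarray:
        return np.array([b[0] for b in self.boundaries])

    def effective_interval(self, k: int) -> tuple[float, float]:
        """Half-open coverage interval of class ``k``: [lower_k, lower_{k+1}),
        with the last class closed at 55."""
        lo = self.boundaries[k][0]
        hi = self.boundaries[k + 1][0] if k + 1 < self.n_classes else 55.0
        return lo, hi

    def midpoint(self, k: int) -> float:
        lo, hi = self.effective_interval(k)
        return 0.5 * (lo + hi)

    def folder_name(self, k: int) -> str:
        return self.labels[k].replace("–", "-").replace(" ", "")

    def to_config(self) -> str:
        """Serialize to a plain-text key=value block."""
        lines = [f"n_classes={self.n_classes}"]
        for k, ((lo, hi), lab) in enumerate(zip(self.boundaries, self.labels)):
            lines.append(f"class_{k}={lo},{hi},{lab}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ClassScheme":
        bounds, labels = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("n_classes"):
                continue
            _, val = line.split("=", 1)
            lo, hi, lab = val.split(",", 2)
            bounds.append((float(lo), float(hi)))
            labels.append(lab)
        return cls(tuple(bounds), tuple(labels))


DEFAULT_SCHEME = ClassScheme()


def fnu_to_class(fnu: float, scheme: ClassScheme = DEFAULT_SCHEME) -> int:
    """Map a turbidity value in FNU to its class index (0..10).

    Classes are half-open on their effective lowers; the last class is
    closed at 55. Values outside [0, 55] raise ``ValueError``.
    """
    if not np.isfinite(fnu) or fnu < 0.0 or fnu > 55.0:
        raise ValueError(f"fnu {fnu!r} outside the instrument range [0, 55]")
    # searchsorted over lowers: right side so a value equal to a lower
    # bound falls in the higher class.
    k = int(np.searchsorted(scheme.lowers, fnu, side="right")) - 1
    return min(k, scheme.n_classes - 1)


def classes_for(fnus, scheme: ClassScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Vectorized :func:`fnu_to_class`."""
    arr = np.asarray(fnus, dtype=float)
    if arr.size and (np.min(arr) < 0.0 or np.max(arr) > 55.0 or not np.all(np.isfinite(arr))):
        raise ValueError("fnu values outside [0, 55]")
    k = np.searchsorted(scheme.lowers, arr, side="right") - 1
    return np.minimum(k, scheme.n_classes - 1).astype(int)


def split_dataset(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.75, 0.15, 0.10),
    seed: int = 0,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> dict[str, pd.DataFrame]:
    """Stratified train/test/val split of a manifest.

    Parameters
    ----------
    manifest : DataFrame
        Must carry ``image_id`` and either ``class_index`` or ``fnu_true``.
    fractions : (train, test, val)
        Positive fractions summing to 1 (within 1e-6).
    seed : int
        Shuffle seed; identical seeds give identical partitions.

    Returns
    -------
    dict with keys ``train``, ``test``, ``val``; the three frames are
    disjoint on ``image_id`` and their union is the input. Per-class
    counts match the target fractions within one image (largest-remainder
    apportionment).
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    if manifest["image_id"].duplicated().any():
        raise ValueError("duplicate image_id in manifest")

    if "class_index" in manifest.columns:
        cls = manifest["class_index"].to_numpy()
    else:
        cls = classes_for(manifest["fnu_true"].to_numpy(), scheme)

    rng = np.random.default_rng(seed)
    parts: dict[str, list[pd.DataFrame]] = {"train": [], "test": [], "val": []}
    names = ("train", "test", "val")
    for k in range(scheme.n_classes):
        idx = np.flatnonzero(cls == k)
        if idx.size == 0:
            logger.warning("class %d (%s) is empty; skipped in stratification", k, scheme.labels[k])
            continue
        idx = rng.permutation(idx)
        # largest-remainder apportionment of idx.size over the fractions
        quotas = fr * idx.size
        counts = np.floor(quotas).astype(int)
        rem = idx.size - counts.sum()
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:rem]] += 1
        splits = np.split(idx, np.cumsum(counts)[:-1])
        for name, part in zip(names, splits):
            parts[name].append(manifest.iloc[part])

    empty = manifest.iloc[:0]
    return {
        name: (pd.concat(chunks, ignore_index=True) if chunks else empty.copy())
        for name, chunks in parts.items()
    }
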