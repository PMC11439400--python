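"""Synthetic underwater turbid-scene generator.

Renders small RGB scenes whose appearance degrades with turbidity under
a single-scattering image-formation model,

    observed = direct * T + veiling * (1 - T),        T = exp(-c * d)

where ``T`` is the per-pixel, per-channel transmission along the line of
sight, ``d`` the scene distance in cm, and ``c`` the beam attenuation
coefficient (1/cm). Attenuation is taken proportional to nephelometric
turbidity, ``c(FNU) = c0 + k * FNU`` per channel, optionally increased
by dissolved-ink tints; ``c0`` defaults to 0 so a 0-FNU, tint-free,
noise-free render reproduces the clean background exactly. Veiling
light is the light scattered into the camera path by the water column;
it washes out contrast as turbidity rises, which is exactly the signal
the downstream classifier learns.

Scenes may include a black/white quadrant Secchi disk (default 4.2 cm
diameter at 12 or 23 cm from the camera) whose quadrant contrast decays
as exp(-c*d) shrinks — the classic visual clarity standard. Backgrounds
emulate the habitats of the reference collection: gravel or sand
substrate shot obliquely (a linear distance ramp), open water (constant
distance), or vegetation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from seston.binning import ClassScheme, DEFAULT_SCHEME
from seston import protocol

#: attenuation slope per channel, 1/(cm * FNU). Red attenuates fastest in
#: turbid water; values chosen so the Secchi disc is near-invisible at
#: 55 FNU at 23 cm (T ~ exp(-0.0036*55*23) ~ 0.01).
DEFAULT_K = (0.0040, 0.0036, 0.0032)

#: clear-water attenuation offset, 1/cm (0 so FNU=0 is perfectly clear).
DEFAULT_C0 = (0.0, 0.0, 0.0)

#: attenuation added per unit tint concentration (mL/L analog), 1/cm,
#: per ink channel weight.
TINT_ATTENUATION = 2.0

BACKGROUND_KINDS = ("gravel", "sand", "open_water", "vegetation")


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for one synthetic underwater scene.

    Attributes
    ----------
    fnu : float
        Turbidity in FNU, 0-55.
    secchi_present : bool
        Whether the quadrant Secchi disk is in frame.
    secchi_distance_cm : float, optional
        Camera-to-disk distance, one of {12, 23}; required iff the disk
        is present.
    secchi_diameter_cm : float
        Disk diameter, default 4.2 cm.
    tint : (float, float, float)
        Per-channel ink concentration analog (mL/L), >= 0.
    background_kind : str
        One of gravel, sand, open_water, vegetation.
    image_size_px : (int, int)
        Width, height of the render.
    noise_sd : float
        Additive Gaussian sensor noise sd (on the [0, 1] intensity
        scale), applied after compositing and clipped to range.
    seed : int
        Seed for background texture and noise; equal (spec, seed) gives
        bit-identical output.
    """

    fnu: float = 0.0
    secchi_present: bool = False
    secchi_distance_cm: Optional[float] = None
    secchi_diameter_cm: float = protocol.SECCHI_DIAMETER_CM
    tint: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_kind: str = "open_water"
    image_size_px: tuple[int, int] = (64, 64)
    noise_sd: float = 0.0
    seed: int = 0
    attenuation_k: tuple[float, float, float] = DEFAULT_K
    attenuation_c0: tuple[float, float, float] = DEFAULT_C0
    veiling_rgb: tuple[float, float, float] = (0.55, 0.55, 0.55)

    def validate(self) -> None:
        if not np.isfinite(self.fnu) or not (0.0 <= self.fnu <= 55.0):
            raise ValueError(f"fnu must be in [0, 55], got {self.fnu!r}")
        if self.secchi_present and self.secchi_distance_cm is None:
            raise ValueError("secchi_distance_cm required when secchi_present")
        if not self.secchi_present and self.secchi_distance_cm is not None:
            raise ValueError("secchi_distance_cm given but secchi_present is False")
        if self.secchi_present and self.secchi_distance_cm <= 0:
            raise ValueError("secchi_distance_cm must be positive")
        if self.secchi_diameter_cm <= 0:
            raise ValueError("secchi_diameter_cm must be positive")
        if any(t < 0 for t in self.tint):
            raise ValueError("tint concentrations must be >= 0")
        if self.background_kind not in BACKGROUND_KINDS:
            raise ValueError(
                f"background_kind must be one of {BACKGROUND_KINDS}, got {self.background_kind!r}"
            )
        w, h = self.image_size_px
        if w <= 0 or h <= 0:
            raise ValueError("image_size_px dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ImageRecord:
    """One rendered (or loaded) image with its ground truth and metadata."""

    image_id: str
    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    fnu_true: float
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values outside nominal [0, 1] range")
        if not (0.0 <= self.fnu_true <= 55.0):
            raise ValueError("fnu_true outside [0, 55]")


def _background(kind: str, w: int, h: int, rng: np.random.Generator) -> np.ndarray:
    """Clean background reflectance (H x W x 3 in [0, 1]), seeded texture."""
    yy = np.linspace(0.0, 1.0, h)[:, None] * np.ones((1, w))
    if kind == "open_water":
        base = np.stack(
            [0.18 + 0.10 * yy, 0.30 + 0.12 * yy, 0.38 + 0.12 * yy], axis=-1
        )
        base += rng.normal(0.0, 0.005, size=base.shape)
    elif kind == "gravel":
        # blocky speckle: low-res random tiles upsampled by repetition
        tiles = rng.uniform(0.15, 0.75, size=(max(h // 4, 1), max(w // 4, 1)))
        tex = np.kron(tiles, np.ones((4, 4)))[:h, :w]
        base = np.stack([tex * 0.95, tex * 0.90, tex * 0.85], axis=-1)
    elif kind == "sand":
        tex = 0.55 + 0.08 * rng.standard_normal((h, w))
        # smooth with a small box filter for grain correlation
        ker = np.ones(3) / 3.0
        tex = np.apply_along_axis(lambda r: np.convolve(r, ker, mode="same"), 1, tex)
        base = np.stack([tex * 1.05, tex * 0.95, tex * 0.75], axis=-1)
    elif kind == "vegetation":
        tex = 0.30 + 0.15 * rng.standard_normal((h, w))
        base = np.stack([tex * 0.55, tex * 1.10, tex * 0.50], axis=-1)
    else:  # pragma: no cover - guarded by SceneSpec.validate
        raise ValueError(kind)
    return np.clip(base, 0.0, 1.0)


def _distance_map_cm(kind: str, w: int, h: int) -> np.ndarray:
    """Per-pixel scene distance in cm.

    Open water sits at a constant 30 cm; substrate/vegetation scenes are
    shot obliquely, so distance ramps linearly from 10 cm at the bottom
    of the frame to 60 cm at the top.
    """
    if kind == "open_water":
        return np.full((h, w), 30.0)
    ramp = np.linspace(60.0, 10.0, h)[:, None]
    return np.broadcast_to(ramp, (h, w)).copy()


def _secchi_mask(w: int, h: int, diameter_cm: float, distance_cm: float):
    """Disk pixel mask plus black/white quadrant pattern.

    Angular size follows a pinhole model with focal length equal to the
    frame width, so the apparent radius in pixels is
    ``w * (diameter / 2) / distance``.
    """
    radius_px = w * (diameter_cm / 2.0) / distance_cm
    cx, cy = w / 2.0, h / 2.0
    x = np.arange(w)[None, :] - cx
    y = np.arange(h)[:, None] - cy
    inside = (x**2 + y**2) <= radius_px**2
    # alternating quadrants: white where x and y have the same sign
    white = (x >= 0) == (y >= 0)
    return inside, white


def render_scene(spec: SceneSpec) -> ImageRecord:
    """Render one synthetic scene under the attenuation/veiling model.

    Deterministic given ``spec`` (including its seed). Raises
    ``ValueError`` naming the offending field for an invalid spec.
    """
    spec.validate()
    w, h = spec.image_size_px
    rng = np.random.default_rng(spec.seed)

    direct = _background(spec.background_kind, w, h, rng)
    dist = _distance_map_cm(spec.background_kind, w, h)

    if spec.secchi_present:
        inside, white = _secchi_mask(w, h, spec.secchi_diameter_cm, spec.secchi_distance_cm)
        disk = np.where(white, 0.95, 0.05)
        for ch in range(3):
            direct[..., ch] = np.where(inside, disk, direct[..., ch])
        dist = np.where(inside, spec.secchi_distance_cm, dist)

    c0 = np.asarray(spec.attenuation_c0)
    k = np.asarray(spec.attenuation_k)
    tint = np.asarray(spec.tint)
    c = c0 + k * spec.fnu + TINT_ATTENUATION * tint  # per-channel, 1/cm

    veil = np.asarray(spec.veiling_rgb, dtype=float).copy()
    if tint.sum() > 0:
        # inks color the water column: veiling shifts toward the
        # channels the ink does not absorb
        absorb = tint / max(tint.sum(), 1e-12)
        veil = np.clip(veil * (1.0 - 0.5 * absorb), 0.0, 1.0)

    transmission = np.exp(-c[None, None, :] * dist[..., None])
    observed = direct * transmission + veil[None, None, :] * (1.0 - transmission)

    if spec.noise_sd > 0:
        observed = observed + rng.normal(0.0, spec.noise_sd, size=observed.shape)
    observed = np.clip(observed, 0.0, 1.0)

    rec = ImageRecord(
        image_id=f"scene_fnu{spec.fnu:06.2f}_seed{spec.seed}",
        pixels=observed,
        fnu_true=spec.fnu,
        metadata={
            "flowing": spec.background_kind == "gravel",
            "secchi": spec.secchi_present,
            "secchi_distance_cm": spec.secchi_distance_cm,
            "substrate": spec.background_kind,
            "tint": tuple(spec.tint),
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
            "camera": "synthetic",
        },
    )
    rec.validate()
    return rec


def secchi_contrast(record: ImageRecord, spec: SceneSpec) -> float:
    """Michelson contrast between the Secchi disk's white and black quadrants.

    ``(W - B) / (W + B)`` on quadrant mean luminance; the closed-form
    expectation under the render model is proportional to the
    transmission ``exp(-c * d_secchi)``.
    """
    if not spec.secchi_present:
        raise ValueError("spec has no Secchi disk")
    w, h = spec.image_size_px
    inside, white = _secchi_mask(w, h, spec.secchi_diameter_cm, spec.secchi_distance_cm)
    lum = record.pixels.mean(axis=-1)
    w_mean = lum[inside & white].mean()
    b_mean = lum[inside & ~white].mean()
    denom = w_mean + b_mean
    return float((w_mean - b_mean) / denom) if denom > 0 else 0.0


def generate_dataset(
    n_per_class: int,
    scheme: ClassScheme = DEFAULT_SCHEME,
    mix: Optional[dict] = None,
    seed: int = 0,
    image_size_px: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Generate a class-balanced synthetic dataset plus its manifest.

    FNU values are sampled uniformly within each class's effective
    interval, ``n_per_class`` per class. The ``mix`` dict controls
    protocol proportions: ``secchi`` (fraction of frames with the disk,
    default 0.38 as in the reference collection), ``tint`` (fraction of
    tinted frames, default 0.3), ``backgrounds`` (sequence to sample
    uniformly, default all four kinds). Fully reproducible under
    ``seed``.

    Returns
    -------
    (records, manifest)
        Manifest columns: image_id, fnu_true, class_index, class_label,
        secchi, flowing, substrate, seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    mix = dict(mix or {})
    secchi_frac = mix.get("secchi", protocol.SECCHI_FRACTION)
    tint_frac = mix.get("tint", 0.3)
    backgrounds = tuple(mix.get("backgrounds", BACKGROUND_KINDS))

    rng = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    rows = []
    for k in range(scheme.n_classes):
        lo, hi = scheme.effective_interval(k)
        for i in range(n_per_class):
            fnu = float(rng.uniform(lo, hi))
            secchi = bool(rng.random() < secchi_frac)
            tinted = rng.random() < tint_frac
            if tinted:
                # one ink channel dominant, concentration in protocol steps
                conc = protocol.TINT_INCREMENT_ML_PER_L * rng.integers(1, 6)
                channel = rng.integers(0, 3)
                tint = [0.0, 0.0, 0.0]
                tint[channel] = float(conc)
                tint = tuple(tint)
            else:
                tint = (0.0, 0.0, 0.0)
            spec = SceneSpec(
                fnu=fnu,
                secchi_present=secchi,
                secchi_distance_cm=(
                    float(rng.choice(protocol.SECCHI_DISTANCES_CM)) if secchi else None
                ),
                tint=tint,
                background_kind=str(rng.choice(backgrounds)),
                image_size_px=image_size_px,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = render_scene(spec)
            rec.image_id = f"c{k:02d}_{i:04d}"
            records.append(rec)
            rows.append(
                {
                    "image_id": rec.image_id,
                    "fnu_true": fnu,
                    "class_index": k,
                    "class_label": scheme.labels[k],
                    "secchi": secchi,
                    "flowing": rec.metadata["flowing"],
                    "substrate": rec.metadata["substrate"],
                    "seed": rec.metadata["seed"],
                }
            )
    return records, pd.DataFrame(rows)
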