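"""Seeded synthetic data: transform test phantoms and two-class cohorts.

The cohort generator emulates the structure of a cross-sectional brain
MRI study of Alzheimer's disease (AD) patients versus healthy controls
(HC): per-subject stacks of axial PNG slices plus a ``subjects.csv``
table with demographics.  The AD signature is morphological rather than
photometric -- an enlarged dark central region (ventricular enlargement)
and a thinned bright cortical rim (atrophy), both scaled by
``effect_size`` -- so a classifier must pick up texture/shape changes,
not mean brightness.  At ``effect_size = 0`` the two classes are drawn
from identical distributions.

Demographics echo a typical elderly cohort: AD subjects get lower
mini-mental state examination (MMSE) scores (mean 21.67, SD 3.75) and a
clinical dementia rating (CDR) of 1; controls MMSE 28.95 +/- 1.20 and
CDR 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["PhantomSpec", "CohortSpec", "make_phantom", "make_cohort",
           "cohort_arrays"]


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic test image: impulse, constant, grating or noise."""

    kind: str
    size: tuple[int, int] = (64, 64)
    orientation: float = 0.0       # degrees, gratings only
    frequency: float = 0.1         # cycles / pixel, gratings only
    shift: tuple[int, int] = (0, 0)  # (dy, dx) translation
    seed: int = 0
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.size[0] < 1 or self.size[1] < 1:
            raise ValueError(f"size must be positive, got {self.size}")
        if self.kind == "grating" and not (0.0 < self.frequency <= 0.5):
            raise ValueError(
                f"grating frequency must be in (0, 0.5], got {self.frequency}"
            )


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom described by `spec` as a 2-D float array."""
    rows, cols = spec.size
    dy, dx = spec.shift
    if spec.kind == "impulse":
        img = np.zeros((rows, cols))
        img[(rows // 2 + dy) % rows, (cols // 2 + dx) % cols] = spec.value
        return img
    if spec.kind == "constant":
        return np.full((rows, cols), float(spec.value))
    if spec.kind == "grating":
        yy, xx = np.mgrid[0:rows, 0:cols]
        t = np.deg2rad(spec.orientation)
        phase = 2.0 * np.pi * spec.frequency * (
            (xx - dx) * np.cos(t) + (yy - dy) * np.sin(t)
        )
        return spec.value * np.cos(phase)
    if spec.kind == "noise":
        rng = np.random.default_rng(spec.seed)
        img = rng.normal(0.0, 1.0, size=(rows, cols))
        return np.roll(img, (dy, dx), axis=(0, 1))
    raise ValueError(f"unknown phantom kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic two-class cohort.

    The defaults reproduce the reference cohort structure: 28 AD and 98
    HC subjects, 32 slices of 176x208 pixels each.  ``effect_size``
    scales the AD morphology change (1.0 is a clearly visible but noisy
    difference; 0 makes the classes exchangeable); ``noise_sd`` is the
    per-pixel Gaussian noise on a [0, 1] intensity scale.
    """

    n_ad: int = 28
    n_hc: int = 98
    n_slices: int = 32
    slice_size: tuple[int, int] = (176, 208)
    effect_size: float = 1.0
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 1 or self.n_hc < 1:
            raise ValueError("subject counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _subject_stack(spec: CohortSpec, rng: np.random.Generator, is_ad: bool) -> np.ndarray:
    """Render one subject's slice stack in [0, 1].

    A smooth ellipsoidal "brain" whose cross-section waxes and wanes
    through the stack, with a bright cortical rim and a dark central
    ventricular region.  Subject-level variability: overall scale, axis
    ratio, rotation and centre jitter.  The AD morphology (severity drawn
    around ``effect_size``) dilates the ventricle and thins the rim.
    """
    rows, cols = spec.slice_size
    severity = 0.0
    if is_ad and spec.effect_size > 0:
        severity = max(0.0, rng.normal(spec.effect_size, 0.15 * spec.effect_size))
    # subject anatomy
    scale = rng.normal(1.0, 0.03)
    ratio = rng.normal(1.0, 0.04)
    angle = rng.normal(0.0, 0.05)
    cy = rows / 2 + rng.normal(0.0, 1.5)
    cx = cols / 2 + rng.normal(0.0, 1.5)
    vent_scale = 1.0 + 0.30 * severity + rng.normal(0.0, 0.05)
    rim_width = max(0.02, 0.16 * (1.0 - 0.35 * min(severity, 2.0) / 2.0)
                    + rng.normal(0.0, 0.01))

    yy, xx = np.mgrid[0:rows, 0:cols]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ((xx - cx) * ca + (yy - cy) * sa) / (0.44 * cols * scale)
    v = (-(xx - cx) * sa + (yy - cy) * ca) / (0.42 * rows * scale * ratio)

    stack = np.empty((spec.n_slices, rows, cols))
    for s in range(spec.n_slices):
        z = (s - (spec.n_slices - 1) / 2) / (spec.n_slices / 2 + 1)
        prof = np.sqrt(max(1e-3, 1.0 - z * z))  # slice-wise brain extent
        r = np.sqrt((u / prof) ** 2 + (v / prof) ** 2)
        brain = 0.5 * (1.0 - np.tanh((r - 1.0) / 0.04))
        # ventricle: central dark ellipse, larger mid-stack and with severity
        rv = r / (0.33 * vent_scale * (0.6 + 0.4 * prof))
        vent = 0.5 * (1.0 - np.tanh((rv - 1.0) / 0.10))
        # cortical rim: bright band just inside the outer boundary
        rim = np.exp(-((r - (1.0 - rim_width)) ** 2) / (2 * (rim_width / 2) ** 2))
        img = brain * (0.55 + 0.35 * rim) * (1.0 - 0.75 * vent)
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[s] = np.clip(img, 0.0, 1.0)
    return stack


def _demographics(rng: np.random.Generator, is_ad: bool) -> dict:
    if is_ad:
        return {
            "age": round(float(np.clip(rng.normal(77.75, 6.99), 60, 96)), 1),
            "gender": "M" if rng.random() < 9 / 28 else "F",
            "education": int(np.clip(round(rng.normal(2.57, 1.31)), 1, 5)),
            "ses": int(np.clip(round(rng.normal(2.87, 1.29)), 1, 5)),
            "mmse": int(np.clip(round(rng.normal(21.67, 3.75)), 0, 30)),
            "cdr": 1.0,
        }
    return {
        "age": round(float(np.clip(rng.normal(75.91, 8.98), 60, 96)), 1),
        "gender": "M" if rng.random() < 26 / 98 else "F",
        "education": int(np.clip(round(rng.normal(3.26, 1.31)), 1, 5)),
        "ses": int(np.clip(round(rng.normal(2.51, 1.09)), 1, 5)),
        "mmse": int(np.clip(round(rng.normal(28.95, 1.20)), 0, 30)),
        "cdr": 0.0,
    }


def cohort_arrays(spec: CohortSpec):
    """Yield ``(subject_id, label, stack, demographics)`` deterministically.

    AD subjects come first (ids ``AD_000`` ...), then HC.  Each subject's
    random stream is spawned independently from ``spec.seed``, so any
    subject is reproducible in isolation and the cohort is reproducible
    regardless of consumption order.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_ad + spec.n_hc)
    for i, ss in enumerate(children):
        is_ad = i < spec.n_ad
        label = "AD" if is_ad else "HC"
        sid = f"{label}_{i if is_ad else i - spec.n_ad:03d}"
        rng = np.random.default_rng(ss)
        stack = _subject_stack(spec, rng, is_ad)
        demo = _demographics(rng, is_ad)
        yield sid, label, stack, demo


def make_cohort(spec: CohortSpec, out_dir: str | Path, force: bool = False) -> Path:
    """Write the cohort to `out_dir` as 8-bit PNG stacks plus subjects.csv."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass force=True to "
            f"overwrite)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for sid, label, stack, demo in cohort_arrays(spec):
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        for s in range(stack.shape[0]):
            img = np.round(stack[s] * 255.0).astype(np.uint8)
            Image.fromarray(img, mode="L").save(sdir / f"slice_{s:03d}.png")
        records.append({"subject_id": sid, "label": label, **demo})
    pd.DataFrame(records).to_csv(out_dir / "subjects.csv", index=False)
    return out_dir
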