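"""Per-subject wavelet feature extraction.

Each subject contributes a stack of axial brain-slice images.  The
default protocol mirrors a multi-slice texture pipeline: keep the 32
centre slices, resize each to 256x256, intensity-rescale to [0, 1], run
a 5-level DTCWT and flatten the six level-5 complex subbands (real parts
then imaginary parts, per subband) into 768 features per slice, i.e.
6 x 8 x 8 x 2.  Concatenating the 32 slices gives a 24,576-long row per
subject; a cohort of subjects stacks into the feature matrix handed to
the PCA/classifier stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .dtcwt import ORIENTATIONS, FilterSet, default_filter_set, forward

__all__ = [
    "SubjectRecord",
    "FeatureMatrix",
    "FeatureConfig",
    "select_center_slices",
    "preprocess_slice",
    "slice_features",
    "build_feature_matrix",
    "build_feature_matrix_from_arrays",
    "load_subjects",
    "write_features",
    "read_features",
]

#: label of the positive (patient) class and the negative (control) class
AD, HC = "AD", "HC"


@dataclass
class SubjectRecord:
    """One subject: identifier, diagnosis label and ordered slice paths."""

    subject_id: str
    label: str
    slice_paths: list[Path]
    demographics: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in (AD, HC):
            raise ValueError(
                f"subject {self.subject_id!r}: label must be 'AD' or 'HC', "
                f"got {self.label!r}"
            )
        self.slice_paths = [Path(p) for p in self.slice_paths]


@dataclass
class FeatureMatrix:
    """Subjects-by-features matrix with aligned labels and column names."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary targets: AD (patient) = 1, HC (control) = 0."""
        return (self.labels == AD).astype(int)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings; the defaults are the study protocol."""

    n_slices: int = 32
    image_size: tuple[int, int] = (256, 256)
    levels: int = 5
    magnitude_only: bool = False
    with_demographics: bool = False
    filters: FilterSet | None = None

    def resolved_filters(self) -> FilterSet:
        return self.filters if self.filters is not None else default_filter_set()


def select_center_slices(all_slice_paths: Sequence, n_slices: int) -> list:
    """The `n_slices` contiguous entries centred on the list midpoint.

    Ties (odd surplus) resolve to the lower-median start, i.e. the window
    starts at ``(len - n) // 2``.
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be positive, got {n_slices}")
    total = len(all_slice_paths)
    if total < n_slices:
        raise ValueError(
            f"cannot select {n_slices} centre slices from a stack of {total}"
        )
    start = (total - n_slices) // 2
    return list(all_slice_paths[start : start + n_slices])


def preprocess_slice(image: np.ndarray, target: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Rescale intensities to [0, 1] and bilinearly resize to `target`.

    Integer images are divided by their dtype maximum (255 for 8-bit
    sources); floating-point input is assumed to already be on a [0, 1]
    scale and is passed through unscaled.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.shape == tuple(target):
        return arr
    return _sk_resize(arr, target, order=1, mode="edge", anti_aliasing=False,
                      preserve_range=True)


def slice_features(
    image: np.ndarray,
    levels: int = 5,
    filters: FilterSet | None = None,
    magnitude_only: bool = False,
) -> np.ndarray:
    """Flatten the deepest-level DTCWT subbands of one slice into a vector.

    The six oriented complex subbands of level `levels` are concatenated
    in canonical orientation order; within each subband the real part
    (row-major) precedes the imaginary part.  For a 256x256 slice at
    level 5 this yields 6 x 8 x 8 x 2 = 768 features (384 with
    ``magnitude_only``, which stores |z| instead of the two parts).
    """
    pyr = forward(image, levels, filters)
    bands = pyr.levels[-1]  # (..., 6, r, c)
    if magnitude_only:
        parts = [np.abs(bands[..., k, :, :]).reshape(bands.shape[:-3] + (-1,))
                 for k in range(6)]
    else:
        parts = []
        for k in range(6):
            b = bands[..., k, :, :].reshape(bands.shape[:-3] + (-1,))
            parts.extend([b.real, b.imag])
    return np.concatenate(parts, axis=-1)


def feature_names_for(config: FeatureConfig) -> list[str]:
    """Column descriptors: slice index, level, orientation, row, col, part."""
    rows = config.image_size[0] >> config.levels
    cols = config.image_size[1] >> config.levels
    parts = ("mag",) if config.magnitude_only else ("re", "im")
    names = []
    for s in range(config.n_slices):
        for theta in ORIENTATIONS:
            for part in parts:
                for r in range(rows):
                    for c in range(cols):
                        names.append(
                            f"s{s:02d}_L{config.levels}_t{theta:+03d}_{r}_{c}_{part}"
                        )
    return names


_NUMERIC_DEMOGRAPHICS = ("age", "gender", "education", "ses", "mmse")


def _load_slice(path: Path, subject_id: str) -> np.ndarray:
    try:
        with Image.open(path) as img:
            if img.mode not in ("L", "I", "I;16", "F"):
                img = img.convert("L")
            return np.asarray(img)
    except (OSError, ValueError) as exc:
        raise OSError(
            f"subject {subject_id!r}: cannot read slice image {path}: {exc}"
        ) from exc


def build_feature_matrix(
    subjects: Sequence[SubjectRecord],
    config: FeatureConfig = FeatureConfig(),
) -> FeatureMatrix:
    """Extract one feature row per subject from its slice stack on disk."""
    stacks = []
    for sub in subjects:
        chosen = select_center_slices(sub.slice_paths, config.n_slices)
        stack = np.stack(
            [
                preprocess_slice(_load_slice(p, sub.subject_id), config.image_size)
                for p in chosen
            ]
        )
        stacks.append(stack)
    return build_feature_matrix_from_arrays(
        stacks,
        labels=[s.label for s in subjects],
        subject_ids=[s.subject_id for s in subjects],
        config=config,
        demographics=[s.demographics for s in subjects],
        preprocessed=True,
    )


def build_feature_matrix_from_arrays(
    stacks: Iterable[np.ndarray],
    labels: Sequence[str],
    config: FeatureConfig = FeatureConfig(),
    subject_ids: Sequence[str] | None = None,
    demographics: Sequence[Mapping[str, float] | None] | None = None,
    preprocessed: bool = False,
) -> FeatureMatrix:
    """Extract features from in-memory slice stacks (n_slices, rows, cols).

    `stacks` that are not yet `preprocessed` are centre-selected, rescaled
    and resized first, so synthetic cohorts can bypass image files.
    """
    filters = config.resolved_filters()
    rows = []
    for stack in stacks:
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise ValueError(f"slice stack must be 3-D, got shape {stack.shape}")
        if not preprocessed:
            idx = select_center_slices(range(stack.shape[0]), config.n_slices)
            stack = np.stack(
                [preprocess_slice(stack[i], config.image_size) for i in idx]
            )
        elif stack.shape[0] != config.n_slices:
            raise ValueError(
                f"expected {config.n_slices} slices per subject, got {stack.shape[0]}"
            )
        feats = slice_features(
            stack, config.levels, filters, config.magnitude_only
        )  # (n_slices, features_per_slice)
        rows.append(feats.reshape(-1))
    values = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if values.shape[0] != len(labels):
        raise ValueError("number of stacks and labels differ")
    names = feature_names_for(config)
    if config.with_demographics and demographics is not None:
        demo = _demographic_block(demographics)
        values = np.hstack([values, demo])
        names = names + [f"demo_{k}" for k in _NUMERIC_DEMOGRAPHICS]
    if np.isnan(values).any():
        raise ValueError("feature matrix contains missing values")
    ids = list(subject_ids) if subject_ids is not None else [
        f"subj{i:03d}" for i in range(values.shape[0])
    ]
    return FeatureMatrix(values=values, labels=labels, feature_names=names,
                         subject_ids=ids)


def _demographic_block(demographics) -> np.ndarray:
    """Z-scored numeric demographics (gender coded M=0, F=1)."""
    rows = []
    for d in demographics:
        if d is None:
            raise ValueError("with_demographics=True but a subject has none")
        g = d.get("gender", 0)
        if isinstance(g, str):
            g = 0.0 if g.upper().startswith("M") else 1.0
        rows.append([float(d.get("age", np.nan)), float(g),
                     float(d.get("education", np.nan)), float(d.get("ses", np.nan)),
                     float(d.get("mmse", np.nan))])
    block = np.asarray(rows)
    mu = block.mean(axis=0)
    sd = block.std(axis=0)
    sd[sd == 0] = 1.0
    return (block - mu) / sd


# ---------------------------------------------------------------------------
# cohort IO
# ---------------------------------------------------------------------------


def load_subjects(data_dir: str | Path) -> list[SubjectRecord]:
    """Read ``subjects.csv`` and collect each subject's PNG slice paths.

    Expected layout: ``data_dir/subjects.csv`` with columns
    ``subject_id,label[,age,gender,education,ses,mmse]`` and one directory
    of PNG slices per subject, sorted by filename.
    """
    data_dir = Path(data_dir)
    table = pd.read_csv(data_dir / "subjects.csv")
    subjects = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        slice_dir = data_dir / sid
        paths = sorted(slice_dir.glob("*.png"))
        if not paths:
            raise FileNotFoundError(f"no PNG slices found for subject {sid!r} "
                                    f"in {slice_dir}")
        demo = {
            k: row[k] for k in _NUMERIC_DEMOGRAPHICS if k in table.columns
        } or None
        subjects.append(SubjectRecord(sid, str(row["label"]), paths, demo))
    return subjects


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Store the feature matrix as CSV (subject_id, label, then features)."""
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "label", fm.labels)
    df.insert(0, "subject_id", fm.subject_ids)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("subject_id", "label")]
    return FeatureMatrix(
        values=df[names].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object).astype(str),
        feature_names=names,
        subject_ids=[str(s) for s in df["subject_id"]],
    )
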