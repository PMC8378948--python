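"""Block-design preprocessing of 4D task fMRI.

Raw runs are 4D BOLD volumes ``[X, Y, Z, T]`` acquired with a repetition
time (TR) of 0.72 s, accompanied by event timing (onset, duration, condition
label) for the task blocks.  Preprocessing proceeds per subject and task:

1. crop away the empty border of the standard 91 x 109 x 91 grid to
   78 x 93 x 76 voxels;
2. locate each task block, extend it by an 8 s post-stimulus window so the
   delayed hemodynamic response is captured, and convert the span to a frame
   count ``round((duration + 8) / TR)``;
3. augment by drawing random 21-frame windows inside each block, balanced so
   every (subject, task) pair contributes the same number of samples;
4. take absolute inter-frame differences (21 -> 20 frames), highlighting
   voxels whose BOLD intensity is changing;
5. divide by the scalar maximum over the 20 frames, yielding model-ready
   samples ``[20, X', Y', Z', 1]`` with values in [0, 1].

Splits and cross-validation folds are made at the subject level so no
subject contributes samples to more than one partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from taskcrnn.errors import ConfigError, DataError, ShapeError

#: The seven task states, in label order (label i = TASK_NAMES[i]).
TASK_NAMES: tuple[str, ...] = (
    "Emotion",
    "Gambling",
    "Language",
    "Motor",
    "Relational",
    "Social",
    "WM",
)

#: Repetition time of HCP task fMRI, seconds.
HCP_TR_S: float = 0.72

#: Post-stimulus window appended to every block, seconds.
POST_WINDOW_S: float = 8.0

#: Full-grid spatial shape and its cropped counterpart.
FULL_SPATIAL_SHAPE: tuple[int, int, int] = (91, 109, 91)
CROPPED_SPATIAL_SHAPE: tuple[int, int, int] = (78, 93, 76)
#: Leading crop margins (trailing margins follow from full - lead - target).
CROP_LEAD_MARGINS: tuple[int, int, int] = (6, 8, 7)

#: One analysed condition per task: label -> (condition name, duration in s).
DEFAULT_CONDITIONS: dict[str, tuple[str, float]] = {
    "Emotion": ("Fear", 18.0),
    "Gambling": ("Loss", 28.0),
    "Language": ("Story", 24.0),
    "Motor": ("LeftHand", 12.0),
    "Relational": ("Relation", 16.0),
    "Social": ("Mental", 23.0),
    "WM": ("2bk_places", 27.5),
}

#: Blocks of the analysed condition within one run, per task.
DEFAULT_BLOCK_COUNTS: dict[str, int] = {
    "Emotion": 2,
    "Gambling": 2,
    "Language": 4,
    "Motor": 2,
    "Relational": 3,
    "Social": 2,
    "WM": 1,
}

#: Total frames of one full task run, per task (used by the simulator).
TASK_TOTAL_FRAMES: dict[str, int] = {
    "Emotion": 176,
    "Gambling": 253,
    "Language": 316,
    "Motor": 284,
    "Relational": 232,
    "Social": 274,
    "WM": 405,
}

DEFAULT_WINDOW = 21
DEFAULT_TARGET = 12


@dataclass(frozen=True)
class TaskConditionSpec:
    """Timing metadata for one condition of one task paradigm."""

    task_name: str
    condition_label: str
    condition_duration_s: float
    onsets_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.task_name not in TASK_NAMES:
            raise ConfigError(f"unknown task {self.task_name!r}; expected one of {TASK_NAMES}")
        if self.condition_duration_s <= 0:
            raise ConfigError("condition_duration_s must be positive")
        if len(self.onsets_s) < 1:
            raise ConfigError("at least one block onset is required")

    @property
    def n_blocks(self) -> int:
        return len(self.onsets_s)

    @property
    def label(self) -> int:
        """Integer class label 0-6 in TASK_NAMES order."""
        return TASK_NAMES.index(self.task_name)


@dataclass
class RawRun:
    """One 4D BOLD run ``[X, Y, Z, T]`` in arbitrary scanner units."""

    data: np.ndarray
    tr_s: float = HCP_TR_S
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ShapeError(f"RawRun data must be rank-4 [X,Y,Z,T], got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("RawRun contains non-finite intensities")
        if self.tr_s <= 0:
            raise ConfigError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class BlockClip:
    """One cropped task block, ``[X', Y', Z', F]`` frames."""

    data: np.ndarray
    subject_id: str
    task_name: str

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def label(self) -> int:
        return TASK_NAMES.index(self.task_name)


@dataclass
class Sample:
    """One model-ready input: ``[20, X', Y', Z', 1]`` in [0, 1] plus its label."""

    data: np.ndarray
    label: int
    subject_id: str


@dataclass(frozen=True)
class DatasetSplit:
    """Subject-level train/validation/test partition."""

    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subjects: frozenset[str]
    fold_index: int = 0

    def __post_init__(self) -> None:
        parts = (self.train_subjects, self.val_subjects, self.test_subjects)
        total = sum(len(p) for p in parts)
        if len(self.train_subjects | self.val_subjects | self.test_subjects) != total:
            raise DataError("train/val/test subject sets must be pairwise disjoint")


def compute_block_frames(
    duration_s: float, tr_s: float = HCP_TR_S, post_window_s: float = POST_WINDOW_S
) -> int:
    """Number of frames covering one task block plus the post-stimulus window.

    ``round((duration_s + post_window_s) / tr_s)`` with halves rounded away
    from zero.  With TR 0.72 s and an 8 s window this maps the seven
    condition durations (18, 28, 24, 12, 16, 23, 27.5 s) to
    (36, 50, 44, 28, 33, 43, 49) frames.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if tr_s <= 0:
        raise ConfigError("tr_s must be positive")
    if post_window_s < 0:
        raise ConfigError("post_window_s must be non-negative")
    # round half away from zero (uniquely consistent with the published frame table)
    return int(math.floor((duration_s + post_window_s) / tr_s + 0.5))


def crop_spatial(
    volume: np.ndarray,
    lead_margins: tuple[int, int, int] = CROP_LEAD_MARGINS,
    target_shape: tuple[int, int, int] = CROPPED_SPATIAL_SHAPE,
) -> np.ndarray:
    """Cut the empty border off a 3D volume or 4D run.

    Defaults take the standard 91 x 109 x 91 grid to 78 x 93 x 76 by removing
    a fixed, near-symmetric margin (lead 6, 8, 7 voxels).  The time axis, if
    present, is untouched.  The result is a contiguous sub-box (a view).
    """
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise ShapeError(f"expected a rank-3 or rank-4 array, got rank {volume.ndim}")
    spatial = volume.shape[:3]
    for axis in range(3):
        if lead_margins[axis] < 0 or target_shape[axis] < 1:
            raise ConfigError("crop margins must be >= 0 and target dims >= 1")
        if lead_margins[axis] + target_shape[axis] > spatial[axis]:
            raise ShapeError(
                f"cannot crop axis {axis}: margin {lead_margins[axis]} + target "
                f"{target_shape[axis]} exceeds input extent {spatial[axis]}"
            )
    if (
        lead_margins == CROP_LEAD_MARGINS
        and target_shape == CROPPED_SPATIAL_SHAPE
        and spatial != FULL_SPATIAL_SHAPE
    ):
        raise ShapeError(
            f"default crop expects spatial shape {FULL_SPATIAL_SHAPE}, got {spatial}"
        )
    sl = tuple(
        slice(lead_margins[a], lead_margins[a] + target_shape[a]) for a in range(3)
    )
    return volume[sl]


def onset_to_frame(onset_s: float, tr_s: float) -> int:
    """Frame index nearest to an onset time (0-based)."""
    if tr_s <= 0:
        raise ConfigError("tr_s must be positive")
    return int(math.floor(onset_s / tr_s + 0.5))


def extract_block_clip(
    run: RawRun,
    onset_s: float,
    n_frames: int,
    task_name: str = "",
    lead_margins: tuple[int, int, int] = CROP_LEAD_MARGINS,
    target_shape: tuple[int, int, int] = CROPPED_SPATIAL_SHAPE,
) -> BlockClip:
    """Extract one spatially cropped block of ``n_frames`` frames at ``onset_s``."""
    f0 = onset_to_frame(onset_s, run.tr_s)
    if f0 < 0:
        raise DataError(f"negative onset frame {f0}")
    if f0 + n_frames > run.n_frames:
        raise DataError(
            f"block [{f0}, {f0 + n_frames}) exceeds run length {run.n_frames} frames"
        )
    cropped = crop_spatial(run.data[..., f0 : f0 + n_frames], lead_margins, target_shape)
    return BlockClip(data=cropped, subject_id=run.subject_id, task_name=task_name)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_windows(
    clip: BlockClip | np.ndarray,
    window: int = DEFAULT_WINDOW,
    n_draws: int = 1,
    seed: int | np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Draw random contiguous ``window``-frame clips from one block.

    Start frames are uniform over ``[0, F - window]`` and drawn with
    replacement; draws are reproducible for a fixed seed.
    """
    data = clip.data if isinstance(clip, BlockClip) else np.asarray(clip)
    n_frames = data.shape[3]
    if window < 1:
        raise ConfigError("window must be >= 1")
    if n_frames < window:
        raise DataError(f"block has {n_frames} frames, fewer than the {window}-frame window")
    rng = _as_rng(seed)
    starts = rng.integers(0, n_frames - window + 1, size=n_draws)
    return [data[..., s : s + window] for s in starts]


def allocate_draws(target: int, n_blocks: int) -> list[int]:
    """Spread ``target`` window draws as evenly as possible over the blocks.

    The remainder goes to the earliest blocks: 12 over 4 blocks -> [3,3,3,3];
    12 over 1 block -> [12]; 5 over 3 -> [2,2,1].
    """
    if n_blocks < 1:
        raise DataError("at least one block is required")
    base, rem = divmod(target, n_blocks)
    return [base + (1 if i < rem else 0) for i in range(n_blocks)]


def balance_to_target(
    clips_by_task: Mapping[str, Sequence[BlockClip]],
    target: int = DEFAULT_TARGET,
    window: int = DEFAULT_WINDOW,
    seed: int | np.random.Generator | None = None,
) -> dict[str, list[np.ndarray]]:
    """Balanced temporal augmentation for one subject.

    Every task ends up with exactly ``target`` 21-frame windows, distributed
    as evenly as possible across that task's blocks, so the classifier sees
    the same number of samples per class regardless of how often each
    condition was presented.
    """
    rng = _as_rng(seed)
    out: dict[str, list[np.ndarray]] = {}
    for task_name, clips in clips_by_task.items():
        if len(clips) == 0:
            raise DataError(f"no blocks available for task {task_name!r}")
        windows: list[np.ndarray] = []
        for clip, n_draws in zip(clips, allocate_draws(target, len(clips))):
            if n_draws:
                windows.extend(sample_windows(clip, window=window, n_draws=n_draws, seed=rng))
        out[task_name] = windows
    return out


def frame_difference(sample21: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Absolute inter-frame differences along the last (time) axis.

    ``window`` input frames become ``window - 1`` difference frames; voxels
    with a changing BOLD signal light up, static background cancels.
    """
    sample21 = np.asarray(sample21)
    if sample21.ndim != 4 or sample21.shape[3] != window:
        raise ShapeError(
            f"expected rank-4 input with {window} frames on the last axis, got {sample21.shape}"
        )
    return np.abs(np.diff(sample21, axis=3))


def normalize_sample(sample20: np.ndarray) -> np.ndarray:
    """Scale by the global maximum and append the channel axis.

    Input is the rank-4 difference clip ``[X', Y', Z', 20]`` (all values
    >= 0); output is ``[20, X', Y', Z', 1]`` with global max exactly 1.  An
    all-zero clip passes through unchanged with a warning rather than
    raising on the zero divisor.
    """
    sample20 = np.asarray(sample20)
    if sample20.ndim != 4:
        raise ShapeError(f"expected a rank-4 array, got rank {sample20.ndim}")
    if np.any(sample20 < 0):
        raise DataError("normalize_sample expects non-negative values (apply frame_difference first)")
    peak = float(sample20.max()) if sample20.size else 0.0
    if peak == 0.0:
        warnings.warn("all-zero sample passed through normalization unchanged", stacklevel=2)
        scaled = sample20.astype(np.float32, copy=True)
    else:
        scaled = (sample20 / peak).astype(np.float32)
    return np.moveaxis(scaled, 3, 0)[..., np.newaxis]


def make_sample(window_clip: np.ndarray, label: int, subject_id: str) -> Sample:
    """Full per-window pipeline: difference, normalize, wrap."""
    window = window_clip.shape[3]
    diffs = frame_difference(window_clip, window=window)
    return Sample(data=normalize_sample(diffs), label=label, subject_id=subject_id)


def preprocess_subject(
    runs_by_task: Mapping[str, RawRun],
    specs_by_task: Mapping[str, TaskConditionSpec],
    target: int = DEFAULT_TARGET,
    window: int = DEFAULT_WINDOW,
    lead_margins: tuple[int, int, int] = CROP_LEAD_MARGINS,
    target_shape: tuple[int, int, int] = CROPPED_SPATIAL_SHAPE,
    seed: int | np.random.Generator | None = None,
) -> list[Sample]:
    """Run the whole preprocessing chain for one subject.

    Returns ``target`` samples per task, each ``[window-1, X', Y', Z', 1]``.
    """
    rng = _as_rng(seed)
    clips_by_task: dict[str, list[BlockClip]] = {}
    for task_name, run in runs_by_task.items():
        spec = specs_by_task[task_name]
        n_frames = compute_block_frames(spec.condition_duration_s, run.tr_s)
        clips_by_task[task_name] = [
            extract_block_clip(run, onset, n_frames, task_name, lead_margins, target_shape)
            for onset in spec.onsets_s
        ]
    windows = balance_to_target(clips_by_task, target=target, window=window, seed=rng)
    samples: list[Sample] = []
    for task_name in sorted(windows, key=TASK_NAMES.index):
        label = TASK_NAMES.index(task_name)
        subject = runs_by_task[task_name].subject_id
        samples.extend(make_sample(w, label, subject) for w in windows[task_name])
    return samples


def split_subjects(
    subject_ids: Sequence[str],
    seed: int | np.random.Generator | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> DatasetSplit:
    """Random subject-level 80/10/10 split (+-1 subject when not divisible)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    ids = list(dict.fromkeys(subject_ids))
    if len(ids) < 3:
        raise DataError("need at least 3 subjects for a train/val/test split")
    rng = _as_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(order)
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    test = order[:n_test]
    val = order[n_test : n_test + n_val]
    train = order[n_test + n_val :]
    return DatasetSplit(frozenset(train), frozenset(val), frozenset(test))


def make_cv_folds(
    subject_ids: Sequence[str],
    k: int = 10,
    seed: int | np.random.Generator | None = None,
) -> list[DatasetSplit]:
    """k-fold subject-level cross-validation splits.

    Subjects are shuffled once and divided into ``k`` groups; fold ``i`` uses
    group ``i`` as test, group ``(i+1) mod k`` as validation and the rest as
    training, so every subject appears in exactly one test partition.
    """
    ids = list(dict.fromkeys(subject_ids))
    if len(ids) < k:
        raise DataError(f"{len(ids)} subjects is fewer than k={k} folds")
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = _as_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    groups = [order[i::k] for i in range(k)]
    folds = []
    for i in range(k):
        test = frozenset(groups[i])
        if k == 2:
            # with two folds the "next group" would leave no training set;
            # carve the validation subjects out of the non-test group instead
            rest = groups[1 - i]
            n_val = max(1, round(len(rest) / 8))
            val = frozenset(rest[:n_val])
        else:
            val = frozenset(groups[(i + 1) % k])
        train = frozenset(order) - test - val
        if not train:
            raise DataError(f"fold {i}: no training subjects left ({len(ids)} subjects, k={k})")
        folds.append(DatasetSplit(train, val, test, fold_index=i))
    return folds


def default_condition_specs(
    block_counts: Mapping[str, int] | None = None,
    first_onset_s: float = 7.2,
    rest_s: float = 8.0,
) -> dict[str, TaskConditionSpec]:
    """Condition specs with the canonical durations and evenly spaced onsets.

    Real paradigms interleave conditions; for simulation and testing the
    analysed condition's blocks are laid out back to back, separated by the
    8 s post-stimulus window plus ``rest_s`` of rest.
    """
    counts = dict(DEFAULT_BLOCK_COUNTS if block_counts is None else block_counts)
    specs = {}
    for task, (cond, dur) in DEFAULT_CONDITIONS.items():
        n = counts.get(task, 1)
        spacing = dur + POST_WINDOW_S + rest_s
        onsets = tuple(first_onset_s + i * spacing for i in range(n))
        specs[task] = TaskConditionSpec(task, cond, dur, onsets)
    return specs
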