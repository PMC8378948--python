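"""Synthetic multi-subject task-fMRI generator.

Each simulated run is a 4D BOLD-like volume: a flat baseline of 100
(arbitrary units) everywhere, plus — inside a task-specific spherical region
of interest (ROI) — a block regressor convolved with a canonical
double-gamma hemodynamic response, scaled to a few percent of baseline,
plus white Gaussian noise and a slow sinusoidal drift everywhere.  The
seven tasks activate seven distinct ROIs on a fixed lattice inside the
cropped field of view, so their spatial signatures are separable by
construction; block timing follows the canonical condition durations and
per-run block counts.

This emulates the structure the classifier exploits (condition-locked,
HRF-lagged activation in stable locations over a noisy baseline).  It does
not emulate anatomy, physiological noise, motion, or spatial correlation of
the noise field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from taskcrnn.errors import ConfigError
from taskcrnn.preprocess import (
    CROP_LEAD_MARGINS,
    CROPPED_SPATIAL_SHAPE,
    FULL_SPATIAL_SHAPE,
    HCP_TR_S,
    POST_WINDOW_S,
    RawRun,
    TASK_NAMES,
    TaskConditionSpec,
    compute_block_frames,
    default_condition_specs,
    onset_to_frame,
)

#: Fractional ROI centers within the cropped box: 7 corners of a cube lattice.
_ROI_LATTICE: tuple[tuple[float, float, float], ...] = (
    (0.25, 0.25, 0.25),
    (0.75, 0.25, 0.25),
    (0.25, 0.75, 0.25),
    (0.25, 0.25, 0.75),
    (0.75, 0.75, 0.25),
    (0.75, 0.25, 0.75),
    (0.25, 0.75, 0.75),
)

# double-gamma HRF: response peak ~4.5 s, undershoot ~13.5 s, ratio 1/6
_HRF_PEAK_SHAPE = 6.0
_HRF_UNDER_SHAPE = 16.0
_HRF_SCALE_S = 0.9
_HRF_UNDER_RATIO = 1.0 / 6.0


def hrf(t: np.ndarray | float) -> np.ndarray | float:
    """Canonical double-gamma hemodynamic response, normalized to peak 1.

    Zero at t=0, peak near 5 s, a shallow undershoot around 13-15 s, and
    essentially zero by 30 s — the lag that motivates extending every task
    block by an 8 s post-stimulus window.
    """
    t_arr = np.asarray(t, dtype=float)
    raw = gamma_dist.pdf(t_arr, _HRF_PEAK_SHAPE, scale=_HRF_SCALE_S) - (
        _HRF_UNDER_RATIO * gamma_dist.pdf(t_arr, _HRF_UNDER_SHAPE, scale=_HRF_SCALE_S)
    )
    grid = np.arange(0.0, 30.0, 0.01)
    peak = np.max(
        gamma_dist.pdf(grid, _HRF_PEAK_SHAPE, scale=_HRF_SCALE_S)
        - _HRF_UNDER_RATIO * gamma_dist.pdf(grid, _HRF_UNDER_SHAPE, scale=_HRF_SCALE_S)
    )
    out = raw / peak
    return out if np.ndim(t) else float(out)


def proportional_crop(
    spatial_shape: tuple[int, int, int],
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """(lead_margins, target_shape) scaling the standard crop to any grid."""
    lead = []
    target = []
    for n, full, lead_full, target_full in zip(
        spatial_shape, FULL_SPATIAL_SHAPE, CROP_LEAD_MARGINS, CROPPED_SPATIAL_SHAPE
    ):
        trail_full = full - lead_full - target_full
        m_lead = round(lead_full * n / full)
        m_trail = round(trail_full * n / full)
        if n - m_lead - m_trail < 1:
            raise ConfigError(f"spatial extent {n} too small to crop")
        lead.append(m_lead)
        target.append(n - m_lead - m_trail)
    return tuple(lead), tuple(target)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``effect_amplitude`` is the peak activation as a fraction of baseline
    (default 3%, a typical BOLD effect size); ``noise_sd`` is the white
    noise standard deviation in intensity units (baseline is 100);
    ``drift_amplitude`` scales a slow sinusoid (period 128 s) emulating
    scanner drift.
    """

    spatial_shape: tuple[int, int, int] = FULL_SPATIAL_SHAPE
    tr_s: float = HCP_TR_S
    n_subjects: int = 10
    tasks: tuple[TaskConditionSpec, ...] = tuple(default_condition_specs().values())
    roi_radius: int = 6
    effect_amplitude: float = 0.03
    baseline: float = 100.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    drift_period_s: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_amplitude < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ConfigError("amplitudes and noise_sd must be >= 0")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        names = [t.task_name for t in self.tasks]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate task in SimConfig.tasks")
        for t in self.tasks:  # every ROI must fit inside the volume
            self.roi_center(t.task_name)

    @property
    def crop(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        return proportional_crop(self.spatial_shape)

    def roi_center(self, task_name: str) -> tuple[int, int, int]:
        """Deterministic ROI center for a task, inside the cropped box."""
        lead, target = self.crop
        frac = _ROI_LATTICE[TASK_NAMES.index(task_name)]
        center = tuple(
            int(lead[a] + round(frac[a] * (target[a] - 1))) for a in range(3)
        )
        for a in range(3):
            if center[a] - self.roi_radius < 0 or center[a] + self.roi_radius >= self.spatial_shape[a]:
                raise ConfigError(
                    f"ROI for {task_name} (center {center}, radius {self.roi_radius}) "
                    f"does not fit inside volume {self.spatial_shape}"
                )
        return center


def reduced_sim_config(
    spatial_shape: tuple[int, int, int] = (24, 28, 24),
    roi_radius: int = 2,
    **overrides,
) -> SimConfig:
    """A desk-scale configuration on a small grid (crop scales with it)."""
    return SimConfig(spatial_shape=spatial_shape, roi_radius=roi_radius, **overrides)


@dataclass
class SimRun:
    """A simulated run plus its ground truth."""

    run: RawRun
    task: TaskConditionSpec
    roi_mask: np.ndarray  # bool [X, Y, Z]
    signal_timecourse: np.ndarray  # noiseless activation per frame, intensity units

    @property
    def label(self) -> int:
        return self.task.label


def _sphere_mask(shape: tuple[int, int, int], center: tuple[int, int, int], radius: int) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


def block_regressor(
    n_frames: int, tr_s: float, onsets_s: tuple[float, ...], duration_s: float
) -> np.ndarray:
    """Boxcar of the task blocks convolved with the HRF, peak-normalized."""
    boxcar = np.zeros(n_frames)
    for onset in onsets_s:
        f0 = onset_to_frame(onset, tr_s)
        f1 = min(n_frames, f0 + max(1, int(round(duration_s / tr_s))))
        boxcar[f0:f1] = 1.0
    kernel = np.asarray(hrf(np.arange(0, 32.0, tr_s)))
    reg = np.convolve(boxcar, kernel)[:n_frames]
    peak = reg.max()
    return reg / peak if peak > 0 else reg


def run_length_frames(task: TaskConditionSpec, tr_s: float, tail_s: float = 16.0) -> int:
    """Frames needed to cover every block plus post-window plus a tail."""
    last = max(task.onsets_s)
    frames = onset_to_frame(last, tr_s) + compute_block_frames(task.condition_duration_s, tr_s)
    return frames + int(round(tail_s / tr_s))


def generate_run(
    subject_id: str,
    task: TaskConditionSpec,
    config: SimConfig,
    seed: int | None = None,
) -> SimRun:
    """Simulate one subject's run for one task; reproducible per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_frames = run_length_frames(task, config.tr_s)
    shape = config.spatial_shape
    reg = block_regressor(n_frames, config.tr_s, task.onsets_s, task.condition_duration_s)
    signal = config.baseline * config.effect_amplitude * reg
    mask = _sphere_mask(shape, config.roi_center(task.task_name), config.roi_radius)

    data = np.full((*shape, n_frames), config.baseline, dtype=np.float32)
    data[mask] += signal.astype(np.float32)
    if config.drift_amplitude > 0:
        t_s = np.arange(n_frames) * config.tr_s
        drift = config.drift_amplitude * np.sin(2 * np.pi * t_s / config.drift_period_s)
        data += drift.astype(np.float32)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape).astype(np.float32)

    run = RawRun(data=data, tr_s=config.tr_s, subject_id=subject_id)
    return SimRun(run=run, task=task, roi_mask=mask, signal_timecourse=signal)


def subject_ids(config: SimConfig) -> list[str]:
    return [f"sub-{i:03d}" for i in range(1, config.n_subjects + 1)]


def generate_dataset(config: SimConfig, out_dir=None) -> dict[str, dict[str, SimRun]]:
    """All runs of the study: ``{subject_id: {task_name: SimRun}}``.

    Per-run seeds are spawned deterministically from ``config.seed`` and the
    (subject, task) position, so any single run can be regenerated without
    generating the rest.  With ``out_dir`` set, runs are written as NIfTI
    alongside tab-delimited event files (see :mod:`taskcrnn.io`).
    """
    from taskcrnn import io as tio  # deferred: keeps this module numpy-only

    dataset: dict[str, dict[str, SimRun]] = {}
    for si, subject in enumerate(subject_ids(config)):
        dataset[subject] = {}
        for ti, task in enumerate(config.tasks):
            seed = np.random.SeedSequence([config.seed, si, ti]).generate_state(1)[0] % (2**31)
            sim = generate_run(subject, task, config, seed=int(seed))
            dataset[subject][task.task_name] = sim
            if out_dir is not None:
                tio.write_run_with_events(sim, out_dir)
    return dataset
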