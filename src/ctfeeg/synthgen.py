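"""Synthetic epoched EEG with a known position-tuned generative model.

Every downstream stage (decoding, forward encoding, statistics) is
validated against data produced here, where the ground truth is known
exactly. The generative model is

    data[trial](t) = A * W_true @ c_true(p) * s(t) + noise,

where ``p`` is the trial's target position, ``W_true`` (electrodes x
position channels) holds one spatially smooth scalp topography per
position channel, ``c_true(p)`` is a circular-Gaussian tuning profile over
the position channels peaking at channel ``p``, ``s(t)`` is a unit raised
cosine envelope rising shortly before 200 ms post-stimulus, ``A`` the
signal amplitude in microvolts, and the noise is Gaussian (white by
default, optionally spatially correlated over the montage).

Two stimulus designs are emulated: 4-position displays on the
horizontal/vertical midlines recorded from 23 electrodes, and 8-position
circular displays (2.4 deg eccentricity, positions numbered clockwise from
the upper right, none on a midline) recorded from 27 electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochedData
from .montage import Montage

# Geometry of the generative scalp bump. The bump sits over posterior
# scalp contralateral to the attended position and slides anterior for
# upper-field positions, mimicking a coarse retinotopic gradient.
_BUMP_RADIUS_X = 0.6     # lateral displacement scale (unit-disc units)
_BUMP_BASE_Y = -0.55     # posterior midpoint of the bump track
_BUMP_RANGE_Y = 0.25     # anterior-posterior excursion with elevation
_BUMP_WIDTH = 0.45       # 2-D Gaussian width of the bump


def _angles(k: int, start: float, step: float) -> tuple[float, ...]:
    return tuple((start + step * i) % 360.0 for i in range(k))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic design.

    Defaults reproduce the 8-position circular-display design: positions
    at 22.5 + 45 * i degrees clockwise from the top of the screen (position
    1 upper right), 96 trials per position, 27 electrodes, 250 Hz sampling,
    a signal rising at 190 ms and peaking at 264 ms post-stimulus, 10 uV
    peak amplitude against 10 uV white noise (a clear evoked response, the
    regime in which real recordings show graded channel tuning).
    """

    n_positions: int = 8
    position_angles: tuple[float, ...] = field(
        default_factory=lambda: _angles(8, 22.5, 45.0))
    n_trials_per_position: int = 96
    n_electrodes: int = 27
    sfreq: float = 250.0
    epoch_window: tuple[float, float] = (-100.0, 600.0)
    true_tuning_width: float = 1.2     # sigma over position channels
    signal_onset: float = 190.0        # ms
    signal_peak: float = 264.0         # ms
    signal_offset: float = 500.0       # ms
    signal_amplitude: float = 10.0     # uV at the envelope peak
    noise_sd: float = 10.0             # uV
    noise_mode: str = "white"          # or "correlated"
    noise_corr_length: float = 0.6     # spatial scale of correlated noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise ValueError("need at least 2 positions")
        if len(self.position_angles) != self.n_positions:
            raise ValueError("position_angles length must equal n_positions")
        d = np.diff(np.unwrap(np.deg2rad(self.position_angles)))
        if np.any(d <= 0):
            raise ValueError("position angles must be strictly increasing "
                             "modulo 360")
        if not (self.epoch_window[0] < 0.0 < self.epoch_window[1]):
            raise ValueError("epoch window must contain 0 ms")
        if self.true_tuning_width <= 0:
            raise ValueError("tuning width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_mode not in ("white", "correlated"):
            raise ValueError("noise_mode must be 'white' or 'correlated'")
        if not (self.signal_onset < self.signal_peak <= self.signal_offset):
            raise ValueError("need signal_onset < signal_peak <= signal_offset")

    @classmethod
    def experiment1(cls, **overrides) -> "SimConfig":
        """4-position midline design: 1=top, 2=right, 3=bottom, 4=left.

        23 electrodes, 192 trials per position, epochs -200..400 ms, and a
        tuning width matched in angular terms to the 8-position default
        (half the width in channel units, since neighbouring positions are
        90 rather than 45 degrees apart).
        """
        base = dict(
            n_positions=4,
            position_angles=_angles(4, 0.0, 90.0),
            n_trials_per_position=192,
            n_electrodes=23,
            epoch_window=(-200.0, 400.0),
            signal_peak=246.0,
            signal_offset=400.0,
            true_tuning_width=0.6,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    true_weights: np.ndarray          # (m, k): topography per position channel
    true_channel_profile: np.ndarray  # (k, k): [channel, condition]
    signal_timecourse: np.ndarray     # (T,): unit envelope
    position_angles: np.ndarray       # (k,): degrees clockwise from top
    montage_coords: np.ndarray        # (m, 2)
    tuning_width: float = 1.2         # sigma over position channels
    amplitude: float = 1.0            # uV at the envelope peak

    def topography(self, angle_deg: float) -> np.ndarray:
        """Generative scalp bump (unit peak) for an arbitrary screen
        angle: the topography tied to a single position channel."""
        return _bump(self.montage_coords, angle_deg)

    def evoked_topography(self, angle_deg: float) -> np.ndarray:
        """Peak evoked topography a stimulus at ``angle_deg`` would
        produce under the generative model, including the mixing of
        neighbouring channel topographies through the tuning profile.

        The wrapped-Gaussian tuning is evaluated at the (possibly
        fractional) channel distance between each position channel and
        the requested angle, so angles never used as stimulus positions
        (e.g. the midlines of the 8-position display) are supported.
        """
        spacing = 360.0 / len(self.position_angles)
        d = np.abs((self.position_angles - angle_deg + 180.0) % 360.0
                   - 180.0) / spacing
        c = np.exp(-d ** 2 / (2 * self.tuning_width ** 2))
        return self.amplitude * (self.true_weights @ c)


def _bump(coords: np.ndarray, angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    cx = -_BUMP_RADIUS_X * np.sin(th)   # contralateral to the stimulus
    cy = _BUMP_BASE_Y + _BUMP_RANGE_Y * np.cos(th)
    d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
    return np.exp(-d2 / (2 * _BUMP_WIDTH ** 2))


def circular_gaussian_profile(k: int, width: float) -> np.ndarray:
    """(k, k) matrix of wrapped-Gaussian channel profiles, one condition
    per column, each peaking (value 1) at its own channel."""
    idx = np.arange(k)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, k - d)
    return np.exp(-d.astype(float) ** 2 / (2 * width ** 2))


def raised_cosine_envelope(times_ms: np.ndarray, onset: float, peak: float,
                           offset: float) -> np.ndarray:
    """Piecewise raised-cosine envelope: 0 before onset, unit at the peak,
    0 after offset."""
    s = np.zeros_like(times_ms, dtype=float)
    rise = (times_ms >= onset) & (times_ms <= peak)
    s[rise] = 0.5 * (1 - np.cos(np.pi * (times_ms[rise] - onset)
                                / max(peak - onset, 1e-9)))
    fall = (times_ms > peak) & (times_ms <= offset)
    s[fall] = 0.5 * (1 + np.cos(np.pi * (times_ms[fall] - peak)
                                / max(offset - peak, 1e-9)))
    return s


def _noise(rng: np.random.Generator, shape: tuple[int, ...], config: SimConfig,
           coords: np.ndarray) -> np.ndarray:
    white = rng.normal(0.0, config.noise_sd, size=shape)
    if config.noise_mode == "white" or config.noise_sd == 0:
        return white
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = np.exp(-d ** 2 / (2 * config.noise_corr_length ** 2))
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(len(coords)))
    # mix across the electrode axis (axis 1 of trials x electrodes x samples)
    return np.einsum("ij,njt->nit", chol, white)


def simulate_epochs(config: SimConfig, montage: Montage,
                    ) -> tuple[EpochedData, GroundTruth]:
    """Generate epoched EEG under the known position-tuned model.

    Labels are balanced (exactly ``n_trials_per_position`` trials per
    position) and shuffled; identical config (including seed) yields
    identical output.
    """
    if montage.n_electrodes != config.n_electrodes:
        raise ValueError(
            f"montage has {montage.n_electrodes} electrodes, config expects "
            f"{config.n_electrodes}")
    k = config.n_positions
    rng = np.random.default_rng(config.seed)

    n_samples = int(round((config.epoch_window[1] - config.epoch_window[0])
                          / 1000.0 * config.sfreq)) + 1
    times = config.epoch_window[0] + np.arange(n_samples) / config.sfreq * 1000.0

    w_true = np.column_stack(
        [_bump(montage.coords, a) for a in config.position_angles])
    c_true = circular_gaussian_profile(k, config.true_tuning_width)
    envelope = raised_cosine_envelope(
        times, config.signal_onset, config.signal_peak, config.signal_offset)

    labels = rng.permutation(np.repeat(np.arange(1, k + 1),
                                       config.n_trials_per_position))
    n_trials = len(labels)

    # per-condition peak topography, (k, m)
    topo = (config.signal_amplitude * (w_true @ c_true)).T
    data = topo[labels - 1, :, None] * envelope[None, None, :]
    data = data + _noise(rng, data.shape, config, montage.coords)

    epochs = EpochedData(
        data=data,
        times=times,
        sfreq=config.sfreq,
        labels=labels,
        electrodes=montage.names,
        meta=pd.DataFrame({"position": labels, "keep": True}),
    )
    truth = GroundTruth(
        true_weights=w_true,
        true_channel_profile=c_true,
        signal_timecourse=envelope,
        position_angles=np.asarray(config.position_angles, dtype=float),
        montage_coords=montage.coords.copy(),
        tuning_width=config.true_tuning_width,
        amplitude=config.signal_amplitude,
    )
    return epochs, truth


def inject_step_artifact(epochs: EpochedData, trial: int, onset_ms: float,
                         amplitude_uv: float, channel: str = "HEOG",
                         ) -> EpochedData:
    """Return a copy with a step added to one trial's designated channel.

    The step starts at ``onset_ms`` and persists to the end of the epoch,
    emulating a saccade-like DC shift on the horizontal EOG.
    """
    if not (0 <= trial < epochs.n_trials):
        raise IndexError(f"trial {trial} out of range (n={epochs.n_trials})")
    if not (epochs.times[0] <= onset_ms <= epochs.times[-1]):
        raise ValueError("step onset must lie inside the epoch window")
    out = epochs.copy()
    ch = out.electrode_index(channel)
    out.data[trial, ch, out.times >= onset_ms] += amplitude_uv
    return out
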