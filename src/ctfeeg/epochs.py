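"""Epoched EEG container: trials x electrodes x samples with labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EpochedData:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_electrodes, n_samples)
        Voltages in microvolts.
    times : ndarray, shape (n_samples,)
        Sample times in milliseconds, strictly increasing and uniformly
        spaced; the epoch must contain t = 0 (stimulus onset).
    sfreq : float
        Sampling rate in Hz.
    labels : ndarray, shape (n_trials,)
        Integer position label per trial, 1..k.
    electrodes : list of str
        Electrode names, one per data row.
    meta : DataFrame, optional
        Per-trial tags (condition, keep/reject flag, ...). Index aligned
        with the trial axis.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    labels: np.ndarray
    electrodes: list[str]
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.electrodes = list(self.electrodes)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x samples")
        n, m, t = self.data.shape
        if len(self.times) != t:
            raise ValueError("times length does not match sample axis")
        if len(self.labels) != n:
            raise ValueError("labels length does not match trial axis")
        if len(self.electrodes) != m:
            raise ValueError("electrode names do not match electrode axis")
        dt = np.diff(self.times)
        if t > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("times must be strictly increasing and uniform")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("epoch window must contain t = 0")
        if np.any(self.labels < 1):
            raise ValueError("labels must be positive integers (1..k)")
        if self.meta is not None and len(self.meta) != n:
            raise ValueError("meta rows do not match trial count")

    # -- convenience -------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(len(np.unique(self.labels)))

    def electrode_index(self, name: str) -> int:
        try:
            return self.electrodes.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in montage "
                           f"({', '.join(self.electrodes)})") from None

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        if not (self.times[0] - 1e-9 <= t_ms <= self.times[-1] + 1e-9):
            raise ValueError(f"{t_ms} ms outside epoch "
                             f"[{self.times[0]}, {self.times[-1]}] ms")
        return int(np.argmin(np.abs(self.times - t_ms)))

    def time_slice(self, window: tuple[float, float]) -> slice:
        """Slice of sample indices covering ``window`` (ms, inclusive)."""
        lo, hi = window
        if lo >= hi:
            raise ValueError("window start must precede window end")
        return slice(self.time_index(lo), self.time_index(hi) + 1)

    def copy(self) -> "EpochedData":
        return EpochedData(
            data=self.data.copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            labels=self.labels.copy(),
            electrodes=list(self.electrodes),
            meta=None if self.meta is None else self.meta.copy(),
        )

    def select_trials(self, idx: np.ndarray) -> "EpochedData":
        """Subset trials; data, labels and meta are subset consistently."""
        idx = np.asarray(idx)
        return EpochedData(
            data=self.data[idx],
            times=self.times.copy(),
            sfreq=self.sfreq,
            labels=self.labels[idx],
            electrodes=list(self.electrodes),
            meta=None if self.meta is None
            else self.meta.iloc[np.atleast_1d(idx)].reset_index(drop=True),
        )
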