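"""Epoch-level preprocessing and the horizontal-eye-movement step detector.

All operations return new :class:`~ctfeeg.epochs.EpochedData` objects and
preserve trial count, label order and electrode order; explicit rejection
(:func:`drop_trials`) subsets all of these consistently and records the
decision in ``meta``.
"""

from __future__ import annotations

import numpy as np

from .epochs import EpochedData


def rereference(epochs: EpochedData, ref_electrodes: list[str]) -> EpochedData:
    """Re-reference to the average of ``ref_electrodes`` (e.g. both
    earlobes): subtract their mean from every channel, per sample."""
    idx = [epochs.electrode_index(name) for name in ref_electrodes]
    out = epochs.copy()
    ref = out.data[:, idx, :].mean(axis=1, keepdims=True)
    out.data -= ref
    return out


def design_highpass(sfreq: float, cutoff: float, transition: float | None = None,
                    window: str = "hamming") -> np.ndarray:
    """Design the zero-phase FIR high-pass filter used by :func:`highpass`.

    With the conventional Hamming window the filter length is
    ``3.3 / transition * sfreq`` samples; at a 0.1 Hz transition band and
    250 Hz this is 8251 taps, i.e. 33 seconds of data.
    """
    import mne

    if window != "hamming":
        raise ValueError("only the hamming window is supported")
    nyq = sfreq / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    return mne.filter.create_filter(
        None, sfreq, l_freq=cutoff, h_freq=None,
        l_trans_bandwidth=transition if transition is not None else "auto",
        fir_window=window, fir_design="firwin", phase="zero", verbose="error")


def highpass(epochs: EpochedData, cutoff: float,
             transition: float | None = None,
             window: str = "hamming") -> EpochedData:
    """Zero-phase Hamming-windowed sinc FIR high-pass.

    ``transition`` is the transition bandwidth in Hz (default: MNE's
    automatic choice, min(max(cutoff * 0.25, 2), cutoff)). The data must
    be at least as long as the designed filter; for very low cutoffs this
    means the filter belongs on continuous data before epoching.
    """
    import mne

    taps = design_highpass(epochs.sfreq, cutoff, transition, window)
    if len(taps) > epochs.n_samples:
        raise ValueError(
            f"filter length ({len(taps)} samples) exceeds the data length "
            f"({epochs.n_samples} samples); apply to longer (continuous) "
            f"data or widen the transition band")
    out = epochs.copy()
    out.data = mne.filter.filter_data(
        out.data, epochs.sfreq, l_freq=cutoff, h_freq=None,
        l_trans_bandwidth=transition if transition is not None else "auto",
        fir_window=window, fir_design="firwin", phase="zero", verbose="error")
    return out


def baseline_correct(epochs: EpochedData,
                     window: tuple[float, float]) -> EpochedData:
    """Subtract, per trial and electrode, the mean over ``window`` (ms)."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("baseline window start must precede end")
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ValueError(
            f"baseline window ({lo}, {hi}) ms outside epoch "
            f"({epochs.times[0]}, {epochs.times[-1]}) ms")
    sl = epochs.time_slice(window)
    out = epochs.copy()
    out.data -= out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def downsample(epochs: EpochedData, target_sfreq: float) -> EpochedData:
    """Decimate to ``target_sfreq`` (must divide the current rate).

    An anti-alias FIR low-pass is applied first, then every q-th sample is
    kept on a grid anchored at the t = 0 sample, so stimulus onset remains
    on a sample.
    """
    import mne

    if target_sfreq > epochs.sfreq:
        raise ValueError("upsampling is not supported")
    q = epochs.sfreq / target_sfreq
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"target rate {target_sfreq} Hz must divide {epochs.sfreq} Hz")
    q = int(round(q))
    out = epochs.copy()
    if q == 1:
        return out
    data = mne.filter.filter_data(
        out.data, epochs.sfreq, l_freq=None, h_freq=0.8 * target_sfreq / 2,
        fir_design="firwin", phase="zero", verbose="error")
    i0 = epochs.time_index(0.0)
    keep = np.arange(epochs.n_samples)[(np.arange(epochs.n_samples) - i0) % q == 0]
    out.data = data[:, :, keep]
    out.times = epochs.times[keep]
    out.sfreq = target_sfreq
    return out


def compute_heog(epochs: EpochedData, left: str, right: str) -> np.ndarray:
    """Horizontal EOG: left minus right outer-canthus channel, per trial
    and sample. Returns a (trials, samples) array in microvolts."""
    li = epochs.electrode_index(left)
    ri = epochs.electrode_index(right)
    return epochs.data[:, li, :] - epochs.data[:, ri, :]


def detect_step_artifacts(heog: np.ndarray, times_ms: np.ndarray,
                          window_ms: float = 100.0, step_ms: float = 50.0,
                          interval_ms: tuple[float, float] = (0.0, 500.0),
                          threshold_uv: float = 25.0) -> np.ndarray:
    """Step detector for saccade-like HEOG deflections.

    A sliding window (default 100 ms, advanced in 50 ms steps) moves over
    ``interval_ms``; a trial is flagged when, for any placement, the means
    of the window's two halves differ by more than ``threshold_uv``.
    Window boundaries are placed on the time axis (not the sample grid),
    so 50 ms steps remain exact at sampling rates where they are not an
    integer number of samples.

    A step of amplitude A whose onset coincides with a half-window
    boundary yields a mean difference of exactly A. For onsets between
    boundaries the difference is attenuated by up to
    ``step_ms / (window_ms / 2)`` relative, so detection at any onset is
    only guaranteed for amplitudes >= threshold / (1 - step/(window/2))
    (twice the threshold at the default geometry).

    Parameters
    ----------
    heog : ndarray, shape (trials, samples)
    times_ms : ndarray, shape (samples,)

    Returns
    -------
    ndarray of bool, shape (trials,)
    """
    heog = np.atleast_2d(np.asarray(heog, dtype=float))
    times_ms = np.asarray(times_ms, dtype=float)
    if heog.shape[1] != len(times_ms):
        raise ValueError("heog sample axis does not match times")
    lo, hi = interval_ms
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise ValueError("search interval outside the epoch window")
    if window_ms > hi - lo:
        raise ValueError("window longer than the search interval")

    half = window_ms / 2.0
    flagged = np.zeros(heog.shape[0], dtype=bool)
    start = lo
    while start + window_ms <= hi + 1e-9:
        first = (times_ms >= start - 1e-9) & (times_ms < start + half - 1e-9)
        second = ((times_ms >= start + half - 1e-9)
                  & (times_ms < start + window_ms - 1e-9))
        if first.any() and second.any():
            diff = heog[:, second].mean(axis=1) - heog[:, first].mean(axis=1)
            flagged |= np.abs(diff) > threshold_uv
        start += step_ms
    return flagged


def drop_trials(epochs: EpochedData, reject: np.ndarray,
                reason: str = "rejected") -> EpochedData:
    """Drop trials where ``reject`` is True, recording the decision.

    The surviving epochs carry a ``meta[reason]`` column of False (audit
    trail); data, labels and meta are subset consistently.
    """
    reject = np.asarray(reject, dtype=bool)
    if len(reject) != epochs.n_trials:
        raise ValueError("reject mask length must match trial count")
    out = epochs.select_trials(np.flatnonzero(~reject))
    if out.meta is not None:
        out.meta[reason] = False
    return out


def apply_external_cleaning(epochs: EpochedData,
                            cleaned_data: np.ndarray | None = None,
                            reject_mask: np.ndarray | None = None,
                            ) -> EpochedData:
    """Hook for externally computed artifact correction (e.g. ICA blink
    removal): substitute cleaned data and/or drop flagged trials. No
    decomposition is performed here."""
    out = epochs.copy()
    if cleaned_data is not None:
        cleaned_data = np.asarray(cleaned_data, dtype=float)
        if cleaned_data.shape != out.data.shape:
            raise ValueError("cleaned data shape must match epochs")
        out.data = cleaned_data.copy()
    if reject_mask is not None:
        out = drop_trials(out, reject_mask, reason="external_reject")
    return out
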