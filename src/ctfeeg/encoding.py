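"""Delta-basis forward encoding model and channel tuning functions.

The model expresses the voltage at each electrode as a weighted sum of k
hypothetical position-tuned "channels" (one per stimulus position; not to
be confused with EEG sensors, which are called electrodes throughout).
Training trials provide a design matrix C1 (k x n1) whose column for a
trial is the basis-set column of that trial's position; with the delta
basis (the identity), channel p responds 1 to position p and 0 otherwise,
imposing no shape assumption on the tuning profile. Ordinary least
squares of C1 onto the EEG matrix B1 (m x n1) gives the weight matrix

    W = B1 C1' (C1 C1')^-1          (m electrodes x k channels),

and inverting the model on held-out data B2 (m x n2) estimates single
trial channel responses

    C2 = (W' W)^-1 W' B2            (k x n2).

Averaging C2 per condition, circularly shifting each condition's response
vector to a common centre channel, and averaging across conditions yields
the empirical canonical channel tuning function (CTF). Repeating per time
sample gives the CTF over time. Because the model is linear and
invertible, hypothetical channel responses for positions that were never
presented can be multiplied back through W to reconstruct the scalp
topography such a stimulus would evoke.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import ActivationPattern, FoldAssignment, spatial_normalize
from .epochs import EpochedData

#: Midline positions of the 8-position circular display expressed as the
#: adjacent position pair they fall between (positions clockwise from the
#: upper right; "top" is the midpoint of positions 8 and 1).
MIDPOINT_PAIRS: dict[str, tuple[int, int]] = {
    "top": (8, 1),
    "right": (2, 3),
    "bottom": (4, 5),
    "left": (6, 7),
}


@dataclass
class BasisSet:
    """Channel response model per position: a k x k matrix whose column p
    is the modelled channel response to position p."""

    matrix: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("basis must be a square k x k matrix")
        if self.kind == "delta" and not np.array_equal(
                self.matrix, np.eye(self.matrix.shape[0])):
            raise ValueError("delta basis must be the identity matrix")

    @classmethod
    def delta(cls, k: int) -> "BasisSet":
        return cls(matrix=np.eye(k), kind="delta")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DesignMatrix:
    """C1: one basis column per trial (k x n)."""

    C1: np.ndarray
    labels: np.ndarray
    basis: BasisSet


def build_design(labels: np.ndarray, basis: BasisSet) -> DesignMatrix:
    labels = np.asarray(labels, dtype=int)
    k = basis.k
    if np.any(labels < 1) or np.any(labels > k):
        bad = labels[(labels < 1) | (labels > k)]
        raise ValueError(f"labels out of range 1..{k}: {np.unique(bad).tolist()}")
    return DesignMatrix(C1=basis.matrix[:, labels - 1], labels=labels,
                        basis=basis)


@dataclass
class EncodingModel:
    """Estimated weight matrix W (electrodes x channels)."""

    W: np.ndarray
    electrodes: list[str] | None = None
    fold: int | None = None
    time_index: int | None = None

    @property
    def k(self) -> int:
        return self.W.shape[1]


def estimate_weights(B1: np.ndarray, design: DesignMatrix,
                     electrodes: list[str] | None = None,
                     ) -> EncodingModel:
    """OLS regression of the design matrix onto the training EEG.

    With the delta basis, column p of W is exactly the mean topography of
    the training trials labelled p. The solve uses numpy's least-squares
    with its default relative rank tolerance.
    """
    B1 = np.asarray(B1, dtype=float)
    C1 = design.C1
    if B1.shape[1] != C1.shape[1]:
        raise ValueError("B1 and C1 must have the same trial count")
    k = C1.shape[0]
    present = np.unique(design.labels)
    missing = sorted(set(range(1, k + 1)) - set(present.tolist()))
    # W' solves C1' W' = B1'
    Wt, _, rank, _ = np.linalg.lstsq(C1.T, B1.T, rcond=None)
    if rank < k:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < k={k}); "
            f"missing classes: {missing if missing else 'none (collinear basis)'}")
    return EncodingModel(W=Wt.T, electrodes=electrodes)


@dataclass
class ChannelResponses:
    """Estimated channel responses on test trials (C2: k x n2)."""

    C2: np.ndarray
    labels: np.ndarray | None = None

    def condition_means(self) -> np.ndarray:
        """(k_channels, k_conditions) mean response per trial type."""
        if self.labels is None:
            raise ValueError("condition means require trial labels")
        k = self.C2.shape[0]
        out = np.full((k, k), np.nan)
        for p in range(1, k + 1):
            sel = self.labels == p
            if np.any(sel):
                out[:, p - 1] = self.C2[:, sel].mean(axis=1)
        return out


def invert_model(model: EncodingModel, B2: np.ndarray,
                 labels: np.ndarray | None = None) -> ChannelResponses:
    """Estimate channel responses on held-out trials: OLS of W onto B2."""
    B2 = np.asarray(B2, dtype=float)
    W = model.W
    if B2.shape[0] != W.shape[0]:
        raise ValueError("B2 electrode axis does not match W")
    C2, _, rank, sv = np.linalg.lstsq(W, B2, rcond=None)
    if rank < W.shape[1]:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise ValueError(
            f"weight matrix is rank-deficient (rank {rank} < k={W.shape[1]}, "
            f"condition number {cond:.3g}); cannot invert")
    return ChannelResponses(C2=C2,
                            labels=None if labels is None else np.asarray(labels))


# ---------------------------------------------------------------------------
# CTF construction and alignment


@dataclass
class ChannelTuningFunction:
    """Canonical CTF: channel responses aligned to a common centre.

    ``aligned`` has shape (k,) for a single window or (k, T) over time;
    the centre channel (1-based) holds the response at the attended
    position, neighbours hold responses at increasing positional distance.
    """

    aligned: np.ndarray
    center: int
    times: np.ndarray | None = None
    cond_means: np.ndarray | None = None    # (k, k) or (k, k, T)
    weights: np.ndarray | None = None       # fold-averaged W, (m, k[, T])
    electrodes: list[str] | None = None

    @property
    def k(self) -> int:
        return self.aligned.shape[0]

    def display_values(self) -> np.ndarray:
        """Append the wrap-around (most distant) channel once more so the
        plotted profile is symmetric about the centre."""
        far = (self.center - 1 + self.k // 2) % self.k
        wrap = np.take(self.aligned, far, axis=0)
        return np.concatenate([self.aligned, np.expand_dims(wrap, 0)], axis=0)

    def symmetrized(self) -> np.ndarray:
        """Average of the aligned CTF and its mirror about the centre
        channel (a line-symmetric profile)."""
        k, c = self.k, self.center - 1
        mirror_idx = (2 * c - np.arange(k)) % k
        return 0.5 * (self.aligned + self.aligned[mirror_idx])

    def average_window(self, window: tuple[float, float],
                       ) -> "ChannelTuningFunction":
        """Collapse the time axis over ``window`` (ms)."""
        if self.times is None or self.aligned.ndim != 2:
            raise ValueError("this CTF has no time axis")
        lo, hi = window
        sel = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        if not np.any(sel):
            raise ValueError(f"window ({lo}, {hi}) ms contains no samples")
        return ChannelTuningFunction(
            aligned=self.aligned[:, sel].mean(axis=1),
            center=self.center,
            cond_means=None if self.cond_means is None
            else self.cond_means[:, :, sel].mean(axis=2),
            weights=None if self.weights is None
            else self.weights[:, :, sel].mean(axis=2),
            electrodes=self.electrodes,
        )

    def to_frame(self) -> pd.DataFrame:
        aligned = np.atleast_2d(self.aligned.T).T  # (k, T)
        times = self.times if self.times is not None else np.array([np.nan])
        k, t = aligned.shape
        off = np.arange(k) - (self.center - 1)
        ti, ki = np.meshgrid(np.arange(t), np.arange(k), indexing="ij")
        return pd.DataFrame({
            "time_ms": times[ti.ravel()],
            "channel_offset": off[ki.ravel()],
            "response": aligned[ki.ravel(), ti.ravel()],
        })


def canonical_ctf(responses: ChannelResponses, center: int = 4,
                  ) -> ChannelTuningFunction:
    """Align per-condition mean responses to a common centre and average.

    Condition p's k-vector is circularly shifted by (center - p) so that
    every condition's own channel lands on the centre channel; the shifted
    vectors are then averaged across conditions.
    """
    cond = responses.condition_means()
    k = cond.shape[0]
    if not (1 <= center <= k):
        raise ValueError(f"center channel must lie in 1..{k}")
    aligned = np.column_stack(
        [np.roll(cond[:, p - 1], center - p) for p in range(1, k + 1)])
    return ChannelTuningFunction(aligned=aligned.mean(axis=1), center=center,
                                 cond_means=cond)


def ctf_timecourse(epochs: EpochedData, folds: FoldAssignment,
                   center: int = 4, basis: BasisSet | None = None,
                   labels: np.ndarray | None = None,
                   ) -> ChannelTuningFunction:
    """Full train/invert/align pipeline at every time sample.

    Per fold and sample, weights are estimated on the training split and
    inverted on the held-out split; fold-wise channel responses are
    concatenated so every trial is tested exactly once, then averaged per
    condition, aligned, and averaged across conditions. The returned CTF
    also carries the per-condition means and the fold-averaged weight
    matrices for topography reconstruction.
    """
    labels = epochs.labels if labels is None else np.asarray(labels)
    k = int(labels.max())
    basis = BasisSet.delta(k) if basis is None else basis
    n_t = epochs.n_samples
    m = epochs.n_electrodes

    c2_all = np.full((k, epochs.n_trials, n_t), np.nan)
    w_sum = np.zeros((m, k, n_t))
    for train, test in folds.split():
        design = build_design(labels[train], basis)
        for ti in range(n_t):
            model = estimate_weights(epochs.data[train, :, ti].T, design,
                                     electrodes=epochs.electrodes)
            resp = invert_model(model, epochs.data[test, :, ti].T)
            c2_all[:, test, ti] = resp.C2
            w_sum[:, :, ti] += model.W
    w_mean = w_sum / folds.n_folds

    cond = np.empty((k, k, n_t))
    for p in range(1, k + 1):
        cond[:, p - 1, :] = c2_all[:, labels == p, :].mean(axis=1)
    aligned = np.stack(
        [np.roll(cond[:, p - 1, :], center - p, axis=0)
         for p in range(1, k + 1)]).mean(axis=0)
    return ChannelTuningFunction(aligned=aligned, center=center,
                                 times=epochs.times.copy(), cond_means=cond,
                                 weights=w_mean,
                                 electrodes=list(epochs.electrodes))


def ctf_tuning_stat(ctf_per_subject: np.ndarray, center: int = 4,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Paired t per time sample: centre-channel vs most peripheral channel.

    ``ctf_per_subject`` has shape (subjects, k, T). Zero-variance samples
    with a nonzero mean difference produce an infinite t (degenerate,
    flagged as inf rather than an error); zero mean with zero variance
    gives t = 0. Returns (t, p) arrays of length T; feed the differences
    to the cluster-permutation routines for multiple-comparison control.
    """
    arr = np.asarray(ctf_per_subject, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected subjects x channels x time")
    s, k, _ = arr.shape
    if s < 2:
        raise ValueError("need at least 2 subjects for a paired t-test")
    edge = (center - 1 + k // 2) % k
    diff = arr[:, center - 1, :] - arr[:, edge, :]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(s))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = 2 * sps.t.sf(np.abs(t), s - 1)
    return t, p


def fit_tuning_width(ctf: ChannelTuningFunction | np.ndarray,
                     center: int | None = None) -> tuple[float, float, float]:
    """Fit ``a * exp(-d^2 / (2 sigma^2)) + b`` to an aligned CTF.

    ``d`` is the circular channel distance from the centre channel.
    Returns ``(sigma, a, b)``. Accepts a collapsed (1-D)
    :class:`ChannelTuningFunction` or a bare aligned k-vector with an
    explicit 1-based ``center``.
    """
    from scipy.optimize import curve_fit

    if isinstance(ctf, ChannelTuningFunction):
        values = ctf.aligned
        center = ctf.center
    else:
        values = np.asarray(ctf, dtype=float)
        if center is None:
            raise ValueError("bare vectors require an explicit center")
    if values.ndim != 1:
        raise ValueError("collapse the time axis (average_window) first")
    k = len(values)
    d = np.abs(np.arange(k) - (center - 1))
    d = np.minimum(d, k - d).astype(float)

    def model(d, a, sigma, b):
        return a * np.exp(-d ** 2 / (2 * sigma ** 2)) + b

    p0 = [max(values.max() - values.min(), 1e-6), 1.0, float(values.min())]
    popt, _ = curve_fit(model, d, values, p0=p0, maxfev=20000)
    a, sigma, b = popt
    return abs(float(sigma)), float(a), float(b)


# ---------------------------------------------------------------------------
# Reconstruction of never-presented positions


def hypothetical_responses(ctf: ChannelTuningFunction) -> np.ndarray:
    """(k, k) matrix whose column p is the hypothetical channel-response
    vector for a stimulus at position p: the line-symmetrized canonical
    CTF circularly re-centred on channel p (the inverse of alignment)."""
    sym = ctf.symmetrized()
    if sym.ndim != 1:
        raise ValueError("collapse the time axis (average_window) first")
    k, c = ctf.k, ctf.center
    return np.column_stack([np.roll(sym, p - c) for p in range(1, k + 1)])


def interpolate_channel_response(ctf: ChannelTuningFunction,
                                 position,
                                 position_angles: np.ndarray | None = None,
                                 ) -> np.ndarray:
    """Channel-response vector for an arbitrary position on the circle.

    ``position`` is either a midpoint tag (``top``/``right``/``bottom``/
    ``left``, the midpoints of the adjacent-position pairs of the
    8-position display) or a continuous angle in degrees (clockwise from
    the top; requires ``position_angles`` for the k channels). The result
    is the correspondingly weighted average of the two neighbouring
    positions' hypothetical channel-response vectors.
    """
    hyp = hypothetical_responses(ctf)
    k = ctf.k
    if isinstance(position, str):
        if position not in MIDPOINT_PAIRS:
            raise ValueError(f"unknown midpoint tag {position!r}; use one of "
                             f"{sorted(MIDPOINT_PAIRS)}")
        if k != 8:
            raise ValueError("midpoint tags assume the 8-position display")
        a, b = MIDPOINT_PAIRS[position]
        return 0.5 * (hyp[:, a - 1] + hyp[:, b - 1])

    angle = float(position) % 360.0
    if position_angles is None:
        raise ValueError("continuous angles require position_angles")
    ang = np.asarray(position_angles, dtype=float) % 360.0
    if len(ang) != k:
        raise ValueError("position_angles must have one entry per channel")
    # find the adjacent pair (clockwise) whose arc contains the angle
    order = np.argsort(ang)
    for i in range(k):
        a_idx, b_idx = order[i], order[(i + 1) % k]
        lo, hi = ang[a_idx], ang[b_idx]
        span = (hi - lo) % 360.0
        offset = (angle - lo) % 360.0
        if offset <= span + 1e-9:
            w_b = offset / span if span > 0 else 0.0
            return (1 - w_b) * hyp[:, a_idx] + w_b * hyp[:, b_idx]
    raise ValueError(f"angle {angle} not on the circle parameterization")


def reconstruct_topography(model, response: np.ndarray,
                           electrodes: list[str] | None = None,
                           window: tuple[float, float] | None = None,
                           ) -> ActivationPattern:
    """Scalp topography predicted for a channel-response vector: W @ c."""
    W = model.W if isinstance(model, EncodingModel) else np.asarray(model)
    response = np.asarray(response, dtype=float)
    if W.shape[1] != response.shape[0]:
        raise ValueError("response length must equal the number of channels")
    if electrodes is None:
        electrodes = (model.electrodes if isinstance(model, EncodingModel)
                      and model.electrodes is not None
                      else [f"E{i + 1}" for i in range(W.shape[0])])
    return ActivationPattern(values=W @ response, electrodes=list(electrodes),
                             window=window)


def contrast_and_normalize(pattern_a: ActivationPattern,
                           pattern_b: ActivationPattern) -> ActivationPattern:
    """Elementwise difference (a - b) followed by spatial z-scoring."""
    if pattern_a.electrodes != pattern_b.electrodes:
        raise ValueError("patterns must share the same electrode set")
    diff = ActivationPattern(values=pattern_a.values - pattern_b.values,
                             electrodes=list(pattern_a.electrodes),
                             window=pattern_a.window)
    return spatial_normalize(diff)


def compare_patterns(group_a: np.ndarray, group_b: np.ndarray,
                     adjacency: np.ndarray, cluster_alpha: float = 0.05,
                     n_perm: int = 1000, seed: int | None = None):
    """Compare two groups of per-subject activation patterns.

    Returns ``(r, cluster_result)``: the Pearson correlation across
    electrodes of the two group-mean patterns, and per-electrode unpaired
    t-tests corrected by cluster-based permutation over the electrode
    adjacency graph. Patterns must already be restricted to the common
    electrode set.
    """
    from .stats import cluster_permutation_topo

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be subjects x electrodes over the "
                         "same electrodes")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    r = float(np.corrcoef(a.mean(axis=0), b.mean(axis=0))[0, 1])
    clusters = cluster_permutation_topo(a, b, adjacency,
                                        cluster_alpha=cluster_alpha,
                                        n_perm=n_perm, seed=seed)
    return r, clusters
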