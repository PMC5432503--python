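"""Condition-balanced ERP averaging and the N2pc difference wave.

The N2pc is the enhanced negativity over posterior scalp contralateral to
an attended target, conventionally measured at PO7/PO8 as the
contralateral-minus-ipsilateral difference for left- vs right-hemifield
targets. Targets on the vertical meridian have no contralateral
hemisphere, so no N2pc is defined for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochedData

#: Left/right position pairs at each vertical elevation of the 8-position
#: circular display (left-hemifield position, right-hemifield position),
#: positions numbered clockwise from the upper right. Shipped as a data
#: table so alternative display geometries can supply their own.
ELEVATION_PAIRS: dict[str, tuple[int, int]] = {
    "upper": (8, 1),
    "upper_middle": (7, 2),
    "lower_middle": (6, 3),
    "lower": (5, 4),
}


@dataclass
class Erp:
    """Averaged event-related potential (electrodes x samples, uV)."""

    values: np.ndarray
    times: np.ndarray
    electrodes: list[str]
    n_trials_per_cell: dict
    condition: str = ""

    def electrode_index(self, name: str) -> int:
        try:
            return self.electrodes.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in ERP") from None


@dataclass
class DifferenceWave:
    """Contralateral-minus-ipsilateral wave, one value per sample."""

    values: np.ndarray
    times: np.ndarray
    electrode_pair: tuple[str, str]
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.times,
            "value_uv": self.values,
            "condition": self.condition,
        })


def balanced_erp(epochs: EpochedData, cells, condition: str = "") -> Erp:
    """Average trials with equal weight per cell.

    ``cells`` assigns each trial to a balancing cell (an array-like of
    tags, or the name of a ``meta`` column). Each cell is averaged first
    and the cell means are then averaged with equal weight, so unequal
    cell sizes do not bias the ERP.
    """
    if isinstance(cells, str):
        if epochs.meta is None or cells not in epochs.meta:
            raise KeyError(f"meta column {cells!r} not found")
        cells = epochs.meta[cells].to_numpy()
    cells = np.asarray(cells)
    if len(cells) != epochs.n_trials:
        raise ValueError("cell tags must match trial count")

    uniq = pd.unique(cells)
    counts: dict = {}
    means = []
    for cell in uniq:
        idx = np.flatnonzero(cells == cell)
        if len(idx) == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"empty balancing cell: {cell!r}")
        counts[cell] = int(len(idx))
        means.append(epochs.data[idx].mean(axis=0))
    return Erp(
        values=np.mean(means, axis=0),
        times=epochs.times.copy(),
        electrodes=list(epochs.electrodes),
        n_trials_per_cell=counts,
        condition=condition,
    )


def n2pc(erp_left_target: Erp, erp_right_target: Erp,
         pair: tuple[str, str] = ("PO7", "PO8")) -> DifferenceWave:
    """Contralateral-minus-ipsilateral difference at a lateral electrode
    pair, averaged over left- and right-target ERPs.

    ``pair`` is (left-hemisphere electrode, right-hemisphere electrode).
    For left targets the contralateral site is the right electrode; for
    right targets the left electrode.
    """
    left_el, right_el = pair
    li_l = erp_left_target.electrode_index(left_el)
    ri_l = erp_left_target.electrode_index(right_el)
    li_r = erp_right_target.electrode_index(left_el)
    ri_r = erp_right_target.electrode_index(right_el)
    if len(erp_left_target.times) != len(erp_right_target.times):
        raise ValueError("ERPs have mismatching time axes")
    contra_minus_ipsi_left = (erp_left_target.values[ri_l]
                              - erp_left_target.values[li_l])
    contra_minus_ipsi_right = (erp_right_target.values[li_r]
                               - erp_right_target.values[ri_r])
    return DifferenceWave(
        values=0.5 * (contra_minus_ipsi_left + contra_minus_ipsi_right),
        times=erp_left_target.times.copy(),
        electrode_pair=pair,
        condition=f"{erp_left_target.condition}|{erp_right_target.condition}",
    )


def n2pc_from_epochs(epochs: EpochedData, left_label: int, right_label: int,
                     pair: tuple[str, str] = ("PO7", "PO8"),
                     position_angles: np.ndarray | None = None,
                     cells=None) -> DifferenceWave:
    """N2pc for one left-hemifield vs one right-hemifield target label.

    If ``position_angles`` (degrees clockwise from top, per label 1..k) is
    given, labels on the vertical meridian are refused: the N2pc is blind
    to targets above or below fixation by construction.
    """
    if position_angles is not None:
        for lab in (left_label, right_label):
            ang = float(position_angles[lab - 1]) % 360.0
            if np.isclose(np.sin(np.deg2rad(ang)), 0.0, atol=1e-9):
                raise ValueError(
                    f"label {lab} lies on the vertical meridian (angle "
                    f"{ang} deg); no contralateral hemisphere exists, so "
                    f"no N2pc can be computed")
    erps = []
    for lab in (left_label, right_label):
        idx = np.flatnonzero(epochs.labels == lab)
        if len(idx) == 0:
            raise ValueError(f"no trials with label {lab}")
        sub = epochs.select_trials(idx)
        sub_cells = (np.asarray(cells)[idx] if cells is not None
                     else np.zeros(len(idx), dtype=int))
        erps.append(balanced_erp(sub, sub_cells, condition=f"pos{lab}"))
    return n2pc(erps[0], erps[1], pair=pair)
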