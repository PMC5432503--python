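"""Reading and writing epoched data.

The native container is one HDF5 file holding the numeric arrays (data in
trials x electrodes x samples, times, labels) plus a JSON sidecar
(``<path>.json``) with the metadata a human might want to inspect without
opening the HDF5: sampling rate, electrode names, per-trial tags, and the
run-configuration hash when written by the pipeline. EEGLAB ``.set``
epochs (with or without a separate ``.fdt``) can be imported via MNE.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochedData

_SCHEMA = ("data", "times", "labels")


def write_epochs(epochs: EpochedData, path: str,
                 config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, compression="gzip")
        fh.create_dataset("times", data=epochs.times)
        fh.create_dataset("labels", data=epochs.labels)
        fh.attrs["sfreq"] = epochs.sfreq
    sidecar = {
        "sfreq": epochs.sfreq,
        "electrodes": list(epochs.electrodes),
        "units": "uV",
        "time_units": "ms",
        "n_trials": int(epochs.n_trials),
        "meta": None if epochs.meta is None
        else json.loads(epochs.meta.to_json(orient="split")),
    }
    if config_hash is not None:
        sidecar["config_hash"] = config_hash
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def _read_native(path: str) -> EpochedData:
    sidecar_path = path + ".json"
    if not os.path.exists(sidecar_path):
        raise FileNotFoundError(f"missing JSON sidecar: {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    for key in ("sfreq", "electrodes"):
        if key not in sidecar:
            raise ValueError(f"sidecar is missing required field {key!r}")
    with h5py.File(path, "r") as fh:
        for name in _SCHEMA:
            if name not in fh:
                raise ValueError(f"container is missing dataset {name!r}")
        data = fh["data"][()]
        times = fh["times"][()]
        labels = fh["labels"][()]
    meta = None
    if sidecar.get("meta") is not None:
        meta = pd.DataFrame(sidecar["meta"]["data"],
                            columns=sidecar["meta"]["columns"])
    return EpochedData(data=data, times=times, sfreq=float(sidecar["sfreq"]),
                       labels=labels, electrodes=sidecar["electrodes"],
                       meta=meta)


def _read_eeglab(path: str) -> EpochedData:
    """Import EEGLAB epochs; event types (parsed as integers where
    possible) become position labels."""
    import mne

    epo = mne.io.read_epochs_eeglab(path, verbose="error")
    data = epo.get_data(copy=True) * 1e6            # Volts -> microvolts
    times = epo.times * 1000.0                      # seconds -> ms
    code_to_label = {}
    for name, code in epo.event_id.items():
        token = name.split("/")[-1]
        try:
            code_to_label[code] = int(token)
        except ValueError:
            code_to_label[code] = code
    labels = np.array([code_to_label[c] for c in epo.events[:, 2]])
    return EpochedData(data=data, times=times, sfreq=float(epo.info["sfreq"]),
                       labels=labels, electrodes=list(epo.ch_names))


def read_epochs(path: str, format: str = "native") -> EpochedData:
    """Load epoched data from the native container or an EEGLAB .set."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "native":
        return _read_native(path)
    if format == "eeglab_set":
        return _read_eeglab(path)
    raise ValueError(f"unknown format {format!r}; use 'native' or 'eeglab_set'")
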