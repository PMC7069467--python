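"""Readers and writers for continuous recordings.

Two on-disk forms are supported:

* BrainVision Core Data Format triplets (``.vhdr``/``.vmrk``/``.eeg``),
  read through MNE; marker descriptions become event labels.
* A plain text format used by the synthetic generator: a tab-delimited
  channels x samples matrix (``<prefix>.data.tsv``), a JSON sidecar with
  rate and channel labels (``<prefix>.json``) and an events TSV with
  columns ``sample_index`` and ``label`` (``<prefix>.events.tsv``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocessing import Recording


def write_plain_recording(rec: Recording, prefix) -> Path:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".data.tsv"), rec.data, delimiter="\t", fmt="%.6f")
    sidecar = {"rate": rec.rate, "channel_labels": list(rec.channel_labels)}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    ev = pd.DataFrame(rec.events, columns=["sample_index", "label"])
    ev.to_csv(prefix.with_suffix(".events.tsv"), sep="\t", index=False)
    return prefix


def read_plain_recording(prefix) -> Recording:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".data.tsv"), delimiter="\t", ndmin=2)
    ev_path = prefix.with_suffix(".events.tsv")
    events = []
    if ev_path.exists():
        ev = pd.read_csv(ev_path, sep="\t")
        events = [(int(s), str(l)) for s, l in zip(ev["sample_index"], ev["label"])]
    return Recording(data=data, rate=float(sidecar["rate"]),
                     channel_labels=tuple(sidecar["channel_labels"]),
                     events=events)


def read_brainvision(vhdr_path, event_map=None) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording` (microvolts).

    ``event_map`` optionally renames marker descriptions to condition
    labels; unmapped markers keep their description.
    """
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE loads volts
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        label = (event_map or {}).get(desc, desc)
        events.append((int(round(onset * raw.info["sfreq"])), str(label)))
    if not np.all(np.isfinite(data_uv)):
        raise DataError(f"{vhdr_path}: non-finite samples")
    return Recording(data=data_uv, rate=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names), events=events)
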