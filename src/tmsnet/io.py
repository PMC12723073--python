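"""Readers for continuous EEG recordings (BrainVision, EDF) with marker-based
epoching into the internal :class:`~tmsnet.recording.EpochedRecording`."""

from __future__ import annotations

import numpy as np

from .recording import EpochedRecording

__all__ = ["epochs_from_raw", "read_brainvision", "read_edf"]


def epochs_from_raw(
    raw,
    onset_samples,
    tmin_s: float = -1.0,
    tmax_s: float = 1.0,
    picks: list[str] | None = None,
) -> EpochedRecording:
    """Cut fixed-length epochs around event onsets from an mne Raw object.

    ``onset_samples`` are event positions in samples.  Events whose epoch
    would extend past the recording are dropped.  Data are converted from
    mne's volts to microvolts.
    """
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=picks) * 1e6  # V -> uV
    labels = picks if picks is not None else list(raw.ch_names)
    pre = int(round(-tmin_s * fs))
    post = int(round(tmax_s * fs))
    n = data.shape[1]
    trials = []
    for onset in np.asarray(onset_samples, dtype=int):
        if onset - pre < 0 or onset + post > n:
            continue
        trials.append(data[:, onset - pre : onset + post])
    if len(trials) < 2:
        raise ValueError("fewer than 2 complete epochs around the given markers")
    stacked = np.stack(trials, axis=1)  # channels x trials x samples
    time_s = (np.arange(stacked.shape[2]) - pre) / fs
    return EpochedRecording(
        data=stacked,
        time_s=time_s,
        fs_hz=fs,
        channel_labels=labels,
        onset_index=pre,
        meta={"n_events": len(trials)},
    )


def _find_stim_onsets(raw, stim_label: str | None):
    import mne

    events, event_id = mne.events_from_annotations(raw, verbose="error")
    if stim_label is not None:
        keys = [k for k in event_id if stim_label in k]
        if not keys:
            raise ValueError(f"no annotation matching '{stim_label}'")
        codes = {event_id[k] for k in keys}
        events = events[np.isin(events[:, 2], list(codes))]
    return events[:, 0]


def read_brainvision(
    vhdr_path, stim_label: str | None = None, tmin_s: float = -1.0, tmax_s: float = 1.0
) -> EpochedRecording:
    """Epoch a BrainVision (.vhdr/.vmrk/.eeg) recording around its markers."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return epochs_from_raw(raw, _find_stim_onsets(raw, stim_label), tmin_s, tmax_s)


def read_edf(
    edf_path, stim_label: str | None = None, tmin_s: float = -1.0, tmax_s: float = 1.0
) -> EpochedRecording:
    """Epoch an EDF recording around its annotation markers."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    return epochs_from_raw(raw, _find_stim_onsets(raw, stim_label), tmin_s, tmax_s)
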