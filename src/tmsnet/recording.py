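"""Epoched multi-trial EEG container and its HDF5 serialization.

The :class:`EpochedRecording` is the common currency of the pipeline: a
``channels x trials x samples`` array with a uniform time axis expressed in
seconds relative to the stimulus (TMS pulse) onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochedRecording", "save_cohort", "load_cohort"]


@dataclass
class EpochedRecording:
    """Epoched EEG data for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_trials, n_samples)
        Signal in microvolts.
    time_s : ndarray, shape (n_samples,)
        Time of each sample relative to stimulus onset, in seconds.
        Strictly increasing with uniform step ``1 / fs_hz``.
    fs_hz : float
        Sampling rate in Hz.
    channel_labels : list of str
    onset_index : int
        Sample index at which ``time_s`` is (numerically) zero.
    meta : dict
        Free-form provenance (e.g. the ordered list of preprocessing steps).
    """

    data: np.ndarray
    time_s: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    onset_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.validate()

    # -- basic introspection ------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be channels x trials x samples")
        if self.time_s.shape != (self.data.shape[2],):
            raise ValueError("time axis does not match the sample dimension")
        dt = np.diff(self.time_s)
        if not np.all(dt > 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-6, atol=1e-12):
            raise ValueError("time axis step does not match fs_hz")
        if not 0 <= self.onset_index < self.n_samples:
            raise ValueError("onset_index out of range")
        if abs(self.time_s[self.onset_index]) > 0.51 / self.fs_hz:
            raise ValueError("onset_index inconsistent with time axis")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data")

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            data=self.data.copy(),
            time_s=self.time_s.copy(),
            fs_hz=self.fs_hz,
            channel_labels=list(self.channel_labels),
            onset_index=self.onset_index,
            meta=dict(self.meta),
        )

    def sample_window(self, span_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples whose time lies in the closed interval
        ``[span_ms[0], span_ms[1]]`` (milliseconds relative to onset)."""
        lo, hi = span_ms
        eps = 0.5 / self.fs_hz  # half-sample tolerance against float jitter
        t = self.time_s
        return (t >= lo / 1e3 - eps * 1e-6) & (t <= hi / 1e3 + eps * 1e-6)


def save_cohort(path, cohort: list[EpochedRecording]) -> None:
    """Write a list of recordings to the internal HDF5 epochs container.

    Layout: ``/subject_<k>/data``, ``/subject_<k>/time_s`` with attributes
    ``fs_hz``, ``channel_labels``, ``onset_index`` on each subject group.
    """
    with h5py.File(path, "w") as f:
        for k, rec in enumerate(cohort):
            g = f.create_group(f"subject_{k}")
            g.create_dataset("data", data=rec.data)
            g.create_dataset("time_s", data=rec.time_s)
            g.attrs["fs_hz"] = rec.fs_hz
            g.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
            g.attrs["onset_index"] = int(rec.onset_index)
            for key, val in rec.meta.items():
                if isinstance(val, (str, int, float)):
                    g.attrs[f"meta_{key}"] = val


def load_cohort(path) -> list[EpochedRecording]:
    """Read the internal HDF5 epochs container written by :func:`save_cohort`."""
    cohort = []
    with h5py.File(path, "r") as f:
        keys = sorted(
            (k for k in f.keys() if k.startswith("subject_")),
            key=lambda k: int(k.split("_")[1]),
        )
        for k in keys:
            g = f[k]
            meta = {
                a[len("meta_"):]: g.attrs[a] for a in g.attrs if a.startswith("meta_")
            }
            cohort.append(
                EpochedRecording(
                    data=g["data"][()],
                    time_s=g["time_s"][()],
                    fs_hz=float(g.attrs["fs_hz"]),
                    channel_labels=[
                        c.decode() if isinstance(c, bytes) else str(c)
                        for c in g.attrs["channel_labels"]
                    ],
                    onset_index=int(g.attrs["onset_index"]),
                    meta=meta,
                )
            )
    return cohort
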