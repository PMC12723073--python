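"""Trial-wise phase-locking connectivity (PLV and corrected-imaginary PLV).

For a channel pair (x, y) at wavelet cell (scale s, time k) with unit phasors
``u = exp(i * dphi)`` of the cross-trial phase differences:

    PLV(k, s)   = | (1/Nt) sum_n u_n |                      in [0, 1]
    ciPLV(k, s) = Im(P) / sqrt(1 - Re(P)**2),  P = mean(u)  in [-1, 1]

PLV counts any consistent phase relation, including the zero-lag relations
produced by instantaneous field spread (volume conduction); ciPLV discounts
the real (zero-lag) part of the mean phasor and retains only lagged
interactions.  Connectivity matrices average these fields over the
COI-valid cells of a frequency band and an analysis window; for ciPLV the
*signed* field is averaged and the magnitude of the average is stored, so
zero-mean noise around a zero-lag interaction cancels instead of
accumulating as a positive bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import EpochedRecording
from .wavelet import WaveletParams, WaveletSpectrum, coi_for, cwt, default_freq_grid

__all__ = [
    "BandSpec",
    "BANDS",
    "AnalysisWindow",
    "PRESTIMULUS",
    "POSTSTIMULUS",
    "ConnectivityMatrix",
    "BandInvalidError",
    "plv",
    "ciplv",
    "band_window_average",
    "pairwise_mean_phasor",
    "build_connectivity",
    "connectivity_suite",
]


@dataclass(frozen=True)
class BandSpec:
    """Frequency band; membership is by scale center frequency, half-open
    ``[low, high)`` except the topmost analysis band whose upper edge is
    closed (``closed_top=True``)."""

    name: str
    low_hz: float
    high_hz: float
    closed_top: bool = False

    def member(self, freqs_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs_hz)
        upper = f <= self.high_hz if self.closed_top else f < self.high_hz
        return (f >= self.low_hz) & upper


BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta1": BandSpec("beta1", 13.0, 19.0),
    "beta2": BandSpec("beta2", 19.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 70.0, closed_top=True),
    "global": BandSpec("global", 4.0, 70.0, closed_top=True),
}

#: excluded from the analysis set; kept nameable so the short-window
#: invalidity is an explicit, testable error
DELTA = BandSpec("delta", 1.0, 4.0)


@dataclass(frozen=True)
class AnalysisWindow:
    label: str
    span_ms: tuple[float, float]

    @property
    def length_s(self) -> float:
        return (self.span_ms[1] - self.span_ms[0]) / 1e3


PRESTIMULUS = AnalysisWindow("prestimulus", (-1000.0, 0.0))
POSTSTIMULUS = AnalysisWindow("poststimulus", (15.0, 315.0))


class BandInvalidError(ValueError):
    """No COI-valid cells exist for a band in the given window."""

    def __init__(self, band_name: str, window_len_s: float):
        super().__init__(
            f"band '{band_name}' has no COI-valid cells in a "
            f"{window_len_s * 1e3:.0f} ms window (Heisenberg box does not fit)"
        )
        self.band_name = band_name
        self.window_len_s = window_len_s


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel weights in [0, 1], zero diagonal."""

    weights: np.ndarray
    estimator: str
    band: BandSpec
    window: AnalysisWindow
    subject: int | str | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-7):
            raise ValueError("weights must be symmetric")
        self.weights = w


def _unit_phasors(coeffs: np.ndarray) -> np.ndarray:
    mag = np.abs(coeffs)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mag > 0, coeffs / mag, 0.0)
    return u.astype(np.complex64, copy=False)


def _check_pair(cx: np.ndarray, cy: np.ndarray) -> None:
    if cx.shape != cy.shape:
        raise ValueError("channel slices must share trial count and grid")
    if cx.shape[0] < 2:
        raise ValueError("phase locking across trials needs >= 2 trials")


def plv(coeffs_x: np.ndarray, coeffs_y: np.ndarray) -> np.ndarray:
    """Trial-wise phase-locking value field.

    Inputs are complex coefficient slices of one channel each, shape
    (trials, scales, times); returns the (scales, times) PLV field: the
    modulus of the trial-averaged unit phasor of the phase difference.
    """
    cx, cy = np.asarray(coeffs_x), np.asarray(coeffs_y)
    _check_pair(cx, cy)
    u = _unit_phasors(cx) * np.conj(_unit_phasors(cy))
    return np.abs(u.mean(axis=0)).astype(float)


def _signed_ciplv(p: np.ndarray) -> np.ndarray:
    re2 = np.square(p.real.astype(float))
    denom2 = 1.0 - re2
    out = np.zeros_like(denom2)
    ok = denom2 > 1e-12  # |Re| = 1: perfect zero-lag locking carries no lag
    out[ok] = p.imag.astype(float)[ok] / np.sqrt(denom2[ok])
    return np.clip(out, -1.0, 1.0)


def ciplv(
    coeffs_x: np.ndarray, coeffs_y: np.ndarray, mode: str = "trials"
) -> np.ndarray:
    """Signed corrected-imaginary PLV field in [-1, 1].

    ``mode='trials'`` (default) averages the unit phasors across trials,
    estimating on the same ensemble as :func:`plv` and yielding a
    (scales, times) field.  ``mode='time'`` averages across time within each
    trial (the single-trial, data-length-normalized reading) and yields a
    (trials, scales) array.
    """
    cx, cy = np.asarray(coeffs_x), np.asarray(coeffs_y)
    _check_pair(cx, cy)
    u = _unit_phasors(cx) * np.conj(_unit_phasors(cy))
    if mode == "trials":
        return _signed_ciplv(u.mean(axis=0))
    if mode == "time":
        return _signed_ciplv(u.mean(axis=-1))
    raise ValueError("mode must be 'trials' or 'time'")


def band_window_average(
    values: np.ndarray,
    band: BandSpec,
    coi_valid: np.ndarray,
    freqs_hz: np.ndarray,
    window_len_s: float | None = None,
) -> float:
    """Unweighted mean of a (scales, times) field over the COI-valid cells
    whose scale center frequency falls in the band.

    Raises :class:`BandInvalidError` when the valid set is empty -- the
    mechanism that excludes the delta band from short response windows.
    """
    values = np.asarray(values)
    sel = band.member(freqs_hz)
    mask = coi_valid & sel[:, None]
    if not mask.any():
        if window_len_s is None:
            window_len_s = float("nan")
        raise BandInvalidError(band.name, window_len_s)
    return float(values[mask].mean())


try:  # optional JIT of the innermost accumulation; numpy path is equivalent
    import math as _math

    import numba

    @numba.njit(cache=True, fastmath=True)
    def _normalize_inplace(a, b):  # pragma: no cover - exercised via the wrapper
        n_ch, n_tr, k = a.shape
        for c in range(n_ch):
            for n in range(n_tr):
                ar = a[c, n]
                br = b[c, n]
                for kk in range(k):
                    # scale by the component maximum first: tiny coefficients
                    # would otherwise underflow in the float32 square/sum
                    # (and overflow to inf in the division)
                    av = abs(ar[kk])
                    bv = abs(br[kk])
                    mm = av if av >= bv else bv
                    if mm > 0.0:
                        x = ar[kk] / mm
                        y = br[kk] / mm
                        m = _math.sqrt(x * x + y * y)
                        ar[kk] = x / m
                        br[kk] = y / m
                    else:
                        ar[kk] = 0.0
                        br[kk] = 0.0

    @numba.njit(cache=True, fastmath=True)
    def _pair_accum(a, b):  # pragma: no cover - exercised via the wrapper
        n_ch, n_tr, k = a.shape
        g_re = np.zeros((n_ch, n_ch, k), dtype=np.float32)
        g_im = np.zeros((n_ch, n_ch, k), dtype=np.float32)
        for c in range(n_ch):
            for d in range(c, n_ch):
                re = g_re[c, d]
                im = g_im[c, d]
                for n in range(n_tr):
                    ac = a[c, n]
                    bc = b[c, n]
                    ad = a[d, n]
                    bd = b[d, n]
                    for kk in range(k):
                        re[kk] += ac[kk] * ad[kk] + bc[kk] * bd[kk]
                        im[kk] += bc[kk] * ad[kk] - ac[kk] * bd[kk]
                g_re[d, c] = re
                g_im[d, c] = -im
        return g_re, g_im

except ImportError:  # pragma: no cover
    _pair_accum = None
    _normalize_inplace = None


def _pair_accum_numpy(a, b):
    at = a.transpose(2, 0, 1)  # (K, C, Nt)
    bt = b.transpose(2, 0, 1)
    att = at.transpose(0, 2, 1)
    btt = bt.transpose(0, 2, 1)
    g_re = np.matmul(at, att) + np.matmul(bt, btt)
    g_im = np.matmul(bt, att) - np.matmul(at, btt)
    return g_re.transpose(1, 2, 0), g_im.transpose(1, 2, 0)


def pairwise_mean_phasor(spec: WaveletSpectrum) -> np.ndarray:
    """Trial-averaged cross phasor for all channel pairs.

    Returns ``P`` with shape (channels, channels, scales, times) where
    ``P[x, y] = mean_n u_x * conj(u_y)``; Hermitian in the channel axes.
    The accumulation over trials runs in a JIT-compiled kernel when numba is
    importable, which is what keeps cohort-scale simulations fast.
    """
    n_ch, n_tr, n_s, n_t = spec.coeffs.shape
    if _pair_accum is not None:
        # JIT path: normalize the raw coefficient copies in place, then
        # accumulate; avoids the large complex unit-phasor temporary
        flat = spec.coeffs.reshape(n_ch, n_tr, n_s * n_t)
        a = np.ascontiguousarray(flat.real, dtype=np.float32)
        b = np.ascontiguousarray(flat.imag, dtype=np.float32)
        _normalize_inplace(a, b)
        g_re, g_im = _pair_accum(a, b)
    else:
        u = _unit_phasors(spec.coeffs)
        flat = u.reshape(n_ch, n_tr, n_s * n_t)
        a = np.ascontiguousarray(flat.real, dtype=np.float32)
        b = np.ascontiguousarray(flat.imag, dtype=np.float32)
        g_re, g_im = _pair_accum_numpy(a, b)
    p = (g_re + 1j * g_im) / n_tr
    return p.reshape(n_ch, n_ch, n_s, n_t)


def _matrix_from_field(
    field: np.ndarray, band: BandSpec, coi_valid: np.ndarray, freqs_hz, window_len_s
) -> np.ndarray:
    sel = band.member(freqs_hz)
    mask = coi_valid & sel[:, None]
    n_valid = mask.sum()
    if n_valid == 0:
        raise BandInvalidError(band.name, window_len_s)
    w = (field * mask).sum(axis=(-2, -1)) / n_valid
    np.fill_diagonal(w, 0.0)
    return w


def matrices_from_spectrum(
    spec: WaveletSpectrum,
    bands,
    estimators=("plv",),
    subject=None,
    window: AnalysisWindow | None = None,
) -> dict[tuple[str, str], ConnectivityMatrix]:
    """All (estimator, band) connectivity matrices from one windowed spectrum.

    The pairwise mean phasor is computed once and reused across estimators
    and bands.  For PLV the per-cell modulus field is averaged; for ciPLV the
    signed field is averaged and its magnitude stored.
    """
    if window is None:
        window = AnalysisWindow(spec.window_label, spec.window_span_ms)
    p = pairwise_mean_phasor(spec)
    coi = coi_for(spec)
    fields = {}
    if "plv" in estimators:
        fields["plv"] = np.abs(p)
    if "ciplv" in estimators:
        fields["ciplv"] = _signed_ciplv(p)
    out = {}
    for est in estimators:
        field = fields[est]
        for band in bands:
            band = BANDS[band] if isinstance(band, str) else band
            w = _matrix_from_field(
                field, band, coi, spec.freqs_hz, spec.window_len_s
            )
            if est == "ciplv":
                w = np.abs(w)
            w = 0.5 * (w + w.T)  # exact symmetry against float noise
            out[(est, band.name)] = ConnectivityMatrix(
                weights=w, estimator=est, band=band, window=window, subject=subject
            )
    return out


def build_connectivity(
    rec: EpochedRecording,
    window: AnalysisWindow,
    band: BandSpec | str,
    estimator: str = "plv",
    freqs_hz=None,
    params: WaveletParams = WaveletParams(),
    subject=None,
) -> ConnectivityMatrix:
    """One connectivity matrix for a (window, band, estimator) combination."""
    band = BANDS[band] if isinstance(band, str) else band
    if freqs_hz is None:
        freqs_hz = default_freq_grid()
    spec = cwt(rec, window, freqs_hz, params)
    return matrices_from_spectrum(
        spec, [band], estimators=(estimator,), subject=subject, window=window
    )[(estimator, band.name)]


def connectivity_suite(
    rec: EpochedRecording,
    windows=(PRESTIMULUS, POSTSTIMULUS),
    bands=tuple(BANDS),
    estimators=("plv",),
    freqs_hz=None,
    params: WaveletParams = WaveletParams(),
    subject=None,
) -> dict[tuple[str, str, str], ConnectivityMatrix]:
    """Matrices for every (window, estimator, band); one CWT per window.

    Keys are ``(window_label, estimator, band_name)``.
    """
    if freqs_hz is None:
        freqs_hz = default_freq_grid()
    out = {}
    for window in windows:
        spec = cwt(rec, window, freqs_hz, params)
        mats = matrices_from_spectrum(
            spec, bands, estimators=estimators, subject=subject, window=window
        )
        for (est, band_name), mat in mats.items():
            out[(window.label, est, band_name)] = mat
    return out
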