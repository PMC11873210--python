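"""Acoustic feature representations for the ideal observer.

The raw acoustic input is the stacked vector ``[itd_jnd, X_l, X_r]`` of
length ``2N + 1``: the ITD in jnd units followed by the left- and right-ear
log-magnitude spectra (dB) on ``N`` ERB channels.  Each representation is a
linear map ``A`` of this vector (possibly followed by a fixed nonlinearity),
so Gaussian likelihoods propagate as ``A Sigma A^T``:

==========  =======================================================  ======
tag         linear part                                              dim
==========  =======================================================  ======
LOGMAG      identity                                                 2N + 1
ISD         [itd, X_l - X_r]                                         N + 1
BIN_SG      [itd, ILD, dX_l, dX_r]                                   2N
POS_SG      BIN_SG matrix, SG entries then half-wave rectified       2N
IPSI_SG     BIN_SG matrix, contralateral SG block dropped at decode  N + 1
==========  =======================================================  ======

where ILD is the channel-mean of ``X_l - X_r`` and ``dX`` is the first
difference across neighbouring channels (dB per channel step).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .erb import ChannelSpectrum, ErbFilterbank

__all__ = [
    "Representation",
    "FeatureMap",
    "ild",
    "sg",
    "isd",
    "positive_sg",
    "select_ipsilateral",
    "diff_matrix",
    "build_feature_map",
    "source_injection_matrix",
]


class Representation(str, Enum):
    LOGMAG = "LOGMAG"
    ISD = "ISD"
    BIN_SG = "BIN_SG"
    POS_SG = "POS_SG"
    IPSI_SG = "IPSI_SG"


def _check_same_fb(xl: ChannelSpectrum, xr: ChannelSpectrum) -> None:
    if xl.filterbank is not xr.filterbank and not np.array_equal(
        xl.filterbank.centre_frequencies_hz, xr.filterbank.centre_frequencies_hz
    ):
        raise ValueError("left/right spectra live on different filterbanks")


def ild(xl: ChannelSpectrum, xr: ChannelSpectrum) -> float:
    """Broadband interaural level difference: channel mean of left - right (dB)."""
    _check_same_fb(xl, xr)
    return float(np.mean(xl.values_db - xr.values_db))


def sg(x: ChannelSpectrum | np.ndarray) -> np.ndarray:
    """Spectral gradient: first difference across neighbouring channels."""
    v = x.values_db if isinstance(x, ChannelSpectrum) else np.asarray(x, float)
    if v.size < 2:
        raise ValueError("spectral gradient needs at least two channels")
    return np.diff(v)


def isd(xl: ChannelSpectrum, xr: ChannelSpectrum) -> np.ndarray:
    """Interaural spectral difference, channelwise left - right (dB).

    Invariant to any source spectrum added identically to both ears.
    """
    _check_same_fb(xl, xr)
    return xl.values_db - xr.values_db


def positive_sg(g: np.ndarray) -> np.ndarray:
    """Half-wave rectified spectral gradient: entrywise max(0, g). Idempotent."""
    return np.maximum(0.0, np.asarray(g, float))


def select_ipsilateral(
    g_left: np.ndarray, g_right: np.ndarray, measured_itd_jnd: float
) -> np.ndarray:
    """Gradient of the ear the measured ITD points toward.

    Positive ITD means the left ear leads (source on the left), so the left
    gradient is returned; ITD exactly zero resolves to left by convention.
    """
    return np.asarray(g_left if measured_itd_jnd >= 0 else g_right, float)


def diff_matrix(n: int) -> np.ndarray:
    """(n-1) x n first-difference matrix D with (D x)_i = x[i+1] - x[i]."""
    if n < 2:
        raise ValueError("need at least two channels")
    return np.diff(np.eye(n), axis=0)


@dataclass(frozen=True)
class FeatureMap:
    """A representation as an explicit linear map on ``[itd, X_l, X_r]``.

    ``matrix`` has shape (n_features, 2N+1); ``postnonlinearity`` is one of
    ``'none'``, ``'rectify'`` (half-wave rectify the SG entries, POS_SG) or
    ``'ipsilateral-select'`` (drop the contralateral SG block at decode
    time, IPSI_SG).  ``sg_slice`` marks the SG rows the nonlinearity acts
    on; ``left_sg_slice``/``right_sg_slice`` locate the two ear blocks.
    """

    representation: Representation
    matrix: np.ndarray
    postnonlinearity: str
    n_channels: int

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def sg_slice(self) -> slice:
        if self.representation in (
            Representation.BIN_SG,
            Representation.POS_SG,
            Representation.IPSI_SG,
        ):
            return slice(2, self.matrix.shape[0])
        return slice(0, 0)

    @property
    def left_sg_slice(self) -> slice:
        return slice(2, 2 + self.n_channels - 1)

    @property
    def right_sg_slice(self) -> slice:
        return slice(2 + self.n_channels - 1, 2 + 2 * (self.n_channels - 1))

    def apply(self, stacked: np.ndarray) -> np.ndarray:
        """Apply the linear part (and rectification for POS_SG) to a stacked
        ``[itd, X_l, X_r]`` vector or batch of rows."""
        out = stacked @ self.matrix.T
        if self.postnonlinearity == "rectify":
            out = np.array(out, copy=True)
            out[..., self.sg_slice] = np.maximum(0.0, out[..., self.sg_slice])
        return out

    def to_dict(self) -> dict:
        return {
            "representation": self.representation.value,
            "matrix": self.matrix.tolist(),
            "postnonlinearity": self.postnonlinearity,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMap":
        return cls(
            Representation(d["representation"]),
            np.asarray(d["matrix"], float),
            d["postnonlinearity"],
            int(d["n_channels"]),
        )


def build_feature_map(representation: Representation | str, fb: ErbFilterbank) -> FeatureMap:
    """Construct the explicit linear map for a representation on ``fb``.

    The matrix acts on the stacked raw vector ``[itd_jnd, X_l, X_r]``
    (length 2N+1) and reproduces :func:`ild`, :func:`sg` and :func:`isd`
    exactly.
    """
    rep = Representation(representation)
    n = fb.n_channels
    e_itd = np.zeros((1, 2 * n + 1))
    e_itd[0, 0] = 1.0

    if rep is Representation.LOGMAG:
        return FeatureMap(rep, np.eye(2 * n + 1), "none", n)

    if rep is Representation.ISD:
        m = np.zeros((n, 2 * n + 1))
        m[:, 1 : n + 1] = np.eye(n)
        m[:, n + 1 :] = -np.eye(n)
        return FeatureMap(rep, np.vstack([e_itd, m]), "none", n)

    # SG family: [itd, ILD, dX_l, dX_r]
    ild_row = np.zeros((1, 2 * n + 1))
    ild_row[0, 1 : n + 1] = 1.0 / n
    ild_row[0, n + 1 :] = -1.0 / n
    d = diff_matrix(n)
    dl = np.zeros((n - 1, 2 * n + 1))
    dl[:, 1 : n + 1] = d
    dr = np.zeros((n - 1, 2 * n + 1))
    dr[:, n + 1 :] = d
    matrix = np.vstack([e_itd, ild_row, dl, dr])

    if rep is Representation.BIN_SG:
        return FeatureMap(rep, matrix, "none", n)
    if rep is Representation.POS_SG:
        return FeatureMap(rep, matrix, "rectify", n)
    if rep is Representation.IPSI_SG:
        return FeatureMap(rep, matrix, "ipsilateral-select", n)
    raise ValueError(f"unknown representation {representation!r}")


def source_injection_matrix(fmap: FeatureMap) -> np.ndarray:
    """Map from a source spectrum S (length N) into feature space.

    A source spectrum enters the raw vector as ``[0, S, S]``; composing with
    the feature map gives the matrix J with which source-spectrum
    uncertainty propagates into the feature covariance (``J Sigma_S J^T``).
    For ISD (and the ILD coordinate) J vanishes identically.
    """
    n = fmap.n_channels
    j_raw = np.zeros((2 * n + 1, n))
    j_raw[1 : n + 1] = np.eye(n)
    j_raw[n + 1 :] = np.eye(n)
    return fmap.matrix @ j_raw
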