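"""Source-spectrum priors.

The observer's expectation about unknown source spectra is a multivariate
Gaussian over the N ERB-channel log-magnitudes (or the N-1 spectral
gradients): a mean spectrum plus a covariance matrix.  An "ecologically
valid" prior is estimated by pooling 0.2-s frames from audio corpora
(environmental sounds, speech); a "narrow" prior with small isotropic
variance models an observer who knows the stimulus spectrum.

Empirically, corpus priors share a characteristic structure: a large
common-level variance (sounds differ mostly in overall level), inter-channel
correlations decaying with channel distance, and a mean spectrum falling by
a few tens of dB toward high frequencies.  The synthetic corpus generator
reproduces exactly these features for testing without audio downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .erb import ChannelSpectrum, ErbFilterbank, erb_number
from .features import diff_matrix

__all__ = ["SourcePrior", "build_prior", "to_sg_prior", "narrow_prior", "synth_corpus"]

log = logging.getLogger(__name__)


@dataclass
class SourcePrior:
    """Gaussian prior on source spectra: mean (dB) and covariance (dB^2).

    ``representation`` is ``'LOGMAG'`` (length N) or ``'SG'`` (length N-1,
    units dB per channel step).
    """

    mean: np.ndarray
    cov: np.ndarray
    representation: str
    provenance: str = "unknown"
    filterbank: Optional[ErbFilterbank] = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        k = self.mean.size
        if self.cov.shape != (k, k):
            raise ValueError(f"covariance shape {self.cov.shape} != ({k}, {k})")
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        tr = max(np.trace(self.cov), 1.0)
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-8 * tr:
            raise ValueError("covariance is not positive semidefinite")
        if self.representation not in ("LOGMAG", "SG"):
            raise ValueError(f"unknown representation {self.representation!r}")

    @property
    def sg_std_db_per_erb(self) -> float:
        """Root-mean diagonal of the SG-domain covariance (dB/ERB).

        The single number summarizing how much spectral-gradient variation
        the observer expects from a source.
        """
        p = self if self.representation == "SG" else to_sg_prior(self)
        return float(np.sqrt(np.mean(np.diag(p.cov))))

    def save(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "representation": self.representation,
            "provenance": self.provenance,
            "filterbank": self.filterbank.to_dict() if self.filterbank else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SourcePrior":
        with open(path) as fh:
            d = json.load(fh)
        fb = ErbFilterbank.from_dict(d["filterbank"]) if d.get("filterbank") else None
        return cls(
            np.asarray(d["mean"], float),
            np.asarray(d["cov"], float),
            d["representation"],
            d.get("provenance", "unknown"),
            fb,
        )


def _repair_psd(cov: np.ndarray) -> np.ndarray:
    """Clip slightly negative eigenvalues (numerical noise) to zero."""
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(np.trace(cov), 1.0):
        log.warning("clipping negative covariance eigenvalues (min %.3g)", w.min())
        cov = (v * np.maximum(w, 0.0)) @ v.T
        cov = (cov + cov.T) / 2.0
    return cov


def build_prior(
    frames: Iterable[ChannelSpectrum] | np.ndarray,
    provenance: str = "corpus",
    fb: Optional[ErbFilterbank] = None,
) -> SourcePrior:
    """Pool channel spectra into a LOGMAG prior (sample mean, unbiased cov)."""
    if isinstance(frames, np.ndarray):
        data = np.atleast_2d(np.asarray(frames, float))
    else:
        frames = list(frames)
        if frames:
            fb = fb or frames[0].filterbank
        data = np.array([f.values_db for f in frames])
    if data.shape[0] < 2:
        raise ValueError("need at least two frames to estimate a covariance")
    mean = data.mean(axis=0)
    cov = _repair_psd(np.cov(data, rowvar=False, ddof=1))
    return SourcePrior(mean, cov, "LOGMAG", provenance, fb)


def to_sg_prior(p: SourcePrior) -> SourcePrior:
    """Push a LOGMAG prior through the first-difference map.

    ``mean_SG = D mean``, ``cov_SG = D cov D^T``: any common-level (rank-one
    ``c 11^T``) component of the LOGMAG covariance vanishes exactly since
    ``D 1 = 0``.
    """
    if p.representation != "LOGMAG":
        raise ValueError("expected a LOGMAG prior")
    if p.mean.size < 2:
        raise ValueError("need at least two channels")
    d = diff_matrix(p.mean.size)
    return SourcePrior(d @ p.mean, d @ p.cov @ d.T, "SG", p.provenance, p.filterbank)


def narrow_prior(reference: ChannelSpectrum | np.ndarray, sigma_db: float,
                 fb: Optional[ErbFilterbank] = None) -> SourcePrior:
    """Narrow ad-hoc prior: the observer (nearly) knows the source spectrum.

    Mean = reference spectrum, covariance = ``sigma_db^2 I``.  ``sigma_db=0``
    is the known-spectrum limit.
    """
    if sigma_db < 0:
        raise ValueError("sigma must be non-negative")
    if isinstance(reference, ChannelSpectrum):
        mean, fb = reference.values_db, reference.filterbank
    else:
        mean = np.asarray(reference, float)
    return SourcePrior(mean, sigma_db**2 * np.eye(mean.size), "LOGMAG", "narrow", fb)


def synth_corpus(
    fb: ErbFilterbank,
    n_frames: int = 20000,
    *,
    slope_db_total: float = -30.0,
    level_variance_db2: float = 150.0,
    channel_std_db: float = 9.5,
    correlation_length_erb: float = 2.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw synthetic corpus frames (rows of channel dB values).

    The generating Gaussian has a mean falling linearly (on the ERB axis) by
    ``slope_db_total`` dB across the band, plus a covariance made of a
    common-level term ``level_variance_db2 * 11^T`` and per-channel
    fluctuations of standard deviation ``channel_std_db`` whose correlation
    decays exponentially with channel distance (length
    ``correlation_length_erb`` in ERB).  Deterministic given ``seed``.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if level_variance_db2 < 0 or channel_std_db < 0 or correlation_length_erb < 0:
        raise ValueError("variance parameters must be non-negative")
    n = fb.n_channels
    e = erb_number(fb.centre_frequencies_hz)
    frac = (e - e[0]) / (e[-1] - e[0]) if n > 1 else np.zeros(1)
    mean = slope_db_total * frac
    dist = np.abs(e[:, None] - e[None, :])
    if correlation_length_erb > 0:
        corr = np.exp(-dist / correlation_length_erb)
    else:
        corr = np.eye(n)
    cov = level_variance_db2 + channel_std_db**2 * corr
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mean, cov, size=n_frames, method="cholesky")
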