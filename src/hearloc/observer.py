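"""The ideal-observer decoder.

Given an acoustic input ``X`` the observer computes the posterior over
source directions

    P(theta | X)  proportional to  P(X | theta) P(theta),

with a multivariate-normal likelihood ``P(X|theta) = N(T(theta), Sigma)``.
The template ``T(theta)`` combines the direction's HRTF with the prior-mean
source spectrum; the covariance ``Sigma`` is the sum of a measurement-noise
term (input-independent by the jnd construction) and the source-spectrum
uncertainty propagated into feature space.  ``Sigma`` is independent of
``theta`` and of the input, so it is assembled and Cholesky-factored once
per decoder; likelihood evaluation over the grid never refactors.

Representations with a fixed nonlinearity are handled at decode time:
POS_SG rectifies both the observation and the templates (the Gaussian
covariance is kept as an approximation); IPSI_SG conditions on the sign of
the measured ITD and evaluates a reduced Gaussian in which the
contralateral SG block is dropped (the ITD/ILD cross-terms are retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .features import FeatureMap, Representation, build_feature_map, source_injection_matrix
from .hrtf import HrtfSet, ItdJndMap, default_itd_jnd_map
from .prior import SourcePrior

__all__ = [
    "NoiseModel",
    "DecoderModel",
    "Posterior",
    "assemble_covariance",
    "build_templates",
    "log_likelihood",
    "posterior",
    "map_estimate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseModel:
    """Input-independent Gaussian measurement noise in jnd coordinates.

    ``sigma_itd_jnd`` is the ITD noise in jnd units (the jnd transform
    absorbs the ITD-dependence of discrimination thresholds, so 1.0 means
    "one just-noticeable difference").  ``sigma_channel_db`` is the
    per-channel spectral noise per ear, a scalar or a length-N vector.
    """

    sigma_itd_jnd: float = 1.0
    sigma_channel_db: float | np.ndarray = 1.0

    def raw_variances(self, n_channels: int) -> np.ndarray:
        """Diagonal of the noise covariance on the stacked [itd, X_l, X_r]."""
        s_itd = float(self.sigma_itd_jnd)
        s_ch = np.broadcast_to(np.asarray(self.sigma_channel_db, float), (n_channels,))
        if s_itd <= 0 or np.any(s_ch <= 0):
            raise ValueError("noise sigmas must be positive")
        return np.concatenate([[s_itd**2], s_ch**2, s_ch**2])


def assemble_covariance(
    noise: NoiseModel, source: Optional[SourcePrior], fmap: FeatureMap
) -> np.ndarray:
    """Total feature covariance ``A Sigma_noise A^T + J Sigma_S J^T``.

    ``A`` is the representation's linear map on the stacked raw vector and
    ``J`` injects a source spectrum common to both ears.  For ISD (and the
    ILD coordinate of the SG representations) the source term vanishes
    identically.  ``source=None`` gives the pure measurement-noise
    covariance.
    """
    a = fmap.matrix
    sigma = (a * noise.raw_variances(fmap.n_channels)) @ a.T
    if source is not None:
        if source.representation != "LOGMAG":
            raise ValueError("source prior must be in LOGMAG representation")
        if source.mean.size != fmap.n_channels:
            raise ValueError("source prior dimension does not match filterbank")
        j = source_injection_matrix(fmap)
        sigma = sigma + j @ source.cov @ j.T
    sigma = (sigma + sigma.T) / 2.0
    if np.linalg.eigvalsh(sigma).min() <= -1e-10 * np.trace(sigma):
        raise ValueError("assembled covariance is not positive semidefinite")
    return sigma


def build_templates(
    hrtf: HrtfSet,
    source: Optional[SourcePrior],
    fmap: FeatureMap,
    itd_map: Optional[ItdJndMap] = None,
) -> np.ndarray:
    """Per-direction templates ``T(theta)``, shape (n_dir, n_features).

    Each ear's template spectrum is the HRTF log-magnitude plus the
    prior-mean source spectrum (log domain); the ITD coordinate is the
    direction's ITD in jnd units.  Templates are the *linear* feature-map
    output; POS_SG rectification is applied at likelihood evaluation.
    """
    n = hrtf.filterbank.n_channels
    if fmap.n_channels != n:
        raise ValueError("feature map and HRTF set use different filterbanks")
    mean_s = np.zeros(n)
    if source is not None:
        if source.representation != "LOGMAG":
            raise ValueError("source prior must be in LOGMAG representation")
        if source.mean.size != n:
            raise ValueError("source prior dimension does not match filterbank")
        mean_s = source.mean
    itd_map = itd_map or default_itd_jnd_map()
    raw = np.column_stack(
        [itd_map(hrtf.itd_us), hrtf.logmag_left + mean_s, hrtf.logmag_right + mean_s]
    )
    return raw @ fmap.matrix.T


@dataclass
class Posterior:
    """Normalized posterior over the decoder's direction grid."""

    probabilities: np.ndarray
    grid: "object"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("posterior must be nonnegative and sum to 1")
        self.probabilities = p


@dataclass
class _SubModel:
    """Reduced Gaussian for one ipsilateral side (feature indices kept)."""

    idx: np.ndarray
    templates: np.ndarray
    cho: tuple
    logdet: float


class DecoderModel:
    """An ideal-observer decoder for one (HRTF, prior, noise, representation).

    Build once with :meth:`build`; then :meth:`log_likelihood`,
    :meth:`posterior` and :meth:`decode` evaluate inputs against the cached
    templates and Cholesky factorization.
    """

    def __init__(
        self,
        fmap: FeatureMap,
        grid,
        templates: np.ndarray,
        total_cov: np.ndarray,
        measurement_cov: np.ndarray,
        itd_map: ItdJndMap,
    ):
        self.fmap = fmap
        self.representation = fmap.representation
        self.grid = grid
        self.templates = templates
        self.total_cov = total_cov
        self.measurement_cov = measurement_cov
        self.itd_map = itd_map
        self._cho = None
        self._logdet = 0.0
        self._meas_chol = cholesky(self._jittered(measurement_cov), lower=True)
        self._sub: dict[str, _SubModel] = {}
        self._templates_rect = None

        if self.representation is Representation.IPSI_SG:
            n1 = fmap.n_channels - 1
            for side, block in (("left", fmap.left_sg_slice), ("right", fmap.right_sg_slice)):
                idx = np.r_[0:2, block.start : block.stop]
                sub_cov = self._jittered(total_cov[np.ix_(idx, idx)])
                c = cho_factor(sub_cov, lower=True)
                self._sub[side] = _SubModel(
                    idx=idx,
                    templates=templates[:, idx],
                    cho=c,
                    logdet=2.0 * np.sum(np.log(np.diag(c[0]))),
                )
        else:
            cov = self._jittered(total_cov)
            self._cho = cho_factor(cov, lower=True)
            self._logdet = 2.0 * np.sum(np.log(np.diag(self._cho[0])))
            if self.representation is Representation.POS_SG:
                t = np.array(templates, copy=True)
                t[:, fmap.sg_slice] = np.maximum(0.0, t[:, fmap.sg_slice])
                self._templates_rect = t

    @staticmethod
    def _jittered(cov: np.ndarray) -> np.ndarray:
        """Add a tiny diagonal jitter if the matrix is not factorizable."""
        try:
            cholesky(cov, lower=True)
            return cov
        except np.linalg.LinAlgError:
            eps = 1e-10 * np.trace(cov)
            log.info("adding diagonal jitter %.3g to covariance", eps)
            return cov + eps * np.eye(cov.shape[0])

    @classmethod
    def build(
        cls,
        hrtf: HrtfSet,
        source: Optional[SourcePrior],
        noise: NoiseModel,
        representation: Representation | str,
        itd_map: Optional[ItdJndMap] = None,
    ) -> "DecoderModel":
        fmap = build_feature_map(representation, hrtf.filterbank)
        itd_map = itd_map or default_itd_jnd_map()
        total = assemble_covariance(noise, source, fmap)
        meas = assemble_covariance(noise, None, fmap)
        templates = build_templates(hrtf, source, fmap, itd_map)
        return cls(fmap, hrtf.grid, templates, total, meas, itd_map)

    # -- likelihood ---------------------------------------------------------

    def log_likelihood(self, x: np.ndarray) -> np.ndarray:
        """Per-direction Gaussian log-density of feature vector ``x``."""
        x = np.asarray(x, float)
        rep = self.representation
        if rep is Representation.IPSI_SG:
            sub = self._sub["left" if x[0] >= 0 else "right"]
            diff = sub.templates - x[sub.idx]
            solved = cho_solve(sub.cho, diff.T)
            quad = np.einsum("ij,ji->i", diff, solved)
            k = sub.idx.size
            return -0.5 * (quad + sub.logdet + k * np.log(2 * np.pi))
        if x.shape != (self.fmap.n_features,):
            raise ValueError(
                f"feature vector has shape {x.shape}, expected ({self.fmap.n_features},)"
            )
        if rep is Representation.POS_SG:
            x = np.array(x, copy=True)
            x[self.fmap.sg_slice] = np.maximum(0.0, x[self.fmap.sg_slice])
            diff = self._templates_rect - x
        else:
            diff = self.templates - x
        solved = cho_solve(self._cho, diff.T)
        quad = np.einsum("ij,ji->i", diff, solved)
        k = self.fmap.n_features
        return -0.5 * (quad + self._logdet + k * np.log(2 * np.pi))

    def posterior(self, x: np.ndarray, spatial_prior: Optional[np.ndarray] = None) -> Posterior:
        return posterior(self.log_likelihood(x), spatial_prior, grid=self.grid)

    def decode(self, x: np.ndarray, spatial_prior: Optional[np.ndarray] = None) -> int:
        """MAP direction index for feature vector ``x``."""
        return map_estimate(self.posterior(x, spatial_prior))

    def _batch_cache(self, key: str, templates: np.ndarray, cho) -> tuple:
        """Precompute W = Sigma^-1, T W and T W T^T for batched decoding."""
        if not hasattr(self, "_bcache"):
            self._bcache = {}
        if key not in self._bcache:
            w = cho_solve(cho, np.eye(templates.shape[1]))
            tw = templates @ w
            twt = np.einsum("ij,ij->i", templates, tw)
            self._bcache[key] = (tw, twt)
        return self._bcache[key]

    def decode_batch(self, x: np.ndarray) -> np.ndarray:
        """MAP direction indices for a batch of feature vectors (rows).

        Uses the expansion of the Mahalanobis distance
        ``(x-T) Sigma^-1 (x-T)^T = x W x - 2 x W T + T W T`` so the whole
        batch reduces to one matrix product against the cached templates.
        """
        x = np.atleast_2d(np.asarray(x, float))
        rep = self.representation
        out = np.empty(x.shape[0], dtype=int)
        if rep is Representation.IPSI_SG:
            for side, pick in (("left", x[:, 0] >= 0), ("right", x[:, 0] < 0)):
                if not np.any(pick):
                    continue
                sub = self._sub[side]
                tw, twt = self._batch_cache(side, sub.templates, sub.cho)
                score = twt[None, :] - 2.0 * (x[pick][:, sub.idx] @ tw.T)
                out[pick] = np.argmin(score, axis=1)
            return out
        if rep is Representation.POS_SG:
            x = np.array(x, copy=True)
            x[:, self.fmap.sg_slice] = np.maximum(0.0, x[:, self.fmap.sg_slice])
            templates = self._templates_rect
        else:
            templates = self.templates
        tw, twt = self._batch_cache("main", templates, self._cho)
        score = twt[None, :] - 2.0 * (x @ tw.T)
        return np.argmin(score, axis=1)

    # -- noise sampling (trial simulation) ----------------------------------

    def sample_measurement_noise(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw feature-space noise from the measurement part of Sigma only."""
        z = rng.standard_normal((size, self.measurement_cov.shape[0]))
        out = z @ self._meas_chol.T
        return out[0] if size == 1 else out


def log_likelihood(x: np.ndarray, model: DecoderModel) -> np.ndarray:
    """Functional wrapper around :meth:`DecoderModel.log_likelihood`."""
    return model.log_likelihood(x)


def posterior(
    loglik: np.ndarray,
    spatial_prior: Optional[np.ndarray] = None,
    grid=None,
) -> Posterior:
    """Normalize per-direction log-likelihoods into a posterior.

    Uniform spatial prior by default; log-sum-exp stabilized.
    """
    ll = np.asarray(loglik, float)
    if np.all(np.isneginf(ll)):
        raise ValueError("all log-likelihoods are -inf")
    if spatial_prior is not None:
        w = np.asarray(spatial_prior, float)
        if np.any(w < 0):
            raise ValueError("spatial prior weights must be nonnegative")
        with np.errstate(divide="ignore"):
            ll = ll + np.log(w / w.sum())
    m = np.max(ll)
    p = np.exp(ll - m)
    p /= p.sum()
    return Posterior(p, grid)


def map_estimate(p: Posterior) -> int:
    """Index of the posterior mode; ties broken toward the lowest index."""
    return int(np.argmax(p.probabilities))
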