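"""HRTF data model: direction grids, SOFA I/O, synthetic HRTFs, resampling.

Coordinate convention (interaural-polar)
----------------------------------------
Right-handed head frame: +x front, +y toward the left ear, +z up.

* ``lateral`` — angle from the midsagittal plane, ``asin(y)`` in
  [-90, 90] degrees, positive toward the left ear.  All directions with the
  same lateral angle share a cone of confusion (same ITD).
* ``polar`` — position on that cone, in [-90, 270) degrees:
  0 = front horizontal, 90 = above, 180 = rear horizontal, -90/270 = below.
* ``elevation`` — ``asin(z)`` in [-90, 90] degrees.

An :class:`HrtfSet` stores, per direction, the left/right-ear directional
transfer functions as ERB-channel log-magnitudes (dB, free-field referenced)
plus a scalar interaural time difference in microseconds (positive = left
ear leads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import h5py
from scipy.special import sph_harm_y

from .erb import ErbFilterbank, erb_number, frame_logmag, make_filterbank

__all__ = [
    "DirectionGrid",
    "HrtfSet",
    "SynthHrtfParams",
    "interaural_polar",
    "interaural_polar_to_vector",
    "uniform_sphere_grid",
    "filter_grid",
    "region_mask",
    "synth_hrtf",
    "load_sofa",
    "write_sofa",
    "sh_resample",
    "ItdJndMap",
    "default_itd_jnd_map",
    "itd_to_jnd",
]

log = logging.getLogger(__name__)

SPEED_OF_SOUND_M_S = 343.0


# ---------------------------------------------------------------------------
# coordinates


def interaural_polar(unit_vector: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert unit vector(s) to (lateral_deg, polar_deg).

    Accepts shape (3,) or (n, 3).  Raises on (near-)zero vectors.
    """
    v = np.atleast_2d(np.asarray(unit_vector, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero vector has no direction")
    v = v / norms[:, None]
    lateral = np.degrees(np.arcsin(np.clip(v[:, 1], -1.0, 1.0)))
    # polar is undefined on the interaural axis; atan2(0,0)=0 is a harmless pick
    polar = np.degrees(np.arctan2(v[:, 2], v[:, 0]))
    polar = np.where(polar < -90.0, polar + 360.0, polar)  # wrap to [-90, 270)
    if np.ndim(unit_vector) == 1:
        return float(lateral[0]), float(polar[0])
    return lateral, polar


def interaural_polar_to_vector(
    lateral_deg: np.ndarray | float, polar_deg: np.ndarray | float
) -> np.ndarray:
    """Inverse of :func:`interaural_polar`; returns unit vector(s)."""
    lat = np.radians(np.asarray(lateral_deg, dtype=float))
    pol = np.radians(np.asarray(polar_deg, dtype=float))
    r = np.cos(lat)
    v = np.stack([r * np.cos(pol), np.sin(lat), r * np.sin(pol)], axis=-1)
    return v


@dataclass(frozen=True)
class DirectionGrid:
    """A set of distinct directions on the unit sphere."""

    unit_vectors: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.unit_vectors, dtype=float))
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("direction vectors must have unit norm")
        # duplicate directions would make the decoder's argmax ambiguous
        key = np.round(v, 9)
        if np.unique(key, axis=0).shape[0] != v.shape[0]:
            raise ValueError("grid contains duplicate directions")
        object.__setattr__(self, "unit_vectors", v)

    def __len__(self) -> int:
        return self.unit_vectors.shape[0]

    @property
    def lateral_deg(self) -> np.ndarray:
        lat, _ = interaural_polar(self.unit_vectors)
        return lat

    @property
    def polar_deg(self) -> np.ndarray:
        _, pol = interaural_polar(self.unit_vectors)
        return pol

    @property
    def elevation_deg(self) -> np.ndarray:
        return np.degrees(np.arcsin(np.clip(self.unit_vectors[:, 2], -1, 1)))

    @classmethod
    def from_angles(cls, lateral_deg, polar_deg) -> "DirectionGrid":
        return cls(interaural_polar_to_vector(lateral_deg, polar_deg))

    def subset(self, mask_or_index) -> "DirectionGrid":
        return DirectionGrid(self.unit_vectors[mask_or_index])


def uniform_sphere_grid(
    n: int, method: str = "fibonacci", seed: Optional[int] = None
) -> DirectionGrid:
    """``n`` directions distributed approximately uniformly over the sphere.

    ``method='fibonacci'`` (default) is a deterministic low-discrepancy
    lattice; ``method='random'`` draws i.i.d. uniform directions (seeded).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if method == "fibonacci":
        i = np.arange(n)
        z = 1.0 - (2.0 * i + 1.0) / n
        golden = np.pi * (3.0 - np.sqrt(5.0))
        az = golden * i
        r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
        v = np.stack([r * np.cos(az), r * np.sin(az), z], axis=1)
    elif method == "random":
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DirectionGrid(v)


def filter_grid(grid: DirectionGrid, min_elevation_deg: float) -> DirectionGrid:
    """Retain directions with elevation >= ``min_elevation_deg`` (order kept)."""
    mask = grid.elevation_deg >= min_elevation_deg
    if not np.any(mask):
        raise ValueError("elevation filter leaves no directions")
    return grid.subset(mask)


def region_mask(
    grid: DirectionGrid,
    max_lateral_deg: float = 30.0,
    max_band_deg: float = 60.0,
    *,
    mode: str = "polar",
) -> np.ndarray:
    """Mask of directions near the midsagittal plane and the horizontal plane.

    True where |lateral| <= ``max_lateral_deg`` and the direction lies within
    ``max_band_deg`` of the horizontal plane, in the front or rear hemifield.
    ``mode='polar'`` (default) expresses the band as polar angle in
    [-band, band] or [180-band, 180+band]; ``mode='elevation'`` uses
    |elevation| <= band instead.
    """
    lat = grid.lateral_deg
    ok_lat = np.abs(lat) <= max_lateral_deg
    if mode == "polar":
        pol = grid.polar_deg
        ok_band = (np.abs(pol) <= max_band_deg) | (np.abs(pol - 180.0) <= max_band_deg)
    elif mode == "elevation":
        ok_band = np.abs(grid.elevation_deg) <= max_band_deg
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ok_lat & ok_band


# ---------------------------------------------------------------------------
# HRTF container


@dataclass
class HrtfSet:
    """Per-direction directional transfer (dB) and ITD (µs) for one subject."""

    grid: DirectionGrid
    filterbank: ErbFilterbank
    logmag_left: np.ndarray  # (n_dir, n_channels) dB
    logmag_right: np.ndarray
    itd_us: np.ndarray  # (n_dir,) positive = left ear leads
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        n, c = len(self.grid), self.filterbank.n_channels
        self.logmag_left = np.asarray(self.logmag_left, float)
        self.logmag_right = np.asarray(self.logmag_right, float)
        self.itd_us = np.asarray(self.itd_us, float)
        for name, arr, shape in [
            ("logmag_left", self.logmag_left, (n, c)),
            ("logmag_right", self.logmag_right, (n, c)),
            ("itd_us", self.itd_us, (n,)),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


# ---------------------------------------------------------------------------
# synthetic HRTFs


@dataclass(frozen=True)
class SynthHrtfParams:
    """Parameters of the parametric HRTF generator.

    The generator emulates the gross structure of measured HRTFs: a
    spherical-head (Woodworth) ITD in the lateral angle, a head-shadow ILD
    growing with |lateral| and frequency, and a pinna-like spectral notch
    whose centre frequency moves monotonically with the polar angle so that
    every grid direction has a distinct template.  A lateral-dependent
    notch-depth asymmetry between the ears gives the interaural spectral
    difference a weak polar cue, as ear asymmetries do in real heads.
    """

    head_radius_m: float = 0.0875
    ild_max_db: float = 20.0
    notch_depth_db: float = 15.0
    notch_width_erb: float = 0.8
    notch_f_lo_hz: float = 4000.0
    notch_f_hi_hz: float = 11000.0
    notch_asymmetry: float = 0.35
    #: per-subject jitter scales (head radius fraction, notch centre ERB)
    jitter_radius: float = 0.05
    jitter_notch_erb: float = 0.5


def woodworth_itd_us(lateral_deg: np.ndarray, head_radius_m: float) -> np.ndarray:
    """Spherical-head ITD: (a/c)(sin|θ| + |θ|), signed by the lateral angle."""
    th = np.radians(np.asarray(lateral_deg, float))
    return 1e6 * head_radius_m / SPEED_OF_SOUND_M_S * (np.sin(th) + th)


def synth_hrtf(
    grid: DirectionGrid,
    params: SynthHrtfParams = SynthHrtfParams(),
    seed: Optional[int] = None,
    fb: Optional[ErbFilterbank] = None,
    subject_id: Optional[str] = None,
) -> HrtfSet:
    """Generate a parametric HRTF set on ``grid`` (deterministic given seed).

    With a seed, small per-subject perturbations of head radius and notch
    mapping are drawn, emulating inter-subject variability.
    """
    if params.head_radius_m <= 0:
        raise ValueError("head radius must be positive")
    if fb is None:
        fb = make_filterbank(300.0, 12000.0, 1.0)
    rng = np.random.default_rng(seed)
    if seed is None:
        radius, notch_off = params.head_radius_m, 0.0
    else:
        radius = params.head_radius_m * (1.0 + params.jitter_radius * rng.uniform(-1, 1))
        notch_off = params.jitter_notch_erb * rng.uniform(-1, 1)

    lat = grid.lateral_deg
    pol = grid.polar_deg
    e = erb_number(fb.centre_frequencies_hz)  # (C,)
    e_lo, e_hi = erb_number(params.notch_f_lo_hz), erb_number(params.notch_f_hi_hz)

    itd = woodworth_itd_us(lat, radius)
    # exact midline symmetry: lateral 0 -> itd exactly 0
    itd[np.abs(lat) < 1e-12] = 0.0

    # head-shadow ILD, increasing with frequency (normalized ERB index)
    w_freq = (e - e[0]) / (e[-1] - e[0])  # 0..1
    sinlat = np.sin(np.radians(lat))
    ild = params.ild_max_db * sinlat[:, None] * w_freq[None, :]  # (n, C)

    # pinna notch: centre moves monotonically with polar angle
    e_notch = e_lo + (pol + 90.0) / 360.0 * (e_hi - e_lo) + notch_off  # (n,)
    shape = np.exp(-0.5 * ((e[None, :] - e_notch[:, None]) / params.notch_width_erb) ** 2)
    depth_l = params.notch_depth_db * (1.0 + params.notch_asymmetry * sinlat)
    depth_r = params.notch_depth_db * (1.0 - params.notch_asymmetry * sinlat)

    logmag_l = +0.5 * ild - depth_l[:, None] * shape
    logmag_r = -0.5 * ild - depth_r[:, None] * shape
    return HrtfSet(
        grid=grid,
        filterbank=fb,
        logmag_left=logmag_l,
        logmag_right=logmag_r,
        itd_us=itd,
        subject_id=subject_id or (f"synth-{seed}" if seed is not None else "synth"),
    )


# ---------------------------------------------------------------------------
# SOFA I/O (SimpleFreeFieldHRIR; netCDF-4 files are HDF5 containers)


def _sofa_positions_to_vectors(pos: np.ndarray, pos_type: str) -> np.ndarray:
    if pos_type.lower().startswith("spherical"):
        az = np.radians(pos[:, 0])  # CCW from front; +90 deg = left
        el = np.radians(pos[:, 1])
        v = np.stack(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=1
        )
    elif pos_type.lower().startswith("cartesian"):
        v = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    else:
        raise ValueError(f"unsupported SourcePosition type {pos_type!r}")
    return v


def _onset_sample(ir: np.ndarray, frac: float = 0.1) -> float:
    """First crossing of ``frac``·max|ir|, with linear sub-sample interpolation."""
    a = np.abs(ir)
    thr = frac * a.max()
    idx = int(np.argmax(a >= thr))
    if idx == 0 or a[idx] == a[idx - 1]:
        return float(idx)
    return idx - 1 + (thr - a[idx - 1]) / (a[idx] - a[idx - 1])


def _attr_str(obj, name: str, default: str = "") -> str:
    val = obj.attrs.get(name, default)
    if isinstance(val, bytes):
        val = val.decode()
    return str(val)


def load_sofa(
    path, fb: Optional[ErbFilterbank] = None, *, itd_method: str = "onset"
) -> HrtfSet:
    """Read a SimpleFreeFieldHRIR SOFA file into an :class:`HrtfSet`.

    Impulse responses are reduced to ERB-channel log-magnitudes with
    :func:`hearloc.erb.frame_logmag` (rectangular window: HRIRs are short
    deterministic filters).  The ITD comes from ``Data.Delay`` when it
    carries distinct per-ear delays; otherwise it is estimated from the IRs
    (``itd_method='onset'``: 10%-of-peak threshold crossing per ear;
    ``'xcorr'``: cross-correlation peak).
    """
    if fb is None:
        fb = make_filterbank(300.0, 12000.0, 1.0)
    with h5py.File(path, "r") as f:
        conv = _attr_str(f, "SOFAConventions", "")
        if conv and conv != "SimpleFreeFieldHRIR":
            raise ValueError(f"unsupported SOFA convention {conv!r}")
        for req in ("Data.IR", "Data.SamplingRate", "SourcePosition"):
            if req not in f:
                raise ValueError(f"SOFA file missing required variable {req!r}")
        ir = np.asarray(f["Data.IR"])  # (M, R, N)
        fs = float(np.ravel(f["Data.SamplingRate"])[0])
        pos = np.asarray(f["SourcePosition"])
        pos_type = _attr_str(f["SourcePosition"], "Type", "spherical")
        delay = np.asarray(f["Data.Delay"]) if "Data.Delay" in f else None
        recv = np.asarray(f["ReceiverPosition"]) if "ReceiverPosition" in f else None
        subject = _attr_str(f, "ListenerShortName", "") or _attr_str(f, "Title", "sofa")

    if ir.ndim != 3 or ir.shape[1] != 2:
        raise ValueError(f"Data.IR must have shape (M, 2, N), got {ir.shape}")
    m = ir.shape[0]

    # identify ears: receiver with y > 0 is the left ear; default order (L, R)
    left_idx, right_idx = 0, 1
    if recv is not None:
        recv = recv.reshape(-1, recv.shape[-1])
        if recv.shape[0] == 2 and recv[0, 1] < recv[1, 1]:
            left_idx, right_idx = 1, 0

    grid = DirectionGrid(_sofa_positions_to_vectors(pos, pos_type))

    lm = np.empty((2, m, fb.n_channels))
    for r_out, r_in in enumerate((left_idx, right_idx)):
        for i in range(m):
            lm[r_out, i] = frame_logmag(ir[i, r_in], fs, fb, window="boxcar").values_db

    if delay is not None and np.ptp(delay) > 0:
        d = np.broadcast_to(np.asarray(delay, float).reshape(-1, 2), (m, 2))
        itd_us = (d[:, right_idx] - d[:, left_idx]) / fs * 1e6
    else:
        itd_us = np.empty(m)
        for i in range(m):
            if itd_method == "onset":
                on_l = _onset_sample(ir[i, left_idx])
                on_r = _onset_sample(ir[i, right_idx])
                itd_us[i] = (on_r - on_l) / fs * 1e6
            elif itd_method == "xcorr":
                xc = np.correlate(ir[i, left_idx], ir[i, right_idx], mode="full")
                lag = int(np.argmax(xc)) - (ir.shape[2] - 1)
                itd_us[i] = lag / fs * 1e6
            else:
                raise ValueError(f"unknown itd_method {itd_method!r}")

    return HrtfSet(grid, fb, lm[0], lm[1], itd_us, subject_id=subject)


def write_sofa(hrtf: HrtfSet, path, *, fs: float = 48000.0, n_ir: int = 2048) -> None:
    """Write an :class:`HrtfSet` as a minimal SimpleFreeFieldHRIR SOFA file.

    Each IR is synthesized with a piecewise-constant power spectrum matching
    the channel levels exactly (zero phase); the interaural delay is stored
    in ``Data.Delay``, so :func:`load_sofa` round-trips the set.
    """
    fb = hrtf.filterbank
    n_dir = len(hrtf.grid)
    freqs = np.fft.rfftfreq(n_ir, d=1.0 / fs)
    lo, hi = fb.band_edges_hz()
    # invert the boxcar frame_logmag pipeline: per-band flat |S| giving the
    # exact band power
    band_bins = [np.flatnonzero((freqs >= lo[c]) & (freqs < hi[c])) for c in range(fb.n_channels)]
    ir = np.zeros((n_dir, 2, n_ir))
    for i in range(n_dir):
        for r, lm in enumerate((hrtf.logmag_left[i], hrtf.logmag_right[i])):
            spec = np.full(freqs.size, 1e-12)
            for c, bins in enumerate(band_bins):
                if bins.size == 0:
                    continue
                power = 10.0 ** (lm[c] / 10.0)
                spec[bins] = np.sqrt(power * n_ir**2 / (2.0 * bins.size))
            ir[i, r] = np.fft.irfft(spec, n=n_ir)

    t0 = n_ir / 4.0  # common bulk delay, samples
    delay = np.empty((n_dir, 2))
    delay[:, 0] = t0 - hrtf.itd_us * 1e-6 * fs / 2.0  # left: leads when itd > 0
    delay[:, 1] = t0 + hrtf.itd_us * 1e-6 * fs / 2.0

    with h5py.File(path, "w") as f:
        f.attrs["Conventions"] = "SOFA"
        f.attrs["SOFAConventions"] = "SimpleFreeFieldHRIR"
        f.attrs["SOFAConventionsVersion"] = "1.0"
        f.attrs["DataType"] = "FIR"
        f.attrs["ListenerShortName"] = hrtf.subject_id
        f.create_dataset("Data.IR", data=ir)
        f.create_dataset("Data.SamplingRate", data=np.array([fs]))
        f.create_dataset("Data.Delay", data=delay)
        lat, pol = interaural_polar(hrtf.grid.unit_vectors)
        az = np.degrees(
            np.arctan2(hrtf.grid.unit_vectors[:, 1], hrtf.grid.unit_vectors[:, 0])
        )
        el = hrtf.grid.elevation_deg
        sp = f.create_dataset(
            "SourcePosition", data=np.stack([az, el, np.ones(n_dir)], axis=1)
        )
        sp.attrs["Type"] = "spherical"
        sp.attrs["Units"] = "degree, degree, metre"
        f.create_dataset(
            "ReceiverPosition", data=np.array([[0.0, 0.09, 0.0], [0.0, -0.09, 0.0]])
        )


# ---------------------------------------------------------------------------
# spherical-harmonics resampling


def _real_sh_matrix(order: int, vectors: np.ndarray) -> np.ndarray:
    """Real spherical-harmonics design matrix, shape (n_dir, (order+1)^2)."""
    v = np.atleast_2d(vectors)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))  # colatitude
    phi = np.arctan2(v[:, 1], v[:, 0])
    cols = []
    for n in range(order + 1):
        y = sph_harm_y(n, np.arange(0, n + 1)[:, None], theta[None, :], phi[None, :])
        # m = -n..-1 (imag parts), m = 0, m = 1..n (real parts)
        for m in range(n, 0, -1):
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y[m].imag)
        cols.append(y[0].real)
        for m in range(1, n + 1):
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y[m].real)
    return np.stack(cols, axis=1)


def sh_resample(
    hrtf: HrtfSet,
    target: DirectionGrid,
    order: int = 15,
    tikhonov_lambda: float = 1e-4,
) -> HrtfSet:
    """Resample an HRTF set onto ``target`` via regularized SH least squares.

    Per ERB channel (and for the ITD), fits real spherical harmonics up to
    ``order`` by minimizing ``|Y c - d|^2 + lambda |c|^2`` and evaluates the
    fit on the target grid.
    """
    n_coef = (order + 1) ** 2
    if len(hrtf.grid) < n_coef:
        log.info(
            "SH order %d has %d coefficients for %d directions; fit is "
            "under-determined (regularization or min-norm applies)",
            order, n_coef, len(hrtf.grid),
        )
    y_src = _real_sh_matrix(order, hrtf.grid.unit_vectors)
    y_tgt = _real_sh_matrix(order, target.unit_vectors)
    data = np.column_stack([hrtf.logmag_left, hrtf.logmag_right, hrtf.itd_us])
    if tikhonov_lambda > 0:
        gram = y_src.T @ y_src + tikhonov_lambda * np.eye(n_coef)
        coef = np.linalg.solve(gram, y_src.T @ data)
    else:
        rank = np.linalg.matrix_rank(y_src)
        if rank < min(y_src.shape):
            raise np.linalg.LinAlgError(
                "rank-deficient spherical-harmonics fit with lambda=0; "
                "use tikhonov_lambda > 0"
            )
        coef, *_ = np.linalg.lstsq(y_src, data, rcond=None)
    fit = y_tgt @ coef
    c = hrtf.filterbank.n_channels
    return HrtfSet(
        grid=target,
        filterbank=hrtf.filterbank,
        logmag_left=fit[:, :c],
        logmag_right=fit[:, c : 2 * c],
        itd_us=fit[:, -1],
        subject_id=hrtf.subject_id,
    )


# ---------------------------------------------------------------------------
# ITD -> jnd transform


class ItdJndMap:
    """Monotone odd map from ITD (µs) to just-noticeable-difference units.

    In jnd coordinates the ITD measurement noise has unit variance by
    construction.  The map is defined by a tabulated (itd_us, jnd) curve for
    itd >= 0, extended oddly and extrapolated linearly with the last
    segment's slope.  Any tabulated curve (e.g. one derived from
    psychoacoustic discrimination data) can be supplied.
    """

    def __init__(self, itd_knots_us: np.ndarray, jnd_knots: np.ndarray):
        itd_knots_us = np.asarray(itd_knots_us, float)
        jnd_knots = np.asarray(jnd_knots, float)
        if itd_knots_us[0] != 0 or jnd_knots[0] != 0:
            raise ValueError("curve must start at (0, 0)")
        if np.any(np.diff(itd_knots_us) <= 0) or np.any(np.diff(jnd_knots) <= 0):
            raise ValueError("curve must be strictly increasing")
        self.itd_knots_us = itd_knots_us
        self.jnd_knots = jnd_knots
        self._end_slope = (jnd_knots[-1] - jnd_knots[-2]) / (
            itd_knots_us[-1] - itd_knots_us[-2]
        )

    def __call__(self, itd_us: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(itd_us, float)
        a = np.abs(x)
        out = np.interp(a, self.itd_knots_us, self.jnd_knots)
        over = a > self.itd_knots_us[-1]
        out = np.where(
            over, self.jnd_knots[-1] + (a - self.itd_knots_us[-1]) * self._end_slope, out
        )
        out = np.sign(x) * out
        return float(out) if out.ndim == 0 else out

    def inverse(self, jnd: np.ndarray | float) -> np.ndarray | float:
        y = np.asarray(jnd, float)
        a = np.abs(y)
        out = np.interp(a, self.jnd_knots, self.itd_knots_us)
        over = a > self.jnd_knots[-1]
        out = np.where(
            over, self.itd_knots_us[-1] + (a - self.jnd_knots[-1]) / self._end_slope, out
        )
        out = np.sign(y) * out
        return float(out) if out.ndim == 0 else out


def default_itd_jnd_map() -> ItdJndMap:
    """Default ITD-jnd curve: 1 jnd = 20 µs near zero, 60 µs beyond 600 µs.

    The local jnd width is 20 µs up to 100 µs, grows linearly to 60 µs at
    600 µs, and stays 60 µs beyond; jnd(itd) is the integral of the inverse
    width, tabulated on a fine knot grid.
    """
    itd = np.arange(0.0, 1201.0, 5.0)
    width = np.where(
        itd <= 100.0, 20.0, 20.0 + 40.0 * (np.minimum(itd, 600.0) - 100.0) / 500.0
    )
    inv = 1.0 / width
    jnd = np.concatenate([[0.0], np.cumsum((inv[1:] + inv[:-1]) / 2.0 * np.diff(itd))])
    return ItdJndMap(itd, jnd)


_DEFAULT_MAP = default_itd_jnd_map()


def itd_to_jnd(itd_us: np.ndarray | float, mapping: Optional[ItdJndMap] = None):
    """Transform ITD (µs) to jnd units using ``mapping`` (default curve if None)."""
    return (mapping or _DEFAULT_MAP)(itd_us)
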