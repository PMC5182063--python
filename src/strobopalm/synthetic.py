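"""Synthetic localization data with the statistical structure the analysis assumes.

Two generators are provided:

1. Strobed binding/bleaching time traces for residence-time inference.  A
   membrane protein binds a cell pole for an exponentially distributed dwell
   time ``tau_off`` and carries an exponentially distributed *illuminated-time*
   photobleaching budget ``tau_bleach`` that is consumed only while the camera
   shutter is open (the physical basis of the stroboscopic rescaling of the
   bleaching lifetime).  Photoactivation is frame-locked: the activation pulse
   is synchronized to the camera cycle, so a molecule's fluorescent life
   starts at an exposure onset.  Track formation is modelled as per-frame pole
   occupancy: a position-based tracker cannot distinguish two molecules whose
   detections abut in consecutive frames at the same pole, so their runs merge.
   This per-frame (not per-millisecond) concatenation probability is what
   produces the minimum-measurable-on-time plateau at long strobe intervals.

2. Point-source and extended localization clouds for cluster-morphology
   analysis, with Gaussian localization error drawn either from a fixed
   precision or from a Thompson-style photon/background model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .loc_data import AcquisitionSettings, LocalizationTable

__all__ = [
    "KineticParams",
    "ClusterSpec",
    "MoleculeEnsemble",
    "TrackLengthSample",
    "simulate_molecules",
    "simulate_track_lengths",
    "simulate_localization_stream",
    "simulate_cluster",
    "thompson_precision",
    "frames_for_density",
]

#: Fraction of an exposure window a molecule must be bound and unbleached
#: to be detected in that frame (symmetric default).
DEFAULT_DETECTION_FRACTION = 0.5

#: Effective pixel size (nm) entering the Thompson precision formula.
THOMPSON_PIXEL_NM = 100.0


@dataclass(frozen=True)
class KineticParams:
    """True binding/bleaching kinetics of the tagged protein.

    Attributes
    ----------
    tau_off_ms : float
        Binding (dwell) lifetime at the pole, ms.
    tau_bleach_ms : float
        Photobleaching lifetime under continuous illumination, ms.  The
        bleaching clock advances only while the camera shutter is open.
    activation_rate_per_frame : float
        Mean photoactivations per acquisition frame at one pole.  Constant
        per *frame* (the activation pulse is frame-synchronized), which makes
        the tracker's per-frame molecule-concatenation probability independent
        of the strobe interval.
    """

    tau_off_ms: float
    tau_bleach_ms: float
    activation_rate_per_frame: float = 0.08

    def __post_init__(self) -> None:
        if not (self.tau_off_ms > 0 and self.tau_bleach_ms > 0):
            raise ValueError("tau_off_ms and tau_bleach_ms must be > 0")
        if self.activation_rate_per_frame < 0:
            raise ValueError("activation_rate_per_frame must be >= 0")


def frames_for_density(n_molecules: int, rate_per_frame: float) -> int:
    """Number of frames over which ``n_molecules`` activations give the target density."""
    return max(1, int(round(n_molecules / rate_per_frame)))


@dataclass
class MoleculeEnsemble:
    """Per-molecule ground truth and observation geometry of one simulation."""

    dwell_ms: np.ndarray          # true binding duration d ~ Exp(tau_off)
    bleach_budget_ms: np.ndarray  # illuminated-time budget B ~ Exp(tau_bleach)
    bleach_wall_ms: np.ndarray    # wall-clock time to bleach under the strobe
    visible_ms: np.ndarray        # wall-clock visible duration min(dwell, bleach)
    activation_frame: np.ndarray  # frame index of activation (exposure onset)
    n_detected_frames: np.ndarray # frames with >= detection-fraction coverage
    first_frame: np.ndarray       # first detected frame (undetected: -1)
    last_frame: np.ndarray        # last detected frame, clipped to acquisition

    @property
    def detected(self) -> np.ndarray:
        return self.n_detected_frames > 0


@dataclass
class TrackLengthSample:
    """Observed track lengths (frames) from one simulated strobe condition."""

    lengths: np.ndarray
    n_undetected: int
    n_molecules: int

    def histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.lengths, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def simulate_molecules(
    kin: KineticParams,
    acq: AcquisitionSettings,
    n_molecules: int,
    seed: int | np.random.Generator,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
    activation_frames: np.ndarray | None = None,
) -> MoleculeEnsemble:
    """Draw the per-molecule kinetic/observation variables in closed form.

    With activation at an exposure onset, the wall-clock time to photobleach
    is ``floor(B/tau_int)*tau_tl + (B mod tau_int)`` (budget B is spent in
    tau_int-sized slices, one per frame period), and the number of frames in
    which the molecule is bound and unbleached for at least the detection
    fraction f of the exposure is ``floor((V - f*tau_int)/tau_tl) + 1`` for
    visible wall-duration ``V`` (0 if ``V < f*tau_int``).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    ti, tl = acq.tau_int_ms, acq.tau_tl_ms

    dwell = rng.exponential(kin.tau_off_ms, n_molecules)
    budget = rng.exponential(kin.tau_bleach_ms, n_molecules)
    if activation_frames is None:
        u = rng.integers(0, acq.n_frames, n_molecules)
    else:
        u = np.asarray(activation_frames, dtype=np.int64)
        if u.shape != (n_molecules,):
            raise ValueError("activation_frames must have one entry per molecule")

    bleach_wall = np.floor(budget / ti) * tl + np.mod(budget, ti)
    visible = np.minimum(dwell, bleach_wall)

    n_det = np.floor((visible - detection_fraction * ti) / tl).astype(np.int64) + 1
    n_det = np.clip(n_det, 0, None)
    # truncate at the end of the acquisition
    n_det = np.minimum(n_det, acq.n_frames - u)
    first = np.where(n_det > 0, u, -1)
    last = np.where(n_det > 0, u + n_det - 1, -1)
    return MoleculeEnsemble(
        dwell_ms=dwell,
        bleach_budget_ms=budget,
        bleach_wall_ms=bleach_wall,
        visible_ms=visible,
        activation_frame=u,
        n_detected_frames=n_det,
        first_frame=first,
        last_frame=last,
    )


def _runs_from_intervals(first: np.ndarray, last: np.ndarray, n_frames: int) -> np.ndarray:
    """Lengths of maximal runs of occupied frames given detected [first, last] spans."""
    if first.size == 0:
        return np.zeros(0, dtype=np.int64)
    # merge overlapping/abutting intervals without materializing the frame axis
    order = np.argsort(first, kind="stable")
    f = first[order]
    l = last[order]
    run_end = np.maximum.accumulate(l)
    # a new run starts where the interval begins after the furthest end so far
    new_run = np.empty(f.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = f[1:] > run_end[:-1] + 1
    starts = f[new_run]
    idx = np.flatnonzero(new_run)
    ends = np.empty(idx.size, dtype=np.int64)
    ends[:-1] = run_end[idx[1:] - 1]
    ends[-1] = run_end[-1]
    return (ends - starts + 1).astype(np.int64)


def simulate_track_lengths(
    kin: KineticParams,
    acq: AcquisitionSettings,
    n_molecules: int,
    seed: int | np.random.Generator,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
    merge_coincident: bool = True,
) -> TrackLengthSample:
    """Simulate observed track lengths (frames) for one strobe condition.

    ``merge_coincident=True`` (default) models what a position-based tracker
    measures at a pole: maximal runs of consecutive occupied frames, merging
    molecules whose detections abut.  ``merge_coincident=False`` returns the
    strict per-molecule consecutive-frame counts instead (no tracker
    crosstalk), useful for isolating the single-molecule kinetics.
    Molecules never detected are excluded and counted in ``n_undetected``.
    """
    ens = simulate_molecules(kin, acq, n_molecules, seed, detection_fraction)
    det = ens.detected
    n_undetected = int(n_molecules - det.sum())
    if merge_coincident:
        lengths = _runs_from_intervals(
            ens.first_frame[det], ens.last_frame[det], acq.n_frames
        )
    else:
        lengths = ens.n_detected_frames[det].astype(np.int64)
    return TrackLengthSample(lengths=lengths, n_undetected=n_undetected, n_molecules=n_molecules)


def simulate_localization_stream(
    kin: KineticParams,
    acq: AcquisitionSettings,
    emitter_positions: Sequence[tuple[float, float]],
    sigma_nm: float,
    seed: int | np.random.Generator,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
    photons: float = 500.0,
    background: float = 5.0,
) -> LocalizationTable:
    """Spatialize the binding/bleaching simulation into a localization table.

    Each emitter position hosts a stream of photoactivated molecules
    (``Poisson(rate * n_frames)`` of them; exactly one molecule activated at
    frame 0 when the activation rate is 0, for deterministic single-emitter
    scenarios).  Every detected molecule-frame yields one localization at the
    emitter position plus isotropic Gaussian error of s.d. ``sigma_nm``.
    """
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be > 0")
    rng = np.random.default_rng(seed)
    frames: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for ex, ey in emitter_positions:
        if kin.activation_rate_per_frame > 0:
            n_mol = int(rng.poisson(kin.activation_rate_per_frame * acq.n_frames))
        else:
            n_mol = 1
        if n_mol == 0:
            continue
        starts = (
            np.zeros(1, dtype=np.int64) if kin.activation_rate_per_frame == 0 else None
        )
        ens = simulate_molecules(kin, acq, n_mol, rng, detection_fraction, starts)
        det = ens.detected
        n_per = ens.n_detected_frames[det]
        if n_per.sum() == 0:
            continue
        fr = np.concatenate(
            [np.arange(f, f + n) for f, n in zip(ens.first_frame[det], n_per)]
        )
        k = fr.size
        xs.append(ex + rng.normal(0.0, sigma_nm, k))
        ys.append(ey + rng.normal(0.0, sigma_nm, k))
        frames.append(fr)
    if not frames:
        return LocalizationTable()
    table = LocalizationTable.from_arrays(
        frame=np.concatenate(frames),
        x_nm=np.concatenate(xs),
        y_nm=np.concatenate(ys),
        photons=photons,
        background=background,
        sigma_nm=sigma_nm,
    )
    return table.sorted_by_frame()


# ---------------------------------------------------------------------------
# cluster clouds
# ---------------------------------------------------------------------------

def thompson_precision(
    photons: float,
    background: float,
    psf_sigma_nm: float,
    pixel_nm: float = THOMPSON_PIXEL_NM,
) -> float:
    """Thompson–Larson–Webb localization precision (1 s.d., nm).

    sigma^2 = s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)

    with PSF width ``s``, photon count ``N``, background s.d. per pixel ``b``
    and effective pixel size ``a`` (default 100 nm).
    """
    if photons <= 0:
        raise ValueError("photons must be > 0")
    s2 = psf_sigma_nm**2
    var = (
        s2 / photons
        + pixel_nm**2 / (12.0 * photons)
        + 8.0 * np.pi * s2**2 * background**2 / (pixel_nm**2 * photons**2)
    )
    return float(np.sqrt(var))


@dataclass(frozen=True)
class ClusterSpec:
    """Geometry and noise model of one simulated localization cloud.

    ``shape`` is one of ``point`` (zero spatial extent — the zero-area
    baseline construction), ``disk`` (uniform over a disk of ``radius_nm``)
    or ``annular-arc`` (uniform over the annular sector of centre radius
    ``radius_nm``, radial thickness ``width_nm`` and angular extent
    ``arc_start_deg``..``arc_end_deg``).  Localization error is isotropic
    Gaussian with s.d. ``sigma_nm``; when ``sigma_nm`` is None it is computed
    from (photons, background, psf_sigma_nm) via :func:`thompson_precision`.
    """

    shape: Literal["point", "disk", "annular-arc"]
    n_localizations: int
    radius_nm: float = 0.0
    width_nm: float = 50.0
    arc_start_deg: float = 0.0
    arc_end_deg: float = 360.0
    sigma_nm: float | None = 15.0
    photons: float = 500.0
    background: float = 5.0
    psf_sigma_nm: float = 130.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_localizations < 1:
            raise ValueError("n_localizations must be >= 1")
        if self.radius_nm < 0 or self.width_nm < 0:
            raise ValueError("size parameters must be >= 0")
        if self.shape == "point" and self.radius_nm != 0:
            raise ValueError("point shape has zero spatial extent")
        if self.shape not in ("point", "disk", "annular-arc"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def precision_nm(self) -> float:
        if self.sigma_nm is not None:
            if self.sigma_nm <= 0:
                raise ValueError("sigma_nm must be > 0")
            return float(self.sigma_nm)
        return thompson_precision(self.photons, self.background, self.psf_sigma_nm)


def simulate_cluster(spec: ClusterSpec, seed: int | np.random.Generator) -> LocalizationTable:
    """Sample a localization cloud: true emitter positions on the shape plus
    Gaussian localization error."""
    rng = np.random.default_rng(seed)
    n = spec.n_localizations
    cx, cy = spec.center
    if spec.shape == "point":
        tx = np.full(n, cx)
        ty = np.full(n, cy)
    elif spec.shape == "disk":
        r = spec.radius_nm * np.sqrt(rng.random(n))
        th = rng.uniform(0.0, 2.0 * np.pi, n)
        tx = cx + r * np.cos(th)
        ty = cy + r * np.sin(th)
    else:  # annular-arc
        r_in = max(0.0, spec.radius_nm - spec.width_nm / 2.0)
        r_out = spec.radius_nm + spec.width_nm / 2.0
        r = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
        th = rng.uniform(
            np.deg2rad(spec.arc_start_deg), np.deg2rad(spec.arc_end_deg), n
        )
        tx = cx + r * np.cos(th)
        ty = cy + r * np.sin(th)
    sigma = spec.precision_nm()
    x = tx + rng.normal(0.0, sigma, n)
    y = ty + rng.normal(0.0, sigma, n)
    return LocalizationTable.from_arrays(
        frame=np.arange(n),
        x_nm=x,
        y_nm=y,
        photons=spec.photons,
        background=spec.background,
        sigma_nm=sigma,
    )
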