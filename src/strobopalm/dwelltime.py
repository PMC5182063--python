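"""Residence-time inference from strobed track-length distributions.

The apparent (effective) on-time of a bound, tagged molecule convolves the
true binding lifetime tau_off with the photobleaching lifetime tau_b:

    1/tau_eff = 1/tau_off + 1/tau_b                      (continuous light)

Stroboscopic illumination with frame period tau_tl and exposure tau_int slows
bleaching by tau_tl/tau_int, giving the hyperbolic model fitted across strobe
conditions (the Gebhardt-style model, here fitted by non-linear least squares
on the raw effective on-times rather than on the linearizing transform, which
distorts the error distribution):

    tau_eff(tau_tl) = (1/tau_off + tau_int/(tau_b*tau_tl))^(-1)

At strobe intervals much longer than the binding time, observed track lengths
collapse towards one frame and the apparent on-time (in frames) flattens at a
minimum measurable value n_min instead of continuing to fall hyperbolically.
The revised plateau model accounts for this floor:

    n_obs(tau_tl) = max( tau_eff(tau_tl)/tau_tl , n_min )   [frames]

All fitting here is done on the effective on-time expressed in frames, where
the plateau is zero-gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .loc_data import AcquisitionSettings
from .synthetic import KineticParams

__all__ = [
    "EffectiveOnTime",
    "DwellFit",
    "OnTimePrediction",
    "fit_effective_ontime",
    "geometric_mle_neff",
    "predict_observed_ontime",
    "fit_gebhardt",
    "fit_plateau_model",
    "bootstrap_confidence",
    "compare_conditions",
    "DwellFitError",
]


class DwellFitError(RuntimeError):
    """Raised when an on-time or dwell-model fit cannot be performed."""


@dataclass(frozen=True)
class EffectiveOnTime:
    """Fitted effective on-time of one strobe condition.

    ``n_eff_frames`` is the exponential decay constant of the track-length
    histogram, in frames; ``se_frames`` its standard error from the fit.
    """

    tau_tl_ms: float
    n_eff_frames: float
    se_frames: float
    n_tracks: int

    def __post_init__(self) -> None:
        if not (self.n_eff_frames > 0):
            raise ValueError("n_eff_frames must be > 0")


@dataclass(frozen=True)
class OnTimePrediction:
    """Model-predicted effective on-time for one strobe condition."""

    tau_eff_ms: float
    frames: float


@dataclass
class DwellFit:
    """Result of fitting effective on-times across strobe intervals."""

    model: Literal["gebhardt", "plateau"]
    tau_off_ms: float
    tau_bleach_ms: float
    n_min_frames: float | None
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_points: int
    tau_int_ms: float

    def predict_frames(self, tau_tl_ms: np.ndarray) -> np.ndarray:
        tau_tl_ms = np.asarray(tau_tl_ms, dtype=float)
        frames = 1.0 / (
            tau_tl_ms / self.tau_off_ms + self.tau_int_ms / self.tau_bleach_ms
        )
        if self.model == "plateau":
            frames = np.maximum(frames, self.n_min_frames)
        return frames


# ---------------------------------------------------------------------------
# per-condition exponential fit
# ---------------------------------------------------------------------------

def _hist_arrays(hist: dict[int, int]) -> tuple[np.ndarray, np.ndarray]:
    if not hist:
        raise DwellFitError("empty track-length histogram")
    lengths = np.array(sorted(hist), dtype=float)
    counts = np.array([hist[int(l)] for l in lengths], dtype=float)
    if (lengths < 1).any() or (counts < 0).any():
        raise DwellFitError("histogram support must be positive integers with counts >= 0")
    return lengths, counts


def fit_effective_ontime(
    hist: dict[int, int],
    tau_tl_ms: float = float("nan"),
    min_tracks: int = 50,
) -> EffectiveOnTime:
    """Least-squares fit of ``count(L) = A * exp(-L / n_eff)`` to a track-length
    histogram.

    The fit is unweighted on raw counts over the occupied support (interior
    zero bins included, trailing zeros excluded; the L = 1 bin is included).
    Raises :class:`DwellFitError` when fewer than two occupied bins are
    present (the on-time is then unresolvable) or when the track count is
    below ``min_tracks``.
    """
    lengths, counts = _hist_arrays(hist)
    occupied = counts > 0
    if occupied.sum() < 2:
        raise DwellFitError(
            "on-time unresolvable: track-length histogram has a single occupied bin"
        )
    n_tracks = int(counts.sum())
    if n_tracks < min_tracks:
        raise DwellFitError(f"too few tracks ({n_tracks} < {min_tracks})")
    last = np.max(np.flatnonzero(occupied))
    L = np.arange(lengths[0], lengths[last] + 1)
    c = np.zeros_like(L, dtype=float)
    idx = (lengths[: last + 1] - lengths[0]).astype(int)
    c[idx] = counts[: last + 1]

    # log-linear initialization on the occupied bins
    pos = c > 0
    slope, intercept = np.polyfit(L[pos], np.log(c[pos]), 1)
    n0 = -1.0 / slope if slope < 0 else float(np.mean(L))
    a0 = float(np.exp(intercept))

    def model(l, a, n):
        return a * np.exp(-l / n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, pcov = optimize.curve_fit(
                model, L, c, p0=(a0, max(n0, 1e-3)), maxfev=20_000
            )
        except RuntimeError as exc:  # pragma: no cover - pathological input
            raise DwellFitError(f"exponential fit did not converge: {exc}") from exc
    a_hat, n_hat = popt
    if not (n_hat > 0 and np.isfinite(n_hat)):
        raise DwellFitError(f"non-physical on-time estimate {n_hat!r}")
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return EffectiveOnTime(
        tau_tl_ms=tau_tl_ms, n_eff_frames=float(n_hat), se_frames=se, n_tracks=n_tracks
    )


def geometric_mle_neff(lengths: np.ndarray) -> float:
    """Closed-form geometric maximum-likelihood estimate of the decay constant.

    For track lengths L >= 1 with P(L) proportional to exp(-L/n), the MLE of
    the per-frame survival probability is ``1 - 1/mean(L)``, giving
    ``n = -1/log(1 - 1/mean)``.  Provided as an independent cross-check of the
    least-squares histogram fit.
    """
    lengths = np.asarray(lengths, dtype=float)
    m = lengths.mean()
    if m <= 1.0:
        raise DwellFitError("mean track length <= 1 frame: decay constant unresolvable")
    return float(-1.0 / np.log1p(-1.0 / m))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def predict_observed_ontime(
    kin: KineticParams,
    acq: AcquisitionSettings,
    n_min_frames: float | None = None,
) -> OnTimePrediction:
    """Effective on-time predicted for one strobe condition.

    Without ``n_min_frames`` this is the hyperbolic (Gebhardt) model; with it,
    the frames prediction is floored at ``n_min_frames`` (continuous max-form
    plateau model) and the time prediction is the floored value times the
    frame period.
    """
    tau_eff = 1.0 / (
        1.0 / kin.tau_off_ms + acq.tau_int_ms / (kin.tau_bleach_ms * acq.tau_tl_ms)
    )
    frames = tau_eff / acq.tau_tl_ms
    if n_min_frames is not None:
        frames = max(frames, n_min_frames)
        tau_eff = frames * acq.tau_tl_ms
    return OnTimePrediction(tau_eff_ms=float(tau_eff), frames=float(frames))


# ---------------------------------------------------------------------------
# cross-condition NLS fits
# ---------------------------------------------------------------------------

def _frames_model(theta: np.ndarray, tau_tl: np.ndarray, tau_int: float, plateau: bool):
    tau_off, tau_b = np.exp(theta[0]), np.exp(theta[1])
    frames = 1.0 / (tau_tl / tau_off + tau_int / tau_b)
    if plateau:
        frames = np.maximum(frames, np.exp(theta[2]))
    return frames


def _nls_fit(
    points: Sequence[EffectiveOnTime],
    tau_int_ms: float,
    plateau: bool,
    model_tag: str,
    theta0_override: np.ndarray | None = None,
    tau_bleach_fixed_ms: float | None = None,
) -> DwellFit:
    tau_tl = np.array([p.tau_tl_ms for p in points], dtype=float)
    y = np.array([p.n_eff_frames for p in points], dtype=float)
    n_params = 3 if plateau else 2
    n_distinct = len(np.unique(tau_tl))
    min_distinct = (4 if plateau else 3) - (1 if tau_bleach_fixed_ms else 0)
    if n_distinct < min_distinct:
        raise DwellFitError(
            f"{model_tag} fit needs >= {min_distinct} distinct strobe intervals, "
            f"got {n_distinct}"
        )

    if tau_bleach_fixed_ms is None:
        free = np.arange(n_params)
    else:
        free = np.array([i for i in range(n_params) if i != 1])

    def expand(theta_free):
        theta = np.empty(n_params)
        theta[free] = theta_free
        if tau_bleach_fixed_ms is not None:
            theta[1] = np.log(tau_bleach_fixed_ms)
        return theta

    def residuals(theta_free):
        return _frames_model(expand(theta_free), tau_tl, tau_int_ms, plateau) - y

    # start grid in log-space to guard against local minima
    if theta0_override is not None:
        starts = [np.asarray(theta0_override, dtype=float)[free]]
    else:
        tau_off_starts = [tau_tl.min() * 2, np.median(tau_tl), tau_tl.max()]
        tau_b_starts = [tau_int_ms, tau_int_ms * 5]
        nmin_starts = (
            [max(y.min(), 1e-3), max(0.5 * y.min(), 1e-3)] if plateau else [None]
        )
        starts = []
        for to in tau_off_starts:
            for tb in tau_b_starts:
                for nm in nmin_starts:
                    full = [np.log(to), np.log(tb)] + (
                        [np.log(nm)] if plateau else []
                    )
                    starts.append(np.asarray(full)[free])
    best = None
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                residuals, theta0, method="trf", xtol=1e-12, ftol=1e-12,
                gtol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise DwellFitError(f"{model_tag} fit did not converge")

    theta = expand(best.x)
    rss = float(2.0 * best.cost)
    dof = max(len(y) - len(free), 1)
    sigma2 = rss / dof
    # covariance of the free log-parameters from the Jacobian at the optimum
    J = best.jac
    se = np.zeros(n_params)
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se[free] = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se[:] = np.nan
        se[free] = np.nan
    tcrit = stats.t.ppf(0.975, dof)
    names = ["tau_off_ms", "tau_bleach_ms"] + (["n_min_frames"] if plateau else [])
    ci = {
        name: (
            float(np.exp(np.clip(t - tcrit * s, -700, 700))),
            float(np.exp(np.clip(t + tcrit * s, -700, 700))),
        )
        for name, t, s in zip(names, theta, se)
    }
    return DwellFit(
        model=model_tag,
        tau_off_ms=float(np.exp(theta[0])),
        tau_bleach_ms=float(np.exp(theta[1])),
        n_min_frames=float(np.exp(theta[2])) if plateau else None,
        ci95=ci,
        rss=rss,
        n_points=len(y),
        tau_int_ms=tau_int_ms,
    )


def fit_gebhardt(
    points: Sequence[EffectiveOnTime],
    tau_int_ms: float,
    tau_bleach_fixed_ms: float | None = None,
) -> DwellFit:
    """Non-linear least squares of the hyperbolic on-time model (in frames)
    against the raw fitted effective on-times across strobe intervals.

    ``tau_bleach_fixed_ms`` pins the bleaching lifetime (e.g. measured under
    continuous illumination) instead of co-fitting it.
    """
    return _nls_fit(
        points, tau_int_ms, plateau=False, model_tag="gebhardt",
        tau_bleach_fixed_ms=tau_bleach_fixed_ms,
    )


def fit_plateau_model(
    points: Sequence[EffectiveOnTime],
    tau_int_ms: float,
    tau_bleach_fixed_ms: float | None = None,
) -> DwellFit:
    """Non-linear least squares of the plateau model
    ``max(tau_eff/tau_tl, n_min)`` against the fitted effective on-times."""
    return _nls_fit(
        points, tau_int_ms, plateau=True, model_tag="plateau",
        tau_bleach_fixed_ms=tau_bleach_fixed_ms,
    )


def bootstrap_confidence(
    points: Sequence[EffectiveOnTime],
    model: Literal["gebhardt", "plateau"],
    tau_int_ms: float,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap 95% percentile confidence intervals.

    Strobe-condition points are resampled with replacement; resamples with too
    few distinct intervals to identify the model are redrawn.  Deterministic
    under ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    min_distinct = 4 if model == "plateau" else 3
    pts = list(points)
    if len(np.unique([p.tau_tl_ms for p in pts])) < min_distinct:
        raise DwellFitError("too few strobe conditions to resample")
    plateau = model == "plateau"
    # warm-start every resample fit from the full-sample point estimate
    point_fit = _nls_fit(pts, tau_int_ms, plateau=plateau, model_tag=model)
    theta_hat = [np.log(point_fit.tau_off_ms), np.log(point_fit.tau_bleach_ms)]
    if plateau:
        theta_hat.append(np.log(point_fit.n_min_frames))
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {}
    done = 0
    attempts = 0
    while done < n_boot and attempts < 50 * n_boot:
        attempts += 1
        idx = rng.integers(0, len(pts), len(pts))
        resample = [pts[i] for i in idx]
        if len(np.unique([p.tau_tl_ms for p in resample])) < min_distinct:
            continue
        try:
            fit = _nls_fit(
                resample, tau_int_ms, plateau=plateau, model_tag=model,
                theta0_override=np.asarray(theta_hat),
            )
        except DwellFitError:
            continue
        values = {"tau_off_ms": fit.tau_off_ms, "tau_bleach_ms": fit.tau_bleach_ms}
        if model == "plateau":
            values["n_min_frames"] = fit.n_min_frames
        for k, v in values.items():
            samples.setdefault(k, []).append(v)
        done += 1
    if done < n_boot:
        raise DwellFitError("bootstrap failed to reach the requested replicate count")
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in samples.items()
    }


def compare_conditions(
    replicates_a: Sequence[float], replicates_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Welch t-test on replicate binding-time estimates.

    Returns ``(t, p)``; identical replicate sets give t = 0, p = 1.
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicate estimates per condition")
    if np.array_equal(a, b) and np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
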