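"""Transition and correlation-length fits.

Two models are fitted:

* the four-parameter sigmoidal transition
  ``m(r) = 1/2 [(a + b) + (b - a) tanh((r - r0) / rs)]``
  used to locate the core boundary ``r0`` from radial profiles (orientation
  by convention; density, length and energy as cross-checks);

* the exponential tangent-correlation model
  ``C(ds) = <t(s) . t(s+ds)> = exp(-ds / lc)``
  whose decay length ``lc`` is the orientational correlation length.  For a
  thermally fluctuating filament lc is the persistence length
  ``kappa / kBT ~ 10 um``; shorter lc signals active deformation.

Both are unweighted least squares on bin/lag means (counts are reported so
users can re-weight).  The correlation fit is performed in linear space so
near-zero or slightly negative C at long lags remain usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .geometry import ResampledTrack, chord_tangents
from .io_tracks import PodosomeFrame
from .profiles import RadialProfile, profile_local, radial_distance
from .units import nm_to_um

__all__ = [
    "TransitionFit",
    "CorrelationResult",
    "FitError",
    "tanh_transition",
    "fit_transition",
    "estimate_core_radius",
    "tangent_correlation",
    "fit_correlation_length",
]


class FitError(RuntimeError):
    """A required fit failed or was unidentifiable."""


def tanh_transition(r, a, b, r0, rs):
    """Sigmoid with plateaus ``a`` (inner) and ``b`` (outer), midpoint ``r0``
    and transition width ``rs``."""
    return 0.5 * ((a + b) + (b - a) * np.tanh((r - r0) / rs))


@dataclass(frozen=True)
class TransitionFit:
    a: float
    b: float
    r0_nm: float
    rs_nm: float
    residual_norm: float
    converged: bool
    message: str = ""


def _initial_guess(r: np.ndarray, v: np.ndarray, bin_width: float,
                   w: np.ndarray | None = None):
    third = max(1, len(v) // 3)
    a0 = float(np.mean(v[:third]))
    b0 = float(np.mean(v[-third:]))
    # locate the steepest slope on a 3-bin moving average, restricted to
    # well-populated bins so tail noise cannot set the starting midpoint
    vs = np.convolve(v, np.ones(3) / 3.0, mode="same")
    slope = np.abs(np.diff(vs) / np.diff(r))
    if w is not None:
        power = np.minimum(w[:-1], w[1:]) > 0.1 * np.max(w)
        if power.any():
            slope = np.where(power, slope, 0.0)
    r0_0 = float(0.5 * (r[:-1] + r[1:])[int(np.argmax(slope))])
    return a0, b0, r0_0, 2.0 * bin_width


def fit_transition(profile: RadialProfile, n_restarts: int = 5,
                   weight_by_counts: bool = True) -> TransitionFit:
    """Nonlinear least squares of the tanh transition to a radial profile.

    Empty (NaN) bins are excluded.  Bins are weighted by their point counts
    by default (the variance of a bin mean scales as 1/count; without this,
    near-empty far-tail bins can capture the fit), with ``weight_by_counts=
    False`` for plain unweighted residuals.  Initialization is data-driven
    (inner / outer third plateaus, steepest finite-difference slope, rs = 2
    bin widths) with jittered random restarts on non-convergence.  A
    constant profile or a failed fit is flagged - never silently replaced.
    """
    mask = np.isfinite(profile.values)
    r = profile.bin_centers_nm[mask]
    v = profile.values[mask]
    w = profile.counts[mask] if weight_by_counts else np.ones_like(v)
    if len(r) < 6:
        return TransitionFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                             f"only {len(r)} non-empty bins (need >= 6)")
    vmax_abs = float(np.max(np.abs(v)))
    vrange = float(np.max(v) - np.min(v))
    if vmax_abs == 0.0 or vrange <= 1e-12 * vmax_abs:
        return TransitionFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                             "constant profile: r0 unidentifiable")
    # normalize the observable so the optimizer sees O(1) plateau parameters
    # whatever the observable's units (densities can be ~1e-23 in SI/nm^3)
    vscale = vmax_abs
    v = v / vscale
    vrange /= vscale
    p0 = _initial_guess(r, v, profile.bin_width_nm, w)
    # plateaus within the data range (+/- one range), r0 inside the profiled
    # domain, rs between a fraction of a bin and the domain span: the fitted
    # transition must describe the data, not a runaway tail extrapolation
    vlo, vhi = float(np.min(v)), float(np.max(v))
    span = r[-1] - r[0]
    lower = [vlo - vrange, vlo - vrange, r[0], profile.bin_width_nm / 10.0]
    upper = [vhi + vrange, vhi + vrange, r[-1], span]
    guesses = [tuple(np.clip(p0, lower, upper))]
    # multistart: scatter the midpoint across the domain interior
    for frac in np.linspace(0.1, 0.8, max(1, n_restarts)):
        guesses.append((p0[0], p0[1], r[0] + frac * span, p0[3]))
    best = None
    for guess in guesses:
        try:
            popt, _ = curve_fit(tanh_transition, r, v, p0=guess,
                                sigma=1.0 / np.sqrt(w), bounds=(lower, upper),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(np.sqrt(w / w.max())
                                     * (v - tanh_transition(r, *popt))))
        # a midpoint pinned to the domain edge is a plateau/tail artefact,
        # not a located transition: only accepted if nothing interior converges
        pinned = popt[2] <= r[0] + 1e-6 or popt[2] >= r[-1] - 1e-6
        key = (pinned, resid)
        if best is None or key < best[1]:
            best = (popt, key)
    if best is None:
        return TransitionFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                             "no restart converged")
    (a, b, r0, rs), (pinned, resid) = best
    a, b, resid = a * vscale, b * vscale, resid * vscale
    if pinned:
        return TransitionFit(float(a), float(b), float(r0), float(rs), resid,
                             False, "fitted r0 pinned to the domain edge")
    return TransitionFit(float(a), float(b), float(r0), float(rs), resid, True)


def estimate_core_radius(
    resampled_tracks: list[ResampledTrack],
    frame: PodosomeFrame,
    bin_width: float = 25.0,
    extra_profiles: dict[str, RadialProfile] | None = None,
) -> tuple[float, dict[str, TransitionFit]]:
    """Core radius = ``r0`` of the tanh fit to the orientation profile.

    Cross-check fits to any profiles passed in ``extra_profiles`` (density,
    length, energy density) are returned alongside.  Raises ``FitError`` if
    the orientation fit fails, listing which cross-checks succeeded.
    """
    from .geometry import orientation_to_membrane

    thetas, rr = [], []
    for t in resampled_tracks:
        thetas.append(orientation_to_membrane(t, frame.membrane))
        rr.append(radial_distance(t.points, frame))
    prof = profile_local(np.concatenate(thetas), np.concatenate(rr),
                         bin_width, "orientation_deg")
    fits = {"orientation_deg": fit_transition(prof)}
    for name, p in (extra_profiles or {}).items():
        fits[name] = fit_transition(p)
    main = fits["orientation_deg"]
    if not main.converged:
        ok = [k for k, f in fits.items() if f.converged]
        raise FitError(
            f"orientation transition fit failed ({main.message}); "
            f"converged cross-checks: {ok or 'none'}"
        )
    return main.r0_nm, fits


# ---------------------------------------------------------------------------
# tangent correlation


@dataclass(frozen=True)
class CorrelationResult:
    """Tangent auto-correlation ``C(ds)`` pooled over filaments."""

    ds_nm: np.ndarray
    C: np.ndarray
    counts: np.ndarray
    region: str = "all"
    spacing_a: float = 3.0
    lc_um: float | None = None
    converged: bool = True
    retained_ds_nm: np.ndarray = field(default_factory=lambda: np.array([]))


def tangent_correlation(
    tracks: list[ResampledTrack],
    region_mask: "callable | None" = None,
    region: str = "all",
) -> CorrelationResult:
    """``C(ds) = <t(s) . t(s+ds)>`` over all same-filament point pairs.

    ``region_mask(points) -> bool array`` restricts pairs to those whose two
    chord base points both lie in the region (boundary-straddling pairs are
    excluded).  Lag 0 is included and is exactly 1.
    """
    if not tracks:
        raise ValueError("no tracks to correlate")
    a = tracks[0].spacing_a
    max_lag = 0
    per_track = []
    for t in tracks:
        tg = chord_tangents(t)  # true chords only; no duplicated end tangent
        base = t.points[:-1]
        mask = np.ones(len(tg), bool) if region_mask is None else \
            np.asarray(region_mask(base), bool)
        per_track.append((tg, mask))
        max_lag = max(max_lag, len(tg) - 1)
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for tg, mask in per_track:
        m = len(tg)
        n0 = int(mask.sum())
        sums[0] += n0
        counts[0] += n0
        for k in range(1, m):
            pair = mask[: m - k] & mask[k:]
            if not pair.any():
                continue
            dots = np.einsum("ij,ij->i", tg[: m - k][pair], tg[k:][pair])
            sums[k] += dots.sum()
            counts[k] += int(pair.sum())
    keep = counts > 0
    ds = np.arange(max_lag + 1)[keep] * a
    with np.errstate(invalid="ignore"):
        C = sums[keep] / counts[keep]
    return CorrelationResult(ds, C, counts[keep], region=region, spacing_a=a)


def fit_correlation_length(result: CorrelationResult) -> CorrelationResult:
    """Fit ``exp(-ds/lc)`` to C(ds), keeping only lags with more than half
    the lag-0 pair count (statistical-power rule).  Returns a copy with
    ``lc_um`` filled in; if the retained correlation never drops below 0.999
    the filaments are effectively straight and ``lc_um = inf`` is flagged
    instead of a fitted number.
    """
    n0 = result.counts[0]
    retained = result.counts > 0.5 * n0
    retained[0] = True  # shortest lag is always kept when any pairs exist
    ds = result.ds_nm[retained]
    C = result.C[retained]
    if len(ds) < 4:
        raise FitError(f"only {len(ds)} retained lags (need >= 4)")
    if np.min(C) >= 0.999:
        return CorrelationResult(result.ds_nm, result.C, result.counts,
                                 result.region, result.spacing_a,
                                 lc_um=math.inf, converged=True,
                                 retained_ds_nm=ds)
    # p0 from a log-linear slope over the clearly positive part
    pos = C > 0.05
    slope = np.polyfit(ds[pos], np.log(C[pos]), 1)[0]
    lc0 = -1.0 / slope if slope < 0 else float(ds[-1])
    try:
        popt, _ = curve_fit(lambda s, lc: np.exp(-s / lc), ds, C,
                            p0=[max(lc0, result.spacing_a)], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"correlation-length fit did not converge: {exc}") from exc
    lc_nm = float(abs(popt[0]))
    return CorrelationResult(result.ds_nm, result.C, result.counts,
                             result.region, result.spacing_a,
                             lc_um=nm_to_um(lc_nm), converged=True,
                             retained_ds_nm=ds)
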