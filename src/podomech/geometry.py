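"""Per-filament differential geometry.

Filament polylines are resampled to uniform arc-length spacing (3 nm by
default, so every point carries the same weight), then tangents are taken as
normalized forward chords.  The local curvature between consecutive tangents
is ``gamma = arccos(t_i . t_{i+1}) / a`` and the stored bending energy of a
semiflexible filament with bending modulus ``kappa`` is the discretization of

    u_elastic = (kappa / 2) * integral |dt/ds|^2 ds

i.e. each joint contributes ``(kappa * w / 2) * gamma^2`` with ``w`` the
arc length the joint represents.  On points sampled from a circle the chord
construction returns exactly ``gamma = 1/R``, which makes circular arcs exact
analytic oracles for every quantity in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_tracks import FilamentTrack, MembranePlane, PodosomeFrame, TrackValidationError
from .units import M_PER_NM

__all__ = [
    "ResampledTrack",
    "JointGeometry",
    "FilamentSummary",
    "TrackTooShortError",
    "resample",
    "resample_network",
    "tangents",
    "chord_tangents",
    "local_curvature",
    "orientation_to_membrane",
    "filament_strain",
    "joint_energy",
    "joint_geometry",
    "summarize_filament",
]


class TrackTooShortError(ValueError):
    """Contour length below twice the resampling spacing."""


@dataclass(frozen=True)
class ResampledTrack:
    """A filament polyline at uniform arc-length spacing ``spacing_a`` (nm)."""

    filament_id: str
    points: np.ndarray  # (n, 3), nm
    spacing_a: float  # nm

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def reversed(self) -> "ResampledTrack":
        return ResampledTrack(self.filament_id, self.points[::-1].copy(), self.spacing_a)


def resample(track: FilamentTrack | ResampledTrack, a: float = 3.0) -> ResampledTrack:
    """Resample a polyline at uniform arc-length spacing ~``a`` nm.

    Points are linearly interpolated along the original polyline; the first
    and last original endpoints are retained.  The number of segments is
    ``round(L / a)`` so the realized spacing is ``L / round(L / a)`` (equal to
    ``a`` when the contour divides evenly, within ``a / (2 L)`` relative
    otherwise).

    Raises
    ------
    TrackTooShortError
        If the contour length is below ``2 a``; callers exclude such
        filaments and count them in provenance.
    """
    if a <= 0:
        raise ValueError("spacing a must be positive")
    pts = track.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    L = float(seg.sum())
    if L < 2 * a:
        raise TrackTooShortError(
            f"filament {track.filament_id!r}: contour {L:.3g} nm < 2a = {2 * a:.3g} nm"
        )
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_seg = max(2, int(round(L / a)))
    s_new = np.linspace(0.0, L, n_seg + 1)
    new = np.column_stack([np.interp(s_new, cum, pts[:, k]) for k in range(3)])
    # exact endpoint retention against interpolation round-off
    new[0] = pts[0]
    new[-1] = pts[-1]
    return ResampledTrack(track.filament_id, new, L / n_seg)


def resample_network(tracks, a: float = 3.0):
    """Resample every track; returns (resampled list, n_skipped_too_short)."""
    out, skipped = [], 0
    for t in tracks:
        try:
            out.append(resample(t, a))
        except TrackTooShortError:
            skipped += 1
    return out, skipped


def chord_tangents(track: ResampledTrack | FilamentTrack) -> np.ndarray:
    """Unit chord directions, one per segment: shape (n-1, 3)."""
    d = np.diff(track.points, axis=0)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    return d / norms


def tangents(track: ResampledTrack | FilamentTrack) -> np.ndarray:
    """Per-point unit tangents: forward chord at each point, the last point
    inheriting the final chord.  Shape (n, 3)."""
    t = chord_tangents(track)
    return np.vstack([t, t[-1]])


def local_curvature(track: ResampledTrack) -> np.ndarray:
    """Discrete curvature at each interior joint, nm^-1: shape (n-2,).

    ``gamma_j = arccos(t_j . t_{j+1}) / a`` over consecutive chord tangents;
    dot products are clamped to [-1, 1] before the arccos.
    """
    if track.n_points < 3:
        raise TrackValidationError("local curvature needs at least 3 points")
    t = chord_tangents(track)
    dots = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1.0, 1.0)
    return np.arccos(dots) / track.spacing_a


def orientation_to_membrane(
    track: ResampledTrack | FilamentTrack, membrane: MembranePlane
) -> np.ndarray:
    """Unsigned angle of each point's tangent to the membrane plane, degrees
    in [0, 90]: ``theta = arcsin(|t . normal|)``."""
    t = tangents(track)
    s = np.clip(np.abs(t @ membrane.normal), 0.0, 1.0)
    return np.degrees(np.arcsin(s))


def filament_strain(track: FilamentTrack | ResampledTrack) -> float:
    """Compressive strain ``eps = 1 - end_to_end / contour`` in [0, 1).

    Computed on the raw polyline (resampling changes it by <1%).
    """
    L = track.contour_length
    if L <= 0:
        raise TrackValidationError("zero contour length")
    return 1.0 - track.end_to_end / L


def _joint_weights_nm(track: ResampledTrack) -> np.ndarray:
    """Arc length represented by each interior joint, nm.

    Each joint owns half of its two flanking segments (weight ``a``); the
    first and last joints additionally absorb the terminal half-segments
    (weight ``1.5 a``), so the weights always sum to the full contour
    ``(n-1) a`` and the discrete energy is exact for uniform-curvature arcs.
    """
    a = track.spacing_a
    n_joints = track.n_points - 2
    w = np.full(n_joints, a)
    w[0] += 0.5 * a
    w[-1] += 0.5 * a
    return w


def joint_energy(track: ResampledTrack, kappa: float) -> np.ndarray:
    """Bending energy per interior joint, J: ``u_j = (kappa w_j / 2) gamma_j^2``.

    ``kappa`` is the bending modulus in N m^2; curvature and weights are
    converted to SI internally.  Summing over joints discretizes the
    continuum bending integral; for an arc of radius R and contour L the sum
    equals ``kappa L / (2 R^2)`` exactly.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    gamma_m = local_curvature(track) / M_PER_NM  # nm^-1 -> m^-1
    w_m = _joint_weights_nm(track) * M_PER_NM
    return 0.5 * kappa * w_m * gamma_m**2


@dataclass(frozen=True)
class JointGeometry:
    """Per-joint geometry of one resampled filament.

    All arrays are aligned to the ``n - 2`` interior points: position,
    tangent (forward chord), curvature (nm^-1), orientation to the membrane
    (deg), radial distance to the core axis (nm) and bending-energy
    contribution (J).
    """

    filament_id: str
    positions: np.ndarray  # (m, 3) nm
    tangent: np.ndarray  # (m, 3) unit
    curvature: np.ndarray  # (m,) nm^-1
    orientation_deg: np.ndarray  # (m,)
    radial_distance_nm: np.ndarray  # (m,)
    joint_energy_j: np.ndarray  # (m,)


def joint_geometry(
    track: ResampledTrack, frame: PodosomeFrame, kappa: float
) -> JointGeometry:
    """Bundle curvature, orientation, radial distance and bending energy at
    the interior points of one resampled filament."""
    from .profiles import radial_distance  # local import to avoid a cycle

    pts = track.points[1:-1]
    t = tangents(track)[1:-1]
    theta = orientation_to_membrane(track, frame.membrane)[1:-1]
    return JointGeometry(
        filament_id=track.filament_id,
        positions=pts,
        tangent=t,
        curvature=local_curvature(track),
        orientation_deg=theta,
        radial_distance_nm=radial_distance(pts, frame),
        joint_energy_j=joint_energy(track, kappa),
    )


@dataclass(frozen=True)
class FilamentSummary:
    """Whole-filament descriptors derived from one trace."""

    filament_id: str
    contour_length_nm: float
    end_to_end_nm: float
    strain: float
    mean_orientation_deg: float
    mean_curvature_nm1: float
    total_bending_energy_j: float


def summarize_filament(
    raw: FilamentTrack,
    resampled: ResampledTrack,
    membrane: MembranePlane,
    kappa: float,
) -> FilamentSummary:
    return FilamentSummary(
        filament_id=raw.filament_id,
        contour_length_nm=raw.contour_length,
        end_to_end_nm=raw.end_to_end,
        strain=filament_strain(raw),
        mean_orientation_deg=float(
            np.mean(orientation_to_membrane(resampled, membrane))
        ),
        mean_curvature_nm1=float(np.mean(local_curvature(resampled))),
        total_bending_energy_j=float(np.sum(joint_energy(resampled, kappa))),
    )
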