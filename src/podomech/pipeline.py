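"""End-to-end orchestration: load/filter -> frame -> geometry -> profiles ->
fits -> mechanics -> reports.

``run_full`` is a pure composition of the module operations (no hidden
state): every number in the reports equals what the individual operations
return on the same inputs.  Stage outputs are written to disk when an output
directory is given, so the fit and mechanics stages can be re-run with
different constants without recomputing geometry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fits import (CorrelationResult, FitError, TransitionFit,
                   fit_correlation_length, fit_transition, tangent_correlation)
from .geometry import (FilamentSummary, joint_geometry, orientation_to_membrane,
                       resample_network, summarize_filament)
from .io_tracks import (FilamentNetwork, MembranePlane, PodosomeFrame,
                        filter_min_length, read_track_table, write_report,
                        write_track_table)
from .mechanics import (CoreMechanicsReport, MechanicsConstants,
                        PolymerizationReport, core_mechanics_report,
                        polymerization_report, select_protrusive)
from .profiles import (RadialProfile, density_profile, energy_density_profile,
                       estimate_core_center, profile_local, profile_nonlocal,
                       radial_distance)
from .synthetic import SyntheticPodosomeConfig, generate_podosome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_full"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one full analysis run.

    Defaults are the standard processing constants: 60 nm minimum filament
    length, 3 nm resampling, 25 nm radial bins, 10 nm membrane proximity.
    """

    input_path: str | None = None
    dialect: str = "track-tsv"
    voxel_size_nm: float = 1.0
    synthetic: SyntheticPodosomeConfig | None = None
    constants: MechanicsConstants = field(default_factory=MechanicsConstants)
    bin_width_nm: float = 25.0
    resample_spacing_nm: float = 3.0
    min_length_nm: float = 60.0
    slab_height_nm: float = 400.0
    core_center: tuple[float, float, float] | None = None
    membrane_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    membrane_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    theta_radial_deg: float | None = None
    r_core_nm: float | None = None  # fixed core radius (skips the fit)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_width_nm", "resample_spacing_nm", "slab_height_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_length_nm < 0:
            raise ValueError("min_length_nm must be >= 0")
        if self.input_path is None and self.synthetic is None:
            raise ValueError("need either an input_path or a synthetic config")


@dataclass
class PipelineResult:
    config: PipelineConfig
    network: FilamentNetwork
    frame: PodosomeFrame
    profiles: dict[str, RadialProfile]
    transition_fits: dict[str, TransitionFit]
    r_core_nm: float
    correlations: dict[str, CorrelationResult]
    summaries: list[FilamentSummary]
    mechanics: CoreMechanicsReport
    polymerization: PolymerizationReport
    n_too_short: int
    ground_truth: dict | None = None

    def summary_table(self) -> pd.DataFrame:
        """One-row per-podosome summary mirroring the per-podosome reporting
        (r_core, lc in/out, eps_core, U_core, F_elastic, P, Y, sigma, n_p,
        F_polym)."""
        m, p = self.mechanics, self.polymerization
        core_corr = self.correlations.get("core")
        out_corr = self.correlations.get("outside")
        lc_core = core_corr.lc_um if core_corr is not None else float("nan")
        lc_out = out_corr.lc_um if out_corr is not None else float("nan")
        return pd.DataFrame([{
            "r_core_nm": m.r_core_nm,
            "lc_core_um": lc_core,
            "lc_outside_um": lc_out,
            "eps_core": m.eps_core,
            "u_core_kbt": m.u_core_kbt,
            "h_core_nm": m.h_core_nm,
            "f_elastic_nn": m.f_elastic_nn,
            "p_kpa": m.p_kpa,
            "y_mpa": m.y_mpa,
            "phi": m.phi,
            "y_pred_mpa": m.y_pred_mpa,
            "sigma_mn_per_m": m.sigma_mn_per_m,
            "theta_radial_deg": m.theta_radial_deg,
            "n_protrusive": p.n_portions,
            "f_polym_pn": p.f_polym_pn,
            "f_polym_1pn_pn": p.f_polym_1pn_pn,
            "u_polym_kbt": p.u_polym_kbt,
        }])


def _load(config: PipelineConfig):
    if config.synthetic is not None:
        network, frame, gt = generate_podosome(config.synthetic)
        return network, frame.membrane, gt
    network = read_track_table(config.input_path, config.dialect,
                               voxel_size_nm=config.voxel_size_nm)
    membrane = MembranePlane(np.asarray(config.membrane_origin, float),
                             np.asarray(config.membrane_normal, float))
    return network, membrane, None


def run_full(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage and (optionally) write all artifacts under ``outdir``.

    Deterministic given the config (the only randomness is the synthetic
    generator's seed and the fixed-sub-seed fit restarts).  Any stage
    failure raises with the stage name; artifacts written so far are left in
    place.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        network, membrane, ground_truth = _load(config)
        if out is not None:
            write_track_table(network, out / "tracks.tsv")
            if ground_truth is not None:
                write_report(ground_truth, out / "ground_truth.json")

        stage = "filter"
        network = filter_min_length(network, config.min_length_nm)

        stage = "resample"
        resampled, n_short = resample_network(network.tracks,
                                              config.resample_spacing_nm)
        if not resampled:
            raise ValueError("no filaments survive filtering/resampling")

        stage = "frame"
        all_points = np.vstack([t.points for t in resampled])
        frame = estimate_core_center(
            all_points, membrane,
            center=None if config.core_center is None
            else np.asarray(config.core_center, float),
        )

        stage = "geometry"
        kappa = config.constants.kappa
        geoms = [joint_geometry(t, frame, kappa) for t in resampled]
        raw_by_id = {t.filament_id: t for t in network.tracks}
        summaries = [summarize_filament(raw_by_id[t.filament_id], t, membrane, kappa)
                     for t in resampled]
        point_r = {t.filament_id: radial_distance(t.points, frame)
                   for t in resampled}
        point_z = {t.filament_id: membrane.signed_distance(t.points)
                   for t in resampled}
        joint_u = np.concatenate([g.joint_energy_j for g in geoms])
        joint_r = np.concatenate([g.radial_distance_nm for g in geoms])

        stage = "profiles"
        theta_all = np.concatenate(
            [orientation_to_membrane(t, membrane) for t in resampled])
        r_all = np.concatenate([point_r[t.filament_id] for t in resampled])
        profiles = {
            "orientation_deg": profile_local(
                theta_all, r_all, config.bin_width_nm, "orientation_deg"),
            "density": density_profile(
                r_all, config.bin_width_nm, config.slab_height_nm),
            "energy_density": energy_density_profile(
                joint_u, joint_r, config.bin_width_nm, config.slab_height_nm),
            "length_nm": profile_nonlocal(
                {s.filament_id: s.contour_length_nm for s in summaries},
                point_r, config.bin_width_nm, "length_nm"),
            "strain": profile_nonlocal(
                {s.filament_id: s.strain for s in summaries},
                point_r, config.bin_width_nm, "strain"),
        }
        if out is not None:
            for name, prof in profiles.items():
                write_report(prof, out / f"profile_{name}.tsv", format="tsv")

        stage = "fit"
        fits = {name: fit_transition(profiles[name])
                for name in ("orientation_deg", "density", "energy_density",
                             "length_nm")}
        if config.r_core_nm is not None:
            r_core = config.r_core_nm
        else:
            main = fits["orientation_deg"]
            if not main.converged:
                ok = [k for k, f in fits.items() if f.converged]
                raise FitError(
                    f"orientation transition fit failed ({main.message}); "
                    f"converged cross-checks: {ok or 'none'}")
            r_core = main.r0_nm

        def _core_mask(points):
            return radial_distance(points, frame) <= r_core

        def _out_mask(points):
            return radial_distance(points, frame) > r_core

        correlations = {}
        for region, mask in (("core", _core_mask), ("outside", _out_mask)):
            corr = tangent_correlation(resampled, mask, region=region)
            correlations[region] = (
                fit_correlation_length(corr)
                if len(corr.counts) and corr.counts[0] > 0 else None)
        if out is not None:
            write_report({k: dataclasses.asdict(v) for k, v in fits.items()},
                         out / "transition_fits.json")
            write_report(
                {k: (None if v is None
                     else {"lc_um": v.lc_um, "region": v.region,
                           "retained_ds_nm": v.retained_ds_nm.tolist()})
                 for k, v in correlations.items()},
                out / "correlation_fits.json")

        stage = "mechanics"
        portions = select_protrusive(resampled, membrane,
                                     config.constants.membrane_proximity_nm)
        core_len = sum(
            s.contour_length_nm for s in summaries
            if np.mean(point_r[s.filament_id] <= r_core) > 0.5)
        mech = core_mechanics_report(
            joint_u, joint_r, summaries, point_r, point_z, r_core,
            config.constants, theta_radial_deg=config.theta_radial_deg)
        polym = polymerization_report(portions, config.constants,
                                      total_core_length_nm=core_len)
        result = PipelineResult(
            config=config, network=network, frame=frame, profiles=profiles,
            transition_fits=fits, r_core_nm=r_core, correlations=correlations,
            summaries=summaries, mechanics=mech, polymerization=polym,
            n_too_short=n_short, ground_truth=ground_truth,
        )
        if out is not None:
            write_report(mech, out / "core_mechanics.json")
            write_report(polym, out / "polymerization.json")
            result.summary_table().to_csv(out / "summary.tsv", sep="\t",
                                          index=False, float_format="%.9g")
            _write_run_log(config, network, out)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_run_log(config: PipelineConfig, network: FilamentNetwork, out: Path) -> None:
    """Record the resolved config, input checksum and library versions."""
    checksum = None
    if config.input_path and Path(config.input_path).exists():
        checksum = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    log = {
        "podomech_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": dataclasses.asdict(config),
        "input_sha256": checksum,
        "n_filaments": len(network),
        "provenance": network.provenance,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
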