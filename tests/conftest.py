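import numpy as np
import pytest

import podomech as pm


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default-condition synthetic podosome (seed 1).

    Session-scoped: the end-to-end and pipeline tests all read from the same
    run, which also guarantees they see identical state.
    """
    cfg = pm.SyntheticPodosomeConfig(seed=1)
    return pm.run_full(pm.PipelineConfig(synthetic=cfg, seed=1))


@pytest.fixture
def membrane():
    return pm.MembranePlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))


@pytest.fixture
def frame(membrane):
    return pm.PodosomeFrame(membrane=membrane, core_center=np.zeros(3))


def straight_track(length_nm, n=4, direction=(1.0, 0.0, 0.0), fid="straight",
                   start=(0.0, 0.0, 0.0)):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    s = np.linspace(0.0, length_nm, n)
    return pm.FilamentTrack(fid, np.asarray(start) + np.outer(s, d))


def circle_resampled(radius_nm, arc_nm, step_nm, fid="circle"):
    """Points exactly on a circle at uniform arc spacing, wrapped as a
    ResampledTrack: the analytic oracle for curvature (1/R) and bending
    energy (kappa L / 2 R^2)."""
    arc = pm.make_arc_filament(radius_nm, arc_nm, step_nm, filament_id=fid)
    return pm.ResampledTrack(fid, arc.points, step_nm)


@pytest.fixture
def toy_network():
    tracks = [straight_track(90, 10, (1, 0, 0), "a"),
              straight_track(120, 10, (0, 1, 0), "b", start=(0, 0, 50))]
    return pm.FilamentNetwork(tracks=tracks, provenance={"filters": []})
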