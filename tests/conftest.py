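import numpy as np
import pytest

from protrack import PipelineConfig, SimulationSpec, process_frames, simulate_plate


@pytest.fixture(scope="session")
def study_plate():
    """The default study conditions: 300 cells, 60 um spacing, 5 um drift, 4 TPs."""
    spec = SimulationSpec(seed=11)
    images, truth = simulate_plate(spec)
    return spec, images, truth


@pytest.fixture(scope="session")
def study_result(study_plate):
    """Full pipeline run (align, preprocess, segment, track) on the study plate."""
    _, images, _ = study_plate
    return process_frames(images, PipelineConfig(), well="1B")


@pytest.fixture(scope="session")
def small_plate():
    """A 40-cell, 3-time-point plate for fast end-to-end checks."""
    spec = SimulationSpec(
        image_shape=(600, 600), n_cells=40, min_spacing=60.0, n_timepoints=3, seed=5
    )
    images, truth = simulate_plate(spec)
    return spec, images, truth


def label_to_truth_maps(frames_records, truth, tol_um=5.0):
    """Per time point, map each measured label to its nearest truth cell_id."""
    from scipy.spatial.distance import cdist

    maps = []
    for t, recs in enumerate(frames_records):
        tf = truth.frame(t)
        d = cdist(recs[["cx_um", "cy_um"]], tf[["cx_um", "cy_um"]])
        j = d.argmin(axis=1)
        assert d[np.arange(len(j)), j].max() < tol_um, "measured object far from any truth cell"
        maps.append(dict(zip(recs["label"], tf["cell_id"].iloc[j])))
    return maps
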