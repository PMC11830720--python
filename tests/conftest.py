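import numpy as np
import pandas as pd
import pytest

from retinavasc import simulate as sim
from retinavasc.config import RunConfig
from retinavasc.pipeline import measure_map

#: Seed of the shared synthetic cohort used by the recovery and
#: group-comparison tests.
COHORT_SEED = 7
N_PER_GROUP = 50


@pytest.fixture(scope="session")
def sim_geometry():
    return sim.SimGeometry()


@pytest.fixture(scope="session")
def run_config(sim_geometry):
    return RunConfig(pixel_spacing_um=sim_geometry.pixel_spacing_um)


@pytest.fixture(scope="session")
def single_image(sim_geometry):
    """One synthetic eye with its ground truth (deterministic)."""
    rng = np.random.default_rng([COHORT_SEED, 0])
    segmap, a_trees, v_trees = sim.generate_image(
        sim.artery_defaults(), sim.vein_defaults(), rng, sim_geometry, "fixture0"
    )
    return segmap, a_trees, v_trees


@pytest.fixture(scope="session")
def cohort(sim_geometry, run_config):
    """Two-group cohort (control vs NPDR-like), measured end to end.

    Returns (measured DataFrame, truth DataFrame), one row per eye,
    aligned by image_id. Shared by the parameter-recovery and
    group-difference tests so the images are only measured once.
    """
    images = sim.generate_cohort(
        n_per_group=N_PER_GROUP, seed=COHORT_SEED, geometry=sim_geometry
    )
    measured_rows, truth_rows = [], []
    for img in images:
        rec = measure_map(img.segmap, run_config).to_dict()
        rec["image_id"] = img.image_id
        rec["group"] = img.group
        measured_rows.append(rec)
        truth_rows.append({"image_id": img.image_id, "group": img.group, **img.truth})
    measured = pd.DataFrame(measured_rows).set_index("image_id")
    truth = pd.DataFrame(truth_rows).set_index("image_id")
    return measured, truth
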