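"""Shared fixtures: a small two-network cohort exercised by several modules."""
import warnings

import numpy as np
import pytest

from roifc.core import BoldRun
from roifc.ica import concat_and_reduce, match_components
from roifc.preprocess import preprocess_run
from roifc.synthetic import (CohortConfig, NetworkTemplate, battery_nodes,
                             ellipsoid_mask, generate_cohort,
                             template_network_maps)

GRID = (40, 44, 40)
VOXEL = 2.0


def two_network_templates(within=0.8, blob=8.0):
    """Two 3-node networks with widely separated nodes on a 40x44x40 grid."""
    return [
        NetworkTemplate("A", ((24, 24, 24), (54, 24, 24), (24, 60, 54)),
                        within_corr=within, blob_fwhm_mm=blob),
        NetworkTemplate("B", ((54, 60, 24), (24, 24, 54), (54, 60, 54)),
                        within_corr=within, blob_fwhm_mm=blob),
    ]


@pytest.fixture(scope="session")
def small_mask():
    return ellipsoid_mask(GRID, VOXEL)


@pytest.fixture(scope="session")
def small_cohort():
    """Six mildly jittered subjects at voxel SNR 1 with known ground truth."""
    templates = two_network_templates()
    config = CohortConfig(n_subjects=6, grid_shape=GRID, jitter_sd_mm=3.0,
                          noise_sd=1.0, n_timepoints=80, seed=42, coupling={})
    runs, truth = generate_cohort(templates, config)
    return {"templates": templates, "config": config, "runs": runs,
            "truth": truth}


@pytest.fixture(scope="session")
def small_analysis(small_cohort, small_mask):
    """Preprocessed copy of the small cohort plus its group decomposition."""
    runs = [BoldRun(data=r.data.copy(), affine=r.affine, tr_s=r.tr_s,
                    subject_id=r.subject_id)
            for r in small_cohort["runs"]]
    for r in runs:
        r.data = preprocess_run(r, small_mask).data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cs = concat_and_reduce(runs, small_mask, n_components=6, seed=0)
    tmaps = template_network_maps(small_cohort["templates"], GRID, VOXEL)
    component_of = match_components(cs, tmaps)
    nodes = battery_nodes(small_cohort["templates"], search_radius_mm=14.0)
    return {"runs": runs, "cs": cs, "component_of": component_of,
            "nodes": nodes, "templates": small_cohort["templates"],
            "truth": small_cohort["truth"], "mask": small_mask}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
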