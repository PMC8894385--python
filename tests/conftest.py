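import numpy as np
import pytest
from scipy.spatial import cKDTree

from phenoswitch import imaging, synthetic


@pytest.fixture(scope="session")
def rendered_well():
    """One rendered 50-cell well (mixed phenotypes) with ground truth."""
    rng = np.random.default_rng(42)
    specs, truth = synthetic.sample_cell_specs(50, 0.5, 1600, rng)
    image, _ = synthetic.render_well(specs, 1600, seed=rng, check_overlap=False)
    return image, truth


@pytest.fixture(scope="session")
def measured_well(rendered_well):
    """Segmented + measured records of the rendered well, matched to truth
    by nearest centroid."""
    image, truth = rendered_well
    labels = imaging.segment_cells(image)
    records = imaging.classify_records(imaging.measure_shape(labels))
    tree = cKDTree(truth[["x", "y"]].to_numpy())
    dist, idx = tree.query(records[["x", "y"]].to_numpy())
    assert dist.max() < 5.0, "centroid matching failed"
    matched_truth = truth.iloc[idx].reset_index(drop=True)
    return records.reset_index(drop=True), matched_truth
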