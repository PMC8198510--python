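"""Shared fixtures: one coarse noiseless phantom drives most heavy tests."""

import numpy as np
import pytest

from prophase3d.identification import assign_karyotype
from prophase3d.morphometry import measure_all
from prophase3d.phantom import PhantomConfig, generate_phantom
from prophase3d.reference import load_reference
from prophase3d.segmentation import segment_stack

PHANTOM_SEED = 42


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def coarse_phantom(reference):
    """Noiseless 46,XY phantom on the coarse benchmark grid."""
    config = PhantomConfig.coarse(seed=PHANTOM_SEED)
    stack, truth_labels, truth = generate_phantom(config, reference)
    return {
        "config": config,
        "stack": stack,
        "truth_labels": truth_labels,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def segmented_labels(coarse_phantom):
    return segment_stack(coarse_phantom["stack"], band="medium")


@pytest.fixture(scope="session")
def morphometry(segmented_labels):
    return measure_all(segmented_labels)


@pytest.fixture(scope="session")
def assignment(morphometry, reference):
    return assign_karyotype(morphometry, reference)


@pytest.fixture(scope="session")
def truth_by_object(coarse_phantom, segmented_labels):
    """Map segmented object_id -> ground-truth row, via voxel overlap."""
    truth_labels = coarse_phantom["truth_labels"].data
    truth = coarse_phantom["truth"].set_index("object_id")
    mapping = {}
    for oid in segmented_labels.object_ids():
        sel = truth_labels[segmented_labels.data == oid]
        sel = sel[sel > 0]
        assert len(sel) > 0
        vals, counts = np.unique(sel, return_counts=True)
        mapping[int(oid)] = truth.loc[int(vals[np.argmax(counts)])]
    return mapping
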