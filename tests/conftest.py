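"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pandas as pd
import pytest

import rodmap
from rodmap.synthgen import GroundTruth


def make_truth(ages, lengths):
    """Hand-built population ground truth for controlled rendering."""
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(ages) + 1, dtype=int),
            "true_age": ages,
            "true_length_um": lengths,
            "is_leaky": np.zeros(len(ages), dtype=bool),
            "septal_present": np.zeros(len(ages), dtype=bool),
        }
    )
    pop = cells[["cell_id"]].copy()
    pop["length_um"] = lengths
    return pop, GroundTruth(cells=cells)


def render_single_cell(age, length_um, channel, seed=0, **kwargs):
    pop, truth = make_truth([age], [length_um])
    return rodmap.render_scene(
        pop, truth, [channel], seed=seed, field_shape=(160, 160), **kwargs
    )


@pytest.fixture(scope="session")
def noiseless_rod_scene():
    """40 well-separated noiseless rods with a uniform cytoplasmic channel."""
    channel = rodmap.ChannelModel(
        name="cyto", kind="cytoplasmic", noise_sd=0.0, cell_cv=0.0, background=0.0
    )
    return rodmap.make_scene(40, [channel], seed=7, phase_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_cells(noiseless_rod_scene):
    scene = noiseless_rod_scene
    return rodmap.from_labels(
        scene.truth.labels, scene.pixel_size, phase_image=scene.images["phase"]
    )
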