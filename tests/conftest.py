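import numpy as np
import pytest

from tandemloop.extrusion_1d import ExtrusionParams
from tandemloop.locus_model import LocusModel
from tandemloop.polymer_3d import Schedule, simulate_ensemble


def uniform_locus(n_bins: int, bin_bp: int = 600) -> LocusModel:
    """Barrier-free locus with uniform loading."""
    return LocusModel(
        n_bins=n_bins, bin_bp=bin_bp,
        forward_stall=np.zeros(n_bins), reverse_stall=np.zeros(n_bins),
        loading_prob=np.full(n_bins, 1.0 / n_bins),
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """Short equilibrium run of a 60-monomer barrier-free fiber."""
    locus = uniform_locus(60)
    schedule = Schedule.reduced(n_1d_anneal=500, n_3d_anneal_blocks=100,
                                steps_per_block=25, n_sample_blocks=400)
    return simulate_ensemble(locus, ExtrusionParams(200, 30, seed=0),
                             schedule, seed=0)
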