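import numpy as np
import pytest

from afmhmm.twin_experiment import TwinConfig, run_twin_experiment

#: Reduced-scale twin-experiment study conditions shared by the
#: acceptance-style end-to-end tests (computed once per session).
TWIN_CONFIG = TwinConfig(n_sets=5, n_frames=20, n_structures=10,
                         n_orientations=60, seed=1)
#: Larger dataset for the MSM-reconstruction radius scan, where the
#: relative-entropy ordering needs more frames per movie to resolve.
SCAN_CONFIG = TwinConfig(n_sets=6, n_frames=40, n_structures=10,
                         n_orientations=60, seed=1)
SCAN_RADII = (1.5, 2.0, 2.5, 3.2, 3.5)


@pytest.fixture(scope="session")
def twin_report():
    """Reduced-scale twin experiment fitted at all scanned tip radii."""
    return run_twin_experiment(TWIN_CONFIG, radii=SCAN_RADII)


@pytest.fixture(scope="session")
def scan_report():
    """Radius scan on the larger dataset (Baum-Welch MSM reconstruction)."""
    return run_twin_experiment(SCAN_CONFIG, radii=SCAN_RADII,
                               methods=("hmm_baumwelch",))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
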