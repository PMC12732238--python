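import numpy as np
import pytest

from pepscreen import synthetic_data as sd
from pepscreen import tcr_motif as tm

#: scaled-down suite so the whole test run stays fast
SMALL_SUITE_KWARGS = dict(depths=(600, 400, 1500, 1400), n_planted=10, n_duplicates=5)

#: truth anchor sets pinned into the motif config, so screening constraints
#: match the generator's rules exactly
PINNED_CONFIG = tm.MotifConfig(
    anchor_allowed={
        9: {2: frozenset("RK"), 7: frozenset("LIVM"), 9: frozenset("LIVM")},
        8: {2: frozenset("RK"), 8: frozenset("LIVMR")},
    }
)


@pytest.fixture(scope="session")
def suite():
    return sd.generate_peptidome_suite(
        sd.SimulationConfig(seed=20240917, **SMALL_SUITE_KWARGS)
    )


@pytest.fixture(scope="session")
def truth_motif():
    """Motif built from library panels of both lengths, anchors pinned to truth."""
    rng = np.random.default_rng(11)
    panel9 = sd.generate_ligand_panel("VRSRRCLRL", "library", rng, n_library=150)
    panel8 = sd.generate_ligand_panel("RRLPCRKR", "library", rng, n_library=150)
    panel = tm.LigandPanel(peptides=panel9.peptides + panel8.peptides)
    return tm.build_motif(panel, config=PINNED_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
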