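import numpy as np
import pytest

from idpkit.structure_io import Trajectory, abeta_sequences
from idpkit.synthetic import (
    EnsembleSpec,
    build_beta_sheet,
    build_peptide,
    build_phenanthroline,
    compose_ensemble,
)

AB16 = abeta_sequences()["abeta16"]
AB42 = abeta_sequences()["abeta42"]

# classic right-handed α-helix dihedrals (tight i+4→i hydrogen bonds); the
# (−60, −40) basin-centre template is exercised separately
ALPHA_CLASSIC = (-57.8, -47.0)


@pytest.fixture(scope="session")
def ab16_helix():
    """Aβ16 built as an ideal α-helix at the basin centre (−60, −40)."""
    return build_peptide(AB16, "alpha")


@pytest.fixture(scope="session")
def ab16_helix_classic():
    """Aβ16 at classic α-helix dihedrals (−57.8, −47)."""
    return build_peptide(AB16, [ALPHA_CLASSIC] * len(AB16))


@pytest.fixture(scope="session")
def ab16_extended():
    return build_peptide(AB16, "extended")


@pytest.fixture(scope="session")
def ab16_three_ten():
    return build_peptide(AB16, "three_ten")


@pytest.fixture(scope="session")
def phen():
    return build_phenanthroline()


@pytest.fixture(scope="session")
def phen_pt():
    return build_phenanthroline(include_platinum=True)


@pytest.fixture(scope="session")
def antiparallel_sheet():
    return build_beta_sheet("VTVTVT", "antiparallel")


@pytest.fixture(scope="session")
def parallel_sheet():
    return build_beta_sheet("VTVTVT", "parallel")


@pytest.fixture(scope="session")
def helix_coil_ensemble():
    """Noise-free 60-frame 40/60 α/coil ensemble of Aβ16 (seeded)."""
    spec = EnsembleSpec(sequence=AB16, n_frames=60,
                        class_fractions={"alpha": 0.4, "coil": 0.6},
                        noise_sigma=0.0, seed=7)
    return compose_ensemble(spec)


def single_frame_traj(top, frame) -> Trajectory:
    return Trajectory(top, [frame])
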