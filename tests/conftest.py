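import numpy as np
import pytest

from tomseek import sequence_io as sio
from tomseek import synthetic_data as sd


@pytest.fixture(scope="session")
def class_table():
    return sio.ResidueClassTable()


@pytest.fixture(scope="session")
def barrel_family():
    """12 mutated copies of the beta-barrel template (equal length)."""
    spec = sd.ProteomeSpec(
        families=(sd.FamilySpec("FAM", "barrel", 12, 0.08),), n_decoys=0
    )
    records, _ = sd.gen_proteome(spec, 999)
    return records


@pytest.fixture(scope="session")
def barrel_hmm(barrel_family):
    from tomseek import profile_hmm as ph

    return ph.build_hmm(sio.alignment_from_records(barrel_family))


@pytest.fixture(scope="session")
def barrel_calibration(barrel_hmm):
    from tomseek import profile_hmm as ph

    return ph.calibrate_evalue(barrel_hmm, 100, 120, seed=1)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(
        sio.AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)
    )
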