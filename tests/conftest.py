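import numpy as np
import pytest
from hypothesis import settings

from phosphopipe import mq_io
from phosphopipe.mq_io import PHOSPHO_MOD, PeptideRecord

settings.register_profile("fixed", derandomize=True, max_examples=50)
settings.load_profile("fixed")


def make_record(
    pid,
    seq,
    mods=(),
    intensities=None,
    protein="P1",
    reverse=False,
    contaminant=False,
    loc=0.9,
):
    """Terse PeptideRecord builder for fixtures."""
    mods = tuple(mods)
    return PeptideRecord(
        peptide_id=pid,
        sequence=seq,
        modifications=mods,
        n_phospho=sum(1 for n, _ in mods if "Phospho" in n),
        proteins=(protein,),
        leading_protein=protein,
        localization_score=loc,
        is_reverse=reverse,
        is_contaminant=contaminant,
        intensities=dict(intensities or {}),
    )


def phospho(pos):
    return (PHOSPHO_MOD, pos)


@pytest.fixture
def design_1strain():
    """One strain, drug/mock x 3 replicates (6 runs)."""
    return mq_io.make_design(strains=("wt_as",))


@pytest.fixture
def design_2strain():
    return mq_io.make_design(strains=("wt_as", "pka_as"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
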