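import numpy as np
import pytest
from hypothesis import settings

from ppmr.records import PredatorRecord, PreyRecord

# deterministic hypothesis runs
settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_predator(pid="p1", species="sp1", family="fam1", order="ord1",
                  region="reg1", subregion="reg1_sub1", mass=1000.0,
                  length=None, prey=None):
    return PredatorRecord(
        predator_id=pid, species=species, family=family, order=order,
        region=region, subregion=subregion, body_mass=mass,
        body_length=length, prey=prey or [],
    )


def make_prey(taxon="fish_t", stage="adult", masses=(1.0,), group="fish",
              pct=90.0, count=None, total=None, lengths=()):
    return PreyRecord(
        prey_taxon=taxon, life_stage=stage,
        count=count, total_mass=total,
        individual_masses=list(masses), individual_lengths=list(lengths),
        pct_intact=pct, prey_group=group,
    )


@pytest.fixture
def simple_predator():
    """The introductory worked example: 1 kg predator, two 25 g fish and
    two 0.1 g krill."""
    return make_predator(prey=[
        make_prey(masses=[25.0, 25.0], group="fish"),
        make_prey(taxon="krill", masses=[0.1, 0.1], group="other_invert"),
    ])
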