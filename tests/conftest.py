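import numpy as np
import pytest

from pmekit import (DomainHit, DomainLabel, ExpressionEvidence, ProteinRecord,
                    TopologyAnnotation)
from pmekit.synthetic import FamilySimSpec, MotifPlan, simulate_family


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20131074)


@pytest.fixture
def type1_record():
    """A Type-1 style record: PMEI domain, linker with one canonical site,
    PME domain."""
    seq = ("M" + "A" * 29            # leader
           + "G" * 150               # PMEI-like region (31-180)
           + "GGGGG" + "RKLL" + "GGGGG"  # linker with site at 186
           + "P" * 300)              # PME-like region (195-494)
    return ProteinRecord(
        "t1", seq,
        domains=[DomainHit(DomainLabel.PMEI, 31, 180, 1e-10),
                 DomainHit(DomainLabel.PME, 195, 494, 1e-20)],
        topology=TopologyAnnotation(True, 24),
        evidence=ExpressionEvidence(frozenset({"QPCR"})),
    )


@pytest.fixture(scope="session")
def small_family():
    """Deterministic synthetic family with explicit motif plans."""
    plans = (
        MotifPlan("two_site", separation=14, tetrapeptides=("RKLL", "RRLL")),
        MotifPlan("two_site", separation=33, tetrapeptides=("RRLL", "RRLL")),
        MotifPlan("one_site", tetrapeptides=("RKLR",)),
        MotifPlan("novel", tetrapeptides=("GRLL",)),
        MotifPlan("none"),
    )
    spec = FamilySimSpec(n_type1=5, n_type2=3, n_pmei=4, motif_plan=plans,
                         panel_conservation=1.0, sp_prob=0.5, seed=7)
    return spec, simulate_family(spec)
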