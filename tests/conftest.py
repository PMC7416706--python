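import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from repkit import ClonotypeRecord, SimulationParams, build_repertoire, simulate_repertoire


def rec(nt="TGTGCCAGC", aa="CAS", v="TRBV19", j="TRBJ2-1", count=1, **kw):
    return ClonotypeRecord(cdr3_nt=nt, cdr3_aa=aa, v_gene=v, j_gene=j, count=count, **kw)


@pytest.fixture
def small_rep():
    """Four clones, counts 50/30/15/5, distinct nt+vj keys."""
    records = [
        rec(nt="TGTGCCAGCAGT", aa="CASS", v="TRBV19", j="TRBJ2-1", count=50),
        rec(nt="TGTGCCAGCTTT", aa="CASF", v="TRBV27", j="TRBJ2-1", count=30),
        rec(nt="TGTGCCAGCGGG", aa="CASG", v="TRBV19", j="TRBJ1-1", count=15),
        rec(nt="TGTGCCAGCCCC", aa="CASP", v="TRBV13", j="TRBJ2-5", count=5),
    ]
    return build_repertoire(records, "nt+vj", sample_id="small")


@pytest.fixture
def sim_rep():
    params = SimulationParams(n_clones=100, depth=5000, alpha=1.0, seed=11)
    return simulate_repertoire(params, "sim_rep")


def make_sim(seed, n_clones=80, depth=3000, sample_id=None, **kw):
    params = SimulationParams(n_clones=n_clones, depth=depth, seed=seed, **kw)
    return simulate_repertoire(params, sample_id or f"s{seed}")
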