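import numpy as np
import pytest

from mccu import (
    ContactModel,
    ReferenceIndex,
    build_fixture,
    deduplicate_junctions,
    merge_read_pairs,
    render_sequencing_library,
    simulate_ligation_events,
    split_and_map_subreads,
)
from mccu.junctions import LigationJunction, call_junctions_for_reads


@pytest.fixture(scope="session")
def fixture12k():
    """12-kb reference with two NDRs and a CTCF site, fixed phase."""
    return build_fixture(
        12000,
        repeat_length=190,
        ndrs=[(4000, 4300), (7000, 7300)],
        ctcf_sites=[(9500, "+")],
        seed=11,
    )


@pytest.fixture(scope="session")
def default_model():
    return ContactModel()


@pytest.fixture(scope="session")
def library10k(fixture12k, default_model):
    """Error-free 10,000-molecule library rendered to read pairs + truth."""
    mols = simulate_ligation_events(fixture12k, default_model, 10000, seed=21)
    r1, r2, truth = render_sequencing_library(mols, seed=22)
    return mols, r1, r2, truth


@pytest.fixture(scope="session")
def called_junctions(fixture12k, library10k):
    """Unique junctions called by the full pipeline on the 10k library."""
    _, r1, r2, _ = library10k
    merged, _ = merge_read_pairs(r1, r2)
    index = ReferenceIndex(fixture12k.sequence, chrom=fixture12k.chrom)
    by_read = {}
    for m in merged:
        subs = split_and_map_subreads(m, index)
        if subs:
            by_read[m.id] = subs
    return deduplicate_junctions(call_junctions_for_reads(by_read))


def truth_junctions_as_objects(molecules, chrom):
    out = []
    for m in molecules:
        for j in m.junctions:
            out.append(
                LigationJunction(
                    chrom, j.pos_a, j.pos_b, j.dir_a, j.dir_b, m.fragment_ends, str(m.id)
                )
            )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
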