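import numpy as np
import pytest

import pseudosanger as P


@pytest.fixture(scope="session")
def small_ref():
    """10 kb diploid reference with default heterozygosity."""
    return P.make_diploid_reference(10_000, 0.001, seed=101)


@pytest.fixture(scope="session")
def nested_libraries(small_ref):
    """Four nested libraries (600/400/300/200 bp inserts, 15x each) on the
    10 kb reference — the standard study conditions scaled down."""
    libs = []
    for i, mean in enumerate((600, 400, 300, 200)):
        spec = P.LibrarySpec(insert_mean=mean, depth=15)
        libs.append(P.generate_library(small_ref, spec, P.derive_seed(5, i)))
    return libs


@pytest.fixture(scope="session")
def sr_pool(nested_libraries):
    return P.SRPool(nested_libraries[1:], [1, 2, 3])


@pytest.fixture(scope="session")
def sr_index(sr_pool):
    params = P.OverlapParams()
    return P.SpacedSeedIndex(sr_pool.reads, params.seed_pattern,
                             params.sr_stride)


@pytest.fixture(scope="session")
def pipeline_run(nested_libraries):
    """One full pipeline run on the 10 kb conditions, reused across tests."""
    config = P.RunConfig(libraries=nested_libraries, seed=5)
    return P.run_pipeline(config)


def truth_fragment(reference, record):
    """True fragment sequence oriented to the pair's read1 strand."""
    hap = reference.hap_a if record.haplotype == "a" else reference.hap_b
    frag = hap[record.fragment_start:record.fragment_end]
    if record.strand == "-":
        from pseudosanger.seqs import revcomp
        frag = revcomp(frag)
    return frag
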