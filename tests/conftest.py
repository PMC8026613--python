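import pytest

import canvasnet as cn


@pytest.fixture(scope="session")
def study():
    """The default synthetic two-condition study (seed 7)."""
    return cn.generate_fixture(seed=7)


@pytest.fixture(scope="session")
def network(study):
    return cn.build_merged_network(study.calls_a, study.calls_b, study.fragment_map)


@pytest.fixture(scope="session")
def bundle_dir(study, tmp_path_factory):
    """The default study written out as a file bundle."""
    out = tmp_path_factory.mktemp("bundle")
    study.write(out)
    return out


@pytest.fixture
def small_map():
    """A 2-chromosome fragment map with 4 kb fragments."""
    from canvasnet.genome_io import FragmentMap, GenomicInterval

    records = []
    for chrom in ("chr1", "chr2"):
        for i in range(25):
            records.append(
                (
                    f"{chrom}:{i * 4000}-{(i + 1) * 4000}",
                    GenomicInterval(chrom, i * 4000, (i + 1) * 4000),
                )
            )
    return FragmentMap(records)
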