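import pytest

from ewemap.genome import ChromosomeModel, GeneModel, GenomeModel, MarkerLocus


@pytest.fixture
def small_genome() -> GenomeModel:
    """One 2 Mb / 10 cM chromosome with two markers and two genes."""
    chrom = ChromosomeModel(
        "chr1",
        2_000_000,
        10.0,
        markers=[
            MarkerLocus("MK-A", 500_000, 2.5),
            MarkerLocus("MK-B", 1_500_000, 7.5),
        ],
        genes=[
            GeneModel("G1", "chr1", "+", ((100_000, 100_899),)),
            GeneModel("G2", "chr1", "-", ((1_200_000, 1_200_599), (1_201_000, 1_201_299))),
        ],
    )
    return GenomeModel([chrom])


@pytest.fixture
def tiny_flat_genome() -> GenomeModel:
    """A 1 Mb chromosome with zero genetic length (no recombination)."""
    return GenomeModel(
        [
            ChromosomeModel(
                "chrZ",
                1_000_000,
                0.0,
                genes=[GeneModel("GZ", "chrZ", "+", ((1_000, 1_899),))],
            )
        ]
    )
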