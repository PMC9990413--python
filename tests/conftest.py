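import numpy as np
import pytest

from dolphin.alignment_io import AlignedSequence, DomainAlignment, TaxonomyMap
from dolphin.background import BackgroundFrequencies, swissprot_background
from dolphin.alphabet import AMINO_ACIDS


@pytest.fixture(scope="session")
def bg() -> BackgroundFrequencies:
    return swissprot_background()


@pytest.fixture(scope="session")
def uniform_bg() -> BackgroundFrequencies:
    return BackgroundFrequencies({aa: 0.05 for aa in AMINO_ACIDS}, source="uniform")


@pytest.fixture
def toy_alignment() -> DomainAlignment:
    """4 x 6 alignment mixing residues, gaps and an ambiguity code."""
    return DomainAlignment(
        domain_id="TOY",
        sequences=(
            AlignedSequence("s1", "ACDE-F", taxon_group="eukaryota"),
            AlignedSequence("s2", "ACDEYF", taxon_group="eukaryota"),
            AlignedSequence("s3", "AC-EXF", taxon_group="bacteria"),
            AlignedSequence("s4", "AADE-F", taxon_group="eukaryota"),
        ),
    )


@pytest.fixture
def toy_taxonomy(toy_alignment) -> TaxonomyMap:
    return TaxonomyMap(
        {s.sequence_id: s.taxon_group for s in toy_alignment.sequences}
    )


def random_alignment(rng: np.random.Generator, n: int = 5, length: int = 8,
                     gap_rate: float = 0.15) -> DomainAlignment:
    """Small random alignment over the full alphabet with gaps."""
    letters = list(AMINO_ACIDS)
    rows = []
    for i in range(n):
        chars = [
            "-" if rng.random() < gap_rate else letters[int(rng.integers(20))]
            for _ in range(length)
        ]
        rows.append(AlignedSequence(f"r{i}", "".join(chars)))
    return DomainAlignment(domain_id="RND", sequences=tuple(rows))
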