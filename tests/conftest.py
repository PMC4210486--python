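import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alienscan.sequence_io import FamilyDataset, GeneRecord

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_family(seqs, family="fam", prefix="g"):
    """Build a FamilyDataset from raw sequences with sequential ids."""
    return FamilyDataset(
        family=family,
        genes=[GeneRecord(f"{prefix}{i}", family, s) for i, s in enumerate(seqs, 1)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_family():
    """Five short in-frame genes, all encodable under every feature set."""
    return make_family(
        [
            "ATGAAACCCGGGTTTTAA",
            "ATGCCCGGGAAATTTTGA",
            "ATGTTTAAACCCGGGTAG",
            "ATGGGGTTTAAACCCTAA",
            "ATGAAATTTGGGCCCTGA",
        ]
    )


def random_cds(rng, n_codons=60):
    """A random in-frame CDS without internal stops."""
    from alienscan.synthetic_data import SENSE_CODONS

    body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"
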