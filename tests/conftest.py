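import numpy as np
import pytest

from tcrnodseek.io import ClonotypeRecord, Repertoire, SubjectMetadata

AA = "ACDEFGHIKLMNPQRSTVWY"


def encode_seq(i: int, length: int = 8) -> str:
    """Deterministic unique CDR3-like sequence for clone index i."""
    out = []
    for _ in range(length):
        out.append(AA[i % 20])
        i //= 20
    return "".join(out)


def repertoire_from_counts(counts, subject_id="S", offset=0) -> Repertoire:
    records = [
        ClonotypeRecord(cdr3_aa=encode_seq(i + offset), count=int(c))
        for i, c in enumerate(counts)
    ]
    return Repertoire.from_records(subject_id, records)


@pytest.fixture
def make_repertoire():
    return repertoire_from_counts


@pytest.fixture
def toy_cohort():
    """Three-subject toy with hand-enumerated sharing structure.

    Sequences present in >= 2 subjects: CASSA (S1,S2), CASSC (S1,S3),
    CASSD (S1,S2), CASSH (S2,S3) — exactly four.
    """
    s1 = Repertoire.from_records(
        "S1",
        [
            ClonotypeRecord("CASSA", 10),
            ClonotypeRecord("CASSC", 5),
            ClonotypeRecord("CASSD", 2),
            ClonotypeRecord("CASSE", 1),
        ],
    )
    s2 = Repertoire.from_records(
        "S2",
        [
            ClonotypeRecord("CASSA", 8),
            ClonotypeRecord("CASSD", 4),
            ClonotypeRecord("CASSF", 3),
            ClonotypeRecord("CASSH", 2),
        ],
    )
    s3 = Repertoire.from_records(
        "S3",
        [
            ClonotypeRecord("CASSC", 6),
            ClonotypeRecord("CASSH", 3),
            ClonotypeRecord("CASSG", 1),
        ],
    )
    metadata = [
        SubjectMetadata("S1", "malignant", stage="I"),
        SubjectMetadata("S2", "malignant", stage="I"),
        SubjectMetadata("S3", "benign"),
    ]
    return [s1, s2, s3], metadata


@pytest.fixture
def random_repertoire_factory():
    def _factory(rng: np.random.Generator, n_clones: int, max_count: int = 1000):
        counts = rng.integers(1, max_count + 1, size=n_clones)
        return repertoire_from_counts(counts, subject_id=f"R{n_clones}")

    return _factory
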