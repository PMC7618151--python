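import numpy as np
import pytest

from xovermap.infopairs import InformativePair, SnpObservation, with_likelihoods


def build_pair(
    chrom="chr1",
    left=100,
    right=1100,
    status="N",
    b1=0.0,
    p1=0.0,
    b2=0.0,
    p2=0.0,
):
    """One informative pair with explicit coordinates/status/errors."""
    lobs = SnpObservation(pos=left, read_base="A", base_err=b1, phase_err=p1, hap_match=1)
    robs = SnpObservation(
        pos=right, read_base="G", base_err=b2, phase_err=p2,
        hap_match=2 if status == "C" else 1,
    )
    return with_likelihoods(
        InformativePair(chrom=chrom, left=lobs, right=robs, status=status)
    )


@pytest.fixture
def pair_factory():
    return build_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pairs(rng, n=40, chrom_len=10_000, p_c=0.3, chrom="chr1"):
    """Random small pair set on a toy chromosome (for oracle tests)."""
    pairs = []
    for _ in range(n):
        left = int(rng.integers(1, chrom_len - 10))
        right = int(rng.integers(left + 1, chrom_len))
        status = "C" if rng.uniform() < p_c else "N"
        pairs.append(build_pair(chrom=chrom, left=left, right=right, status=status))
    return pairs
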