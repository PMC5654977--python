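import numpy as np
import pandas as pd
import pytest

from epiclone.caller import ALLELES, CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_count_matrix(samples, positions, depth_per_strand=300, alt_reads=None):
    """Hand-built CountMatrix: clean reference reads everywhere, plus
    explicit alternate reads given as {(sample, pos_index, allele): (fwd, rev)}.
    ``positions`` is a list of (chrom, pos, ref); depth may be a scalar or a
    {(sample, pos_index): depth_per_strand} override."""
    pos_df = pd.DataFrame(positions, columns=["chrom", "pos", "ref"])
    S, P = len(samples), len(pos_df)
    counts = np.zeros((S, P, len(ALLELES), 2), np.int64)
    coverage = np.zeros((S, P, 2), np.int64)
    for si in range(S):
        for pi in range(P):
            if isinstance(depth_per_strand, dict):
                d = depth_per_strand.get((samples[si], pi), 300)
            else:
                d = depth_per_strand
            coverage[si, pi, :] = d
            counts[si, pi, ALLELES.index(pos_df["ref"][pi]), :] = d
    for (sample, pi, allele), (fwd, rev) in (alt_reads or {}).items():
        si = samples.index(sample)
        k = ALLELES.index(allele)
        ref_k = ALLELES.index(pos_df["ref"][pi])
        counts[si, pi, k, 0] += fwd
        counts[si, pi, k, 1] += rev
        counts[si, pi, ref_k, 0] -= fwd
        counts[si, pi, ref_k, 1] -= rev
    return CountMatrix(samples=list(samples), positions=pos_df,
                       counts=counts, coverage=coverage)


@pytest.fixture
def toy_positions():
    return [("chr1", 100, "A"), ("chr1", 103, "A"), ("chr1", 250, "C"),
            ("chr1", 400, "G"), ("chr2", 50, "T")]
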