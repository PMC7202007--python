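import numpy as np
import pytest

from sweeplab.vcfio import GenotypeMatrix


def make_gm(gt, dp=None, pos=None, contig=None, ref=None, alt=None,
            n_lines=2):
    """Toy GenotypeMatrix builder: gt is (n_sites, n_ind) with -1 missing;
    individuals are split evenly between lines 'GA' and 'GA-R'."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    half = n_ind // 2
    samples = [f"GA_{i+1}" for i in range(half)] + \
              [f"GA-R_{i+1}" for i in range(n_ind - half)]
    line_of = {s: ("GA" if s.startswith("GA_") else "GA-R") for s in samples}
    if n_lines == 1:
        line_of = {s: "GA" for s in samples}
    return GenotypeMatrix(
        contig=np.asarray(contig if contig is not None
                          else ["chr1"] * n_sites, dtype=object),
        pos=np.asarray(pos if pos is not None
                       else np.arange(1, n_sites + 1) * 100, dtype=np.int64),
        ref=ref or ["A"] * n_sites,
        alt=alt or [["T"]] * n_sites,
        gt=gt,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        samples=samples,
        line_of=line_of,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gm(rng):
    """5 + 5 diploids at 200 biallelic sites with HWE genotypes."""
    n_sites, n_ind = 200, 10
    p = rng.uniform(0.1, 0.9, size=n_sites)
    hap = rng.random((n_sites, n_ind, 2)) < p[:, None, None]
    gt = hap.sum(axis=2).astype(np.int8)
    return make_gm(gt)
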