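import numpy as np
import pytest

from synpss import ProteinChain, SynonymDictionary, WordRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def wgpv_dictionary():
    """A one-word dictionary holding the canonical WGPV entry: three
    sources with structures HHHH/HHCH/CHHH, levels 3/4/2, frequencies
    7/11/3."""
    records = [
        WordRecord("WGPV", "A", "HHHH", 3, 7, (2,)),
        WordRecord("WGPV", "B", "HHCH", 4, 11, (5,)),
        WordRecord("WGPV", "C", "CHHH", 2, 3, (1,)),
    ]
    return SynonymDictionary(4, {"WGPV": records}, {"pool": "worked-example"})


def random_chain(rng, length, cid="p", with_ss=True):
    from synpss.simulate import HomologSimConfig, sample_sequence, sample_ss3

    cfg = HomologSimConfig(seed=0)
    ss3 = sample_ss3(length, cfg, rng)
    seq = sample_sequence(ss3, rng)
    return ProteinChain(cid, seq, ss3 if with_ss else None)


def random_dictionary(rng, n_words, n, max_sources=3):
    """A dictionary of random words with random per-source records."""
    from synpss.matrices import STANDARD_AA

    aa = np.array(list(STANDARD_AA))
    entries = {}
    while len(entries) < n_words:
        word = "".join(aa[rng.integers(0, 20, size=n)])
        if word in entries:
            continue
        recs = []
        for s in range(int(rng.integers(1, max_sources + 1))):
            ss = "".join(np.array(list("HEC"))[rng.integers(0, 3, size=n)])
            recs.append(
                WordRecord(
                    word,
                    f"S{rng.integers(0, 50)}_{s}",
                    ss,
                    int(rng.integers(0, n + 1)),
                    int(rng.integers(1, 20)),
                    tuple(sorted(set(map(int, rng.integers(1, 200, size=2))))),
                )
            )
        entries[word] = recs
    return SynonymDictionary(n, entries, {"pool": "random"})
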