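import pytest

from socascreen import GeneEntry, GeneSet, enumerate_arrays, synthetic_library


def make_entries(n_kinase, n_metabolism, n_controls):
    """Small deterministic gene panels with hand-built valid spacers."""
    # 20-nt spacers, unique per index via a base-4 prefix, GC inside 30-70%
    def spacer(i):
        head = "".join("ACGT"[d] for d in ((i // 16) % 4, (i // 4) % 4, i % 4))
        return head + "ACGTACGTACGTACGTA"

    k = [
        GeneEntry(f"K{i}", GeneSet.KINASE, spacer(i), "TTTA")
        for i in range(n_kinase)
    ]
    m = [
        GeneEntry(f"M{i}", GeneSet.METABOLISM, spacer(10 + i), "TTTC")
        for i in range(n_metabolism)
    ]
    c = [GeneEntry(f"N{i}", GeneSet.CONTROL, spacer(20 + i)) for i in range(n_controls)]
    return k, m, c


@pytest.fixture(scope="session")
def small_library():
    """2 kinase x 3 metabolism x 2 controls -> 6 DKO + 10 SKO + 4 NTC arrays."""
    k, m, c = make_entries(2, 3, 2)
    return enumerate_arrays(k, m, c)


@pytest.fixture(scope="session")
def study_library():
    """The 340-array study design."""
    return synthetic_library(seed=0)
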