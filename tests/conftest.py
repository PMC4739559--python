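import numpy as np
import pytest

from phylodem.io import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_alignment(rng, n, L, alphabet="ACGT"):
    """Random (unstructured) alignment for oracle comparisons."""
    bases = np.array(list(alphabet), dtype="U1")
    mat = rng.choice(bases, size=(n, L))
    return Alignment(
        ids=tuple(f"s{i}" for i in range(n)),
        seqs=tuple("".join(row) for row in mat),
    )


def alignment_from_seqs(*seqs):
    return Alignment(ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=tuple(seqs))


def two_haplotype_alignment(n_major, n_minor, L=1140, steps=1):
    """n_major copies of a reference plus n_minor copies differing at
    `steps` sites - the configuration forced by published count tables."""
    ref = "A" * L
    minor = "T" * steps + "A" * (L - steps)
    seqs = [ref] * n_major + [minor] * n_minor
    return Alignment(
        ids=tuple(f"s{i}" for i in range(n_major + n_minor)), seqs=tuple(seqs)
    )
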