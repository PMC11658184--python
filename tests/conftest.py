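import numpy as np
import pytest

from trnacharge.reference import ReferenceSet, write_annotation, write_fasta
from trnacharge.simulate import (
    make_canonical_gene,
    make_spike_in,
    make_t_element,
    random_reference_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def canonical76(rng):
    """A 76-nt canonical tRNA with consecutive Sprinzl labels 1..76."""
    return make_canonical_gene("nuc-tRNA-Ala-001", rng, amino_acid="Ala",
                               anticodon="AGC")


@pytest.fixture
def small_refset(rng):
    """Five canonical genes + a t-element + a spike-in."""
    genes = [
        make_canonical_gene("nuc-tRNA-Ala-001", rng, amino_acid="Ala", anticodon="AGC"),
        make_canonical_gene("nuc-tRNA-Ala-002", rng, amino_acid="Ala", anticodon="AGC"),
        make_canonical_gene("nuc-tRNA-Gly-001", rng, amino_acid="Gly", anticodon="GCC"),
        make_canonical_gene("pla-tRNA-Glu-001", rng, genome="plastid",
                            amino_acid="Glu", anticodon="TTC", d_loop_len=9),
        make_canonical_gene("mit-tRNA-Met-001", rng, genome="mitochondrial",
                            amino_acid="Met(e)", anticodon="CAT", variable_len=4),
        make_t_element("mit-tE-ccmC", rng),
        make_spike_in("spike-tRNA-Ile", rng),
    ]
    return ReferenceSet(genes)


@pytest.fixture
def refset_on_disk(tmp_path, small_refset):
    """The small reference set serialized to FASTA + annotation TSV."""
    fasta = tmp_path / "ref.fasta"
    ann = tmp_path / "ref.tsv"
    write_fasta(small_refset, fasta)
    write_annotation(small_refset, ann)
    return fasta, ann


@pytest.fixture
def pipeline_refset():
    return random_reference_set(8, 7, include_t_element=True, include_spike_in=True)
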