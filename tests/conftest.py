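import numpy as np
import pytest
from pyfaidx import Fasta

from mutsig96 import (
    SignatureCatalog,
    load_catalog,
    make_reference,
    packaged_catalog_path,
)


@pytest.fixture(scope="session")
def packaged_cat():
    return load_catalog(packaged_catalog_path())


@pytest.fixture(scope="session")
def reference_path(tmp_path_factory):
    """Small deterministic reference with every trinucleotide context."""
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    return make_reference(path, length=50_000, gc_bias=0.5, seed=11)


@pytest.fixture(scope="session")
def reference(reference_path):
    return Fasta(str(reference_path))


@pytest.fixture
def toy_catalog():
    """Two signatures with disjoint two-channel supports (toy geometry).

    S1 puts mass 0.5/0.5 on channels 0 and 1, S2 on channels 2 and 3.
    """
    M = np.zeros((96, 2))
    M[0, 0] = M[1, 0] = 0.5
    M[2, 1] = M[3, 1] = 0.5
    return SignatureCatalog(["S1", "S2"], M)


def write_vcf(path, rows, contig="chrS", length=50_000):
    """Minimal VCF 4.2 writer for fixtures; rows are (pos, ref, alt) or
    (pos, ref, alt, filter)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in rows:
            pos, ref, alt = row[:3]
            filt = row[3] if len(row) > 3 else "."
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\n")
    return path
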