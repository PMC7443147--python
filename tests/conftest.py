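import csv

import pytest

from screenforge.library import GuideRecord, LibraryReference, SampleRecord, SampleSheet


def kmer(i: int, length: int = 20) -> str:
    """Deterministic distinct DNA k-mer for an integer.

    Encodes ``i`` in base 4 over length//2 digits and repeats the block, so
    distinct indices yield spacers at Hamming distance >= 2 of each other.
    """
    bases = "ACGT"
    half = length // 2
    block = "".join(bases[(i >> (2 * j)) & 3] for j in range(half))
    return (block + block)[:length]


def make_library(n_genes: int = 3, guides_per_gene: int = 4) -> LibraryReference:
    guides = []
    i = 0
    for g in range(1, n_genes + 1):
        gene = f"GENE{g}"
        for j in range(1, guides_per_gene + 1):
            guides.append(GuideRecord(f"{gene}_sg{j}", gene, kmer(i)))
            i += 1
    return LibraryReference(guides)


@pytest.fixture
def tiny_lib() -> LibraryReference:
    return make_library(3, 4)


@pytest.fixture
def tiny_lib_csv(tmp_path, tiny_lib):
    path = tmp_path / "library.csv"
    tiny_lib.write(path)
    return path


@pytest.fixture
def two_sample_sheet() -> SampleSheet:
    return SampleSheet(
        [
            SampleRecord("S_ctrl", "ACGTACGT", "control", 1),
            SampleRecord("S_trt", "TGCATGCA", "treated", 1),
        ]
    )


def write_csv(path, header, rows):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return path
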