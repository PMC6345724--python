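import pytest

from tristack import (
    build_difference_matrix,
    build_trimer_matrix,
    load_dinucleotide_table,
)


@pytest.fixture(scope="session")
def table():
    return load_dinucleotide_table()


@pytest.fixture(scope="session")
def trimer_matrix(table):
    return build_trimer_matrix(table)


@pytest.fixture(scope="session")
def diff_matrix(trimer_matrix):
    return build_difference_matrix(trimer_matrix)


@pytest.fixture
def constant_table(tmp_path):
    """A custom table with every step at -1.0 kcal/mol."""
    path = tmp_path / "constant.tsv"
    path.write_text(
        "".join(f"{a}{b}\t-1.0\n" for a in "ACGT" for b in "ACGT")
    )
    return load_dinucleotide_table(override_path=path)
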