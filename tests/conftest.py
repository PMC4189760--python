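import pytest


@pytest.fixture
def write_fasta(tmp_path):
    """Write {name: sequence} to a FASTA file and return its path."""

    def _write(records, filename="reads.fasta"):
        path = tmp_path / filename
        with open(path, "w") as fh:
            for name, seq in records.items():
                fh.write(f">{name}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_text(tmp_path):
    def _write(content, filename):
        path = tmp_path / filename
        path.write_text(content)
        return path

    return _write
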