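import numpy as np
import pytest

from puf3regulon.io import SpeciesDataset
from puf3regulon.motif import compile_profile


@pytest.fixture(scope="session")
def default_profile():
    return compile_profile("TGTANATA")


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="seqs.fasta", wrap=None):
        path = tmp_path / name
        with open(path, "w") as fh:
            for gene, seq in records:
                fh.write(f">{gene}\n")
                if wrap:
                    for i in range(0, len(seq), wrap):
                        fh.write(seq[i : i + wrap] + "\n")
                else:
                    fh.write(seq + "\n")
        return path

    return _write


def random_sequences(gc, n, length, seed):
    """Independent i.i.d. sequence generator used as a test-side data source."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in bases[codes]]


@pytest.fixture
def make_dataset():
    def _make(seqs, species_id="sp1", label="clade", cds=None):
        downstream = {f"g{i:04d}": s for i, s in enumerate(seqs)}
        return SpeciesDataset(
            species_id=species_id, downstream=downstream, cds=cds or {}, label=label
        )

    return _make
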