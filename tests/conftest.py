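import pytest

from splicesurvey.genome_io import GenomeAssembly
from splicesurvey.synthetic_data import GeneratorConfig, generate_genome


@pytest.fixture
def toy_assembly():
    """One plus-strand two-exon gene: ATG | 20 bp GT..AG intron | GCC."""
    seq = "ATG" + "GTAAGTTTTTCTCTCTCTAG" + "GCC"
    return GenomeAssembly({"chr1": seq})


@pytest.fixture(scope="session")
def small_synthetic(tmp_path_factory):
    """A 150-gene synthetic genome shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("synth")
    config = GeneratorConfig(seed=11, n_genes=150)
    fasta, gff3, manifest = generate_genome(config, out)
    return {"fasta": fasta, "gff3": gff3, "manifest": manifest, "dir": out}


def write_fasta(path, sequences):
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n{seq}\n")
    return path


def spearman_oracle(x, y):
    """Rank (average ties) then Pearson — the brute-force Spearman."""
    import numpy as np
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
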