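import warnings

import pytest

from mitomarkers.pipeline import build_gene_alignments
from mitomarkers.simulate import default_model, simulate_clade_dataset, write_dataset

QUERIED_TAXA = ["Fagus", "Fagaceae", "Fagales"]


@pytest.fixture(scope="session")
def dataset():
    """The default 13-species synthetic study (fixed seed)."""
    return simulate_clade_dataset(default_model(seed=7))


@pytest.fixture(scope="session")
def dataset_dir(dataset, tmp_path_factory):
    """The same study written out as GenBank files + manifest."""
    out = tmp_path_factory.mktemp("clade")
    write_dataset(dataset, out)
    return out


@pytest.fixture(scope="session")
def alignments(dataset):
    """Per-gene alignments of the synthetic study's shared genes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_gene_alignments(dataset.genomes)
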