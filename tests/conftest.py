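import numpy as np
import pandas as pd
import pytest

from gzexit import PlantedAssociationConfig, generate_genome_and_peaks
from gzexit.peakgene import assign_peaks_to_genes


@pytest.fixture(scope="session")
def planted_instance():
    """A small planted genome/peak set with its assignments."""
    cfg = PlantedAssociationConfig(
        n_genes=200, n_target_genes=30, p_bind_target=0.8,
        p_bind_background=0.1, chrom_length_bp=10_000_000, seed=11,
    )
    genes, peaks, targets = generate_genome_and_peaks(cfg)
    assignments = assign_peaks_to_genes(peaks, genes)
    return genes, peaks, targets, assignments


@pytest.fixture()
def toy_genes():
    return pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB", "geneC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [1001, 5001, 2001],
            "strand": ["+", "-", "+"],
        }
    )


def make_peaks(summits, chrom="chr1", p_value=0.001):
    summits = np.asarray(summits)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": summits - 100,
            "end": summits + 101,
            "name": [f"p{i}" for i in range(len(summits))],
            "summit": summits,
            "p_value": p_value,
        }
    )
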