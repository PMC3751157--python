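import numpy as np
import pytest

from strexpert import SimParams, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def rules(panel):
    return panel.rules


@pytest.fixture
def clean_params():
    """Noiseless, artifact-free, jitter-free simulator settings."""
    return SimParams(
        seed=0,
        noise_sd_rfu=0.0,
        sizing_jitter_sd_bases=0.0,
        stutter_fraction=0.0,
        inta_fraction=0.0,
        baseline_offset_rfu=0.0,
        baseline_drift_rfu=0.0,
        bleed_matrix=np.eye(4),
    )


@pytest.fixture
def full_het_genotype(panel):
    """A fully heterozygous genotype: two distinct alleles at every locus."""
    alleles = {}
    for locus in panel.loci:
        labels = [lab for lab, _ in locus.ladder_alleles]
        alleles[locus.name] = (labels[0], labels[-1])
    return alleles
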