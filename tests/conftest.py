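import pytest

from gvoomics import synthetic_data as sd


@pytest.fixture(scope="session")
def annotation_bundle():
    """10 three-exon genes plus a planted shared-intron gene pair."""
    return sd.gen_annotation(10, exons_per_gene=(3, 3),
                             share_intron_pair=True, seed=42)


@pytest.fixture(scope="session")
def oocyte_plan():
    return sd.default_methylome_plan()


@pytest.fixture(scope="session")
def oocyte_samples(oocyte_plan):
    """Two WT + two Het clean oocyte methylomes at 10x."""
    samples, truth = sd.gen_methylomes(
        plan=oocyte_plan, n_per_genotype={"WT": 2, "Het": 2},
        coverage_mean=10.0, seed=7)
    return samples, truth
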