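import numpy as np
import pytest

from gdikit.core import Genotype
from gdikit.genotype_io import VariantSite, build_contig_registry
from gdikit.simulate import DemographicModel, contig_registry_for, simulate_genotypes


def make_site(contig="c1", pos=0, gts=(0, 0), qual=50.0, ref="A", alt="T", depths=None):
    return VariantSite(
        contig_id=contig,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        qual=qual,
        genotypes=tuple(int(g) for g in gts),
        depths=depths,
    )


@pytest.fixture
def small_registry():
    return build_contig_registry([("c1", 250_000), ("c2", 150_000), ("c3", 90_000)])


@pytest.fixture(scope="session")
def isolation_dataset():
    """One simulated 3-diploid isolation-model dataset with truth."""
    model = DemographicModel(
        n_a=2_000,
        n_b=2_000,
        n_anc=2_000,
        t_split=6_000,
        mu=1e-8,
        l_bp=250_000,
        n_contigs=8,
        samples=(2, 1),
        seed=11,
    )
    sites, truth = simulate_genotypes(model)
    return model, sites, truth


@pytest.fixture(scope="session")
def sim_vcf_dir(tmp_path_factory, isolation_dataset):
    """The isolation dataset written as VCF + .fai on disk."""
    from gdikit.simulate import write_vcf

    model, sites, _ = isolation_dataset
    d = tmp_path_factory.mktemp("simvcf")
    write_vcf(sites, model.roster, contig_registry_for(model), d / "sim.vcf", d / "sim.fai")
    return d, model


@pytest.fixture
def toy_tree_file(tmp_path):
    p = tmp_path / "toy.nwk"
    p.write_text("((A:1,B:2):1,C:3);\n")
    return p
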