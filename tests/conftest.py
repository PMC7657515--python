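import numpy as np
import pytest

import callstore as cs
from callstore.fixtures import FixtureSpec, generate_phenotypes, generate_vcf, preset
from callstore.popgen import DosageMatrix

# A two-marker, one-sample VCF shaped like the worked protocol example:
# multi-allelic first marker, verbatim-preservable header oddities.
EXAMPLE_VCF = "\n".join([
    "##fileformat = VCFv4.0",
    "##Tassel=<ID=GenotypeTable,Version=5>",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMP1",
    "2\t20032\tS2_20032\tC\tG,T\t99\tPASS\tAR2=0.29;DR2=0.342;AF=0.375\t"
    "GT:AD:DP:GQ\t0/0:9,0,0:9:99",
    "2\t20033\tS2_20033\tC\tG\t99\tPASS\tAR2=0.29;DR2=0.342;AF=0.375\t"
    "GT:AD:DP:GQ\t0/1:5,4:9:99",
]) + "\n"


@pytest.fixture
def example_vcf() -> str:
    return EXAMPLE_VCF


@pytest.fixture
def example_protocol():
    header, block = cs.read_vcf(EXAMPLE_VCF)
    protocol = cs.build_protocol(header, block, "p1", "2019_GT_MAP",
                                 reference_genome_name="ref_v1",
                                 species_name="Manihot esculenta")
    return protocol, block


def load_fixture_store(spec: FixtureSpec, with_phenotypes: bool = True,
                       with_pedigree: bool = False):
    """Generate a synthetic dataset and load it into a fresh store."""
    vcf_text, truth = generate_vcf(spec)
    header, block = cs.read_vcf(vcf_text)
    protocol = cs.build_protocol(header, block, "pending", "fixture_protocol")
    callsets = cs.transpose_to_sample_first(block, protocol)
    store = cs.GenotypeStore()
    pid = store.store_protocol(protocol)
    for s in block.sample_names:
        store.add_stock(s)
    store.store_callsets(pid, callsets)
    if with_phenotypes:
        dm = DosageMatrix.from_callsets(protocol, callsets, ploidy=spec.ploidy)
        for idx, trait in enumerate(("trait1", "trait2")):
            store.store_phenotypes(
                generate_phenotypes(spec, truth, dm, trait_name=trait,
                                    trait_index=idx))
    progeny = []
    if with_pedigree:
        from callstore.fixtures import generate_pedigree
        records, _ = generate_pedigree(spec, founders=block.sample_names)
        for rec in records:
            store.add_stock(rec.progeny)
        # use true (non-misspelled) parent names for linkage
        rng = np.random.default_rng([spec.seed, 104729])
        clean = []
        for i in range(spec.n_progeny):
            p1, p2 = rng.choice(len(block.sample_names), size=2, replace=False)
            clean.append(cs.PedigreeRecord(f"HYB{i + 1:03d}",
                                           block.sample_names[p1],
                                           block.sample_names[p2]))
        store.load_pedigree(clean)
        progeny = [r.progeny for r in clean]
    return {
        "store": store, "protocol_id": pid, "protocol": protocol,
        "block": block, "callsets": callsets, "truth": truth, "spec": spec,
        "vcf_text": vcf_text, "progeny": progeny,
    }


@pytest.fixture(scope="session")
def toy_store():
    return load_fixture_store(preset("toy", 7), with_phenotypes=True)


def sim_dosage(rng: np.random.Generator, n_samples: int, n_markers: int,
               ploidy: int = 2) -> DosageMatrix:
    """Independent-marker alternate-dosage matrix for model checks."""
    p = np.clip(rng.beta(0.8, 0.8, size=n_markers), 0.05, 0.95)
    vals = rng.binomial(ploidy, p[:, None], size=(n_markers, n_samples)).astype(float)
    return DosageMatrix(
        [f"M{i:04d}" for i in range(n_markers)],
        [f"ACC{j + 1:04d}" for j in range(n_samples)],
        vals, dosage_convention="alternate", ploidy=ploidy,
    )
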