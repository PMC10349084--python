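import pytest

from dlhscan import synthetic as syn
from dlhscan.classifier import build_domain_profile
from dlhscan.motifs import bank_from_consensus
from dlhscan.synthetic import GeneratorSpec


@pytest.fixture(scope="session")
def small_protein_sets():
    """20 positives + 50 decoys with full truth manifest."""
    spec = GeneratorSpec(seed=42, n_pos=20, n_neg=50, duplication_fraction=0.3)
    positives, decoys, manifest = syn.generate_protein_sets(spec)
    return spec, positives, decoys, manifest


@pytest.fixture(scope="session")
def domain_profile(small_protein_sets):
    spec = small_protein_sets[0]
    seed_aln = syn.generate_domain_seed_alignment(spec)
    calib = syn.generate_random_proteins(500, spec.sequence_length, seed=spec.seed + 1)
    return build_domain_profile(seed_aln, calib, fpr=0.01)


@pytest.fixture(scope="session")
def motif_bank(small_protein_sets):
    return bank_from_consensus(small_protein_sets[0].motif_set)


@pytest.fixture(scope="session")
def family_alignment():
    return syn.generate_family_alignment(n_leaves=8, seed=7)


@pytest.fixture(scope="session")
def abundance_dataset():
    spec = syn.AbundanceSpec(
        seed=5,
        n_stations=2,
        depths=(5, 40, 80, 300, 500, 800),
        genes_per_taxon=8,
        fold_changes={"Dinophyceae_g0": 8.0, "Dinophyceae_g1": 8.0},
    )
    return spec, *syn.generate_abundance_dataset(spec)
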