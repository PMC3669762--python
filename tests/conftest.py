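import numpy as np
import pytest

from matbin import binning, synthetic_data as sd


def make_records(seqs, prefix="s", **kwargs):
    """Quick ScaffoldRecord list from raw sequences."""
    from matbin.seqio import ScaffoldRecord

    return [
        ScaffoldRecord(id=f"{prefix}{i}", sequence=seq, **kwargs)
        for i, seq in enumerate(seqs)
    ]


def random_dna(n, seed=0, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def three_population_community():
    """3 planted compositional populations (G+C 35/50/65%, order-2 bias),
    60 scaffolds each, lognormal lengths (median 15 kb)."""
    models = [
        (sd.sample_genome_model(g, markov_order=2, bias_strength=0.5, seed=i,
                                label=f"pop{i}"), 1 / 3)
        for i, g in enumerate([0.35, 0.50, 0.65])
    ]
    spec = sd.CommunitySpec(models=models, n_scaffolds=180,
                            length_median_bp=15_000, seed=7)
    records, truth = sd.generate_scaffolds(spec)
    return records, truth


@pytest.fixture(scope="session")
def small_consensus():
    """A small consensus run shared by invariant tests."""
    from matbin import composition

    models = [
        (sd.sample_genome_model(g, markov_order=0, bias_strength=0.2, seed=i,
                                label=f"m{i}"), 0.5)
        for i, g in enumerate([0.40, 0.60])
    ]
    spec = sd.CommunitySpec(models=models, n_scaffolds=40,
                            length_median_bp=8_000, length_sigma=0.3,
                            min_length_bp=4_000, seed=3)
    records, truth = sd.generate_scaffolds(spec)
    features = composition.composition_matrix(records, 3, 4)
    config = binning.ConsensusConfig(
        min_scaffold_length=0, k_values=(4,), trials_per_k=30,
        min_cluster_size=5, seed=11,
    )
    return features, config, binning.consensus(features, config)
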