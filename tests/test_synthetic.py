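"""Ground-truth generator: determinism, placement invariants, targets."""

import numpy as np
import pandas as pd
import pytest

from polymads import evolution as evo
from polymads import synthetic as syn


def small_spec(seed=0, **kw):
    defaults = dict(
        subfamilies=("Malpha", "SEP"),
        triad_configs=[["ABD"], ["ABD"]],
        chromosome_lengths=syn.default_chromosomes(n_groups=3, length=4_000_000),
        master_seed=seed,
        n_decoys_low=0,
        n_decoys_high=0,
        fraction_silent=0.0,
        k_true=2,
    )
    defaults.update(kw)
    return syn.GenomeSpec(**defaults)


def test_two_balanced_triads_give_six_genes():
    genome = syn.generate_genome(small_spec())
    assert len(genome.cds) == 6
    assert all(t.balance == "balanced" for t in genome.truth.triads)
    assert genome.annotation.shape[0] == 6


def test_zero_divergence_duplicate_is_identical():
    spec = small_spec(
        duplication_events=[syn.DuplicationEvent("SEP", "segmental", 0.0, 0.0)]
    )
    genome = syn.generate_genome(spec)
    (dup,) = genome.truth.duplicates
    assert genome.cds[dup.source] == genome.cds[dup.copy]


def test_same_seed_byte_identical_outputs(tmp_path):
    a = syn.generate_genome(small_spec(seed=11))
    b = syn.generate_genome(small_spec(seed=11))
    assert a.cds == b.cds and a.proteins == b.proteins
    assert a.annotation.equals(b.annotation)
    assert a.expression.equals(b.expression)
    a.write_outputs(tmp_path / "a")
    b.write_outputs(tmp_path / "b")
    for name in ("proteins.faa", "annotation.tsv", "expression.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_different_seeds_differ():
    a = syn.generate_genome(small_spec(seed=1))
    b = syn.generate_genome(small_spec(seed=2))
    assert a.cds != b.cds


def test_tandem_same_chromosome_segmental_different():
    genome = syn.generate_genome(syn.default_spec(master_seed=4))
    chrom = dict(zip(genome.annotation.gene_id, genome.annotation.chromosome))
    for d in genome.truth.duplicates:
        if d.mode == "tandem":
            assert chrom[d.source] == chrom[d.copy]
        else:
            assert chrom[d.source] != chrom[d.copy]


def test_ground_truth_covers_every_family_gene():
    genome = syn.generate_genome(syn.default_spec(master_seed=4))
    truth = genome.truth
    truth.validate()
    family = set(truth.subfamily)
    assert family | set(truth.decoys) == set(genome.cds)
    assert set(truth.expression_labels) == family
    assert set(truth.segment) >= family


def test_coordinates_lie_inside_declared_segments():
    genome = syn.generate_genome(syn.default_spec(master_seed=4))
    spec = genome.spec
    anno = genome.annotation.set_index("gene_id")
    for gid, seg in genome.truth.segment.items():
        chrom = anno.at[gid, "chromosome"]
        edges = [0, *spec.segment_breakpoints[chrom], spec.chromosome_lengths[chrom]]
        idx = syn.SEGMENTS.index(seg)
        start, end = anno.at[gid, "start"], anno.at[gid, "end"]
        assert edges[idx] < start <= end <= edges[idx + 1]
        assert start >= 1


def test_invalid_breakpoints_rejected():
    spec = small_spec()
    bad = dict(spec.segment_breakpoints)
    chrom = next(iter(bad))
    bad[chrom] = (100, 50, 200, 300)
    spec.segment_breakpoints = bad
    with pytest.raises(syn.ConfigurationError):
        spec.validate()


def test_zero_chromosomes_rejected():
    with pytest.raises(syn.ConfigurationError):
        syn.GenomeSpec(
            subfamilies=("SEP",), triad_configs=[["ABD"]],
            chromosome_lengths={}, segment_breakpoints={},
        ).validate()


def test_invalid_triad_pattern_rejected():
    with pytest.raises(syn.ConfigurationError):
        small_spec(triad_configs=[["ABD"], ["AZ"]]).validate()


# ---------------------------------------------------------------------------
# codon mutation model


def test_mutate_cds_zero_ks_identity():
    cds = "ATGAAAGGGTTTCTGCCA" * 20 + "TAA"
    assert syn.mutate_cds(cds, 0.0, 5.0, 3) == cds


def test_mutate_cds_preserves_frame_and_stops():
    rng = np.random.default_rng(0)
    cds = syn.reverse_translate(rng, syn.random_protein(rng, 200))
    mutated = syn.mutate_cds(cds, 0.3, 0.5, 1)
    assert len(mutated) == len(cds)
    assert mutated.endswith("TAA")
    syn.translate_cds(mutated)  # raises on internal stops


def test_mutate_cds_rejects_frame_violation():
    with pytest.raises(syn.SequenceError):
        syn.mutate_cds("ATGA", 0.1, 0.1, 0)


def test_mutate_cds_hits_ng86_targets_in_expectation():
    """Mean NG86 Ks over 50 seeds within 20% of the 0.10 target."""
    rng = np.random.default_rng(9)
    base = syn.reverse_translate(rng, syn.random_protein(rng, 300))
    ks_vals, omega_vals = [], []
    for seed in range(50):
        mutated = syn.mutate_cds(base, 0.10, 0.3, seed)
        est = evo.estimate_pair(base, mutated)
        ks_vals.append(est.ks)
        if est.omega is not None:
            omega_vals.append(est.omega)
    assert np.mean(ks_vals) == pytest.approx(0.10, rel=0.20)
    assert np.mean(omega_vals) == pytest.approx(0.3, rel=0.35)


def test_planted_pair_dates_to_one_mya():
    rng = np.random.default_rng(2)
    base = syn.reverse_translate(rng, syn.random_protein(rng, 400))
    mutated = syn.mutate_cds(base, 0.013, 0.3, 5)
    est = evo.estimate_pair(base, mutated)
    assert est.t_mya == pytest.approx(1.0, rel=0.5)


# ---------------------------------------------------------------------------
# expression generator


def test_expression_exact_recovery_when_separated():
    genes = [f"g{i}" for i in range(30)]
    matrix, labels = syn.generate_expression(
        genes, k_true=3, seed=0, noise_sd=0.1, fraction_silent=0.0
    )
    from polymads import expression as expr

    result = expr.kmeans_cluster(matrix, expr.ClusteringConfig(k=3, seed=1))
    from sklearn.metrics import adjusted_rand_score

    truth = [labels[g] for g in genes]
    found = [result.labels[g] for g in genes]
    assert adjusted_rand_score(truth, found) == pytest.approx(1.0)


def test_expression_all_silent():
    genes = [f"g{i}" for i in range(10)]
    matrix, labels = syn.generate_expression(
        genes, k_true=1, seed=0, fraction_silent=1.0
    )
    assert (matrix.to_numpy() < 0).all()
    assert all(v == -1 for v in labels.values())


def test_expression_zero_noise_zero_within_cluster_variance():
    genes = [f"g{i}" for i in range(12)]
    matrix, labels = syn.generate_expression(
        genes, k_true=3, seed=0, noise_sd=0.0, fraction_silent=0.0
    )
    df = matrix.copy()
    df["label"] = [labels[g] for g in genes]
    for _, grp in df.groupby("label"):
        assert grp.drop(columns="label").var().max() == pytest.approx(0.0, abs=1e-12)


def test_expression_k_bigger_than_genes_rejected():
    with pytest.raises(syn.ConfigurationError):
        syn.generate_expression(["a", "b"], k_true=5, seed=0)
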