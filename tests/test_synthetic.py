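"""The planted-design generator: chains, copula labels, end-to-end recovery."""

import numpy as np
import pytest
from scipy import stats

from tnbk.synthetic import (
    MarkovChain,
    PlantedDesign,
    chain_kl,
    make_chain_pair,
    make_design,
    make_tissue_chain_pairs,
    sample_chain_sequences,
    sample_expression,
    sample_sequences,
    sample_tissue_sequences,
    simulate_study,
)


def test_chain_validation():
    with pytest.raises(ValueError, match="shape"):
        MarkovChain("DNA", 2, np.ones((4, 4)) / 4)
    bad = np.ones((16, 4)) / 4
    bad[3] = 0.0
    with pytest.raises(ValueError, match="all-zero"):
        MarkovChain("DNA", 2, bad)
    bad[3] = [0.5, 0.5, 0.5, 0.5]
    with pytest.raises(ValueError, match="sum to 1"):
        MarkovChain("DNA", 2, bad)


def test_degenerate_chain_emits_constant_sequence():
    t = np.zeros((4, 4))
    t[:, 0] = 1.0  # always emit A
    chain = MarkovChain("DNA", 1, t, initial=np.array([1.0, 0, 0, 0]))
    rng = np.random.default_rng(0)
    (seq,) = sample_chain_sequences(chain, [50], rng)
    assert seq == "A" * 50


def test_uniform_chain_dimer_law_of_large_numbers():
    chain = MarkovChain("DNA", 1, np.ones((4, 4)) / 4)
    rng = np.random.default_rng(1)
    (seq,) = sample_chain_sequences(chain, [100_000], rng)
    from tnbk.kmer import count_kmers
    counts, _ = count_kmers(seq, 2, "DNA")
    freqs = np.array([counts.get(w, 0) for w in counts]) / (len(seq) - 1)
    for w, c in counts.items():
        assert abs(c / (len(seq) - 1) - 1 / 16) <= 0.005


def test_same_seed_same_corpus():
    design = make_design(seed=3, n_tissues=3, n_genes=20)
    classes = [0, 1] * 10
    assert sample_sequences(design, classes, seed=5) == sample_sequences(design, classes, seed=5)
    st1 = simulate_study(design, seed=9)
    st2 = simulate_study(design, seed=9)
    assert st1.sequences == st2.sequences
    assert st1.expression == st2.expression


def test_chain_pair_hits_kl_target():
    c0, c1 = make_chain_pair("DNA", 2, per_step_kl=0.05, seed=2)
    assert chain_kl(c0, c1) == pytest.approx(0.05, rel=1e-3)
    with pytest.raises(ValueError, match="unreachable"):
        make_chain_pair("DNA", 2, per_step_kl=5.0, seed=2)


def test_tissue_chain_pairs_tuned_and_distinct():
    pairs = make_tissue_chain_pairs("DNA", 2, n_tissues=4, per_step_kl=0.01, seed=8)
    for lo, hi in pairs:
        assert chain_kl(lo, hi) == pytest.approx(0.01, rel=1e-2)
    # distinct directions: pairs differ across tissues
    assert not np.allclose(pairs[0][1].transition, pairs[1][1].transition)


def test_copula_limits():
    design = make_design(seed=4, n_tissues=6, n_genes=500)
    import dataclasses
    perfect = dataclasses.replace(design, rho=1.0, missing_rate=0.0)
    _, labels, gene_class = sample_expression(perfect, seed=0)
    arr = labels.to_numpy()
    assert (arr == arr[:, [0]]).all()  # identical labels across tissues
    assert (arr[:, 0] == gene_class.to_numpy()).all()

    indep = dataclasses.replace(design, rho=0.0, missing_rate=0.0, n_genes=2000)
    _, labels, _ = sample_expression(indep, seed=0)
    arr = labels.to_numpy()
    q = indep.high_fraction
    chance = q * q + (1 - q) * (1 - q)
    agree = np.mean([
        (arr[:, i] == arr[:, j]).mean()
        for i in range(6) for j in range(i + 1, 6)
    ])
    assert abs(agree - chance) <= 0.03


def test_missingness_rate_and_invariant():
    design = make_design(seed=4, n_tissues=8, n_genes=1000)
    matrix, _, _ = sample_expression(design, seed=1)
    frac = matrix.values.isna().to_numpy().mean()
    assert abs(frac - design.missing_rate) <= 0.02
    assert (~matrix.values.isna()).any(axis=1).all()  # every gene measured somewhere


def test_design_validation():
    chains = make_chain_pair("DNA", 2, 0.01, seed=1)
    with pytest.raises(ValueError, match="rho"):
        PlantedDesign(chains=chains, rho=1.5)
    with pytest.raises(ValueError, match="missing_rate"):
        PlantedDesign(chains=chains, missing_rate=-0.1)


def test_top5_cutoff_recovers_latent_high_class():
    """Labeling the synthetic matrix at TOP 5% recovers >= 90% of the
    genes whose planted class is high when class medians are 10x apart."""
    import dataclasses
    from tnbk.labeling import POSITIVE, TOP, balanced_labeled_set, compute_cutoff, label_genes
    design = dataclasses.replace(make_design(seed=12, n_tissues=4, n_genes=2000),
                                 high_fraction=0.05, missing_rate=0.0)
    matrix, labels, _ = sample_expression(design, seed=13)
    t = matrix.tissues[0]
    cut = compute_cutoff(matrix, t, TOP, 5)
    called = {g for g, c in label_genes(matrix, cut) if c == POSITIVE}
    truth = set(labels.index[labels[t]])
    assert len(truth & called) / len(truth) >= 0.90


def test_tissue_sequences_encode_labels():
    """Genes that are high everywhere differ in composition from genes low
    everywhere, along each tissue's loading direction."""
    design = make_design(seed=21, n_tissues=4, n_genes=200, per_step_kl=0.05)
    import pandas as pd
    genes = [f"g{i}" for i in range(200)]
    labels = pd.DataFrame(
        np.tile(np.array([0] * 100 + [1] * 100)[:, None], (1, 4)).astype(bool),
        index=genes, columns=[f"tissue{i:02d}" for i in range(1, 5)],
    )
    seqs = sample_tissue_sequences(design, labels, seed=2)
    from tnbk.nbk import train
    m = train([seqs[g] for g in genes], ["c0"] * 100 + ["c1"] * 100, k=3)
    fresh = sample_tissue_sequences(design, labels, seed=3)
    acc = (m.predict([fresh[g] for g in genes]) == np.array(["c0"] * 100 + ["c1"] * 100)).mean()
    assert acc >= 0.9


def test_end_to_end_recovery_of_gene_class():
    """Desk-scale pipeline check on a well-separated rho=0.8 design: the
    second stage recovers the planted gene-level class at >= 0.9 accuracy
    and at least matches the single-tissue stage on that quantity."""
    from tnbk.experiments import ExperimentConfig, bundle_from_study, config_seed
    from tnbk.experiments import cross_validate  # noqa: F401  (phase metrics below)
    from tnbk.kmer import KmerCorpus
    from tnbk.nbk import KmerNaiveBayes
    from tnbk.two_phase import build_feature_vectors, train_phase2, predict_phase2

    design = make_design(seed=31, n_tissues=8, n_genes=800, per_step_kl=0.01)
    study = simulate_study(design, seed=32)
    bundle = bundle_from_study(study, "TOP", 20, seed=33)
    tissues = bundle.tissues
    genes = sorted(study.sequences)
    row = {g: i for i, g in enumerate(genes)}
    corpus = KmerCorpus.build([study.sequences[g] for g in genes], 3, "DNA")
    # split genes in half: models trained on sets excluding the eval half
    eval_half = set(genes[::2])
    models = {}
    for t in tissues:
        ls = bundle.labeled_sets[t]
        keep = [(g, c) for g, c in ls.members if g not in eval_half]
        rows = np.array([row[g] for g, _ in keep])
        models[t] = KmerNaiveBayes(k=3).fit(corpus.select(rows),
                                            np.array([c for _, c in keep]))
    eval_genes = sorted(eval_half)
    vectors = build_feature_vectors(models, study.sequences, eval_genes,
                                    tissues[0], tissues)
    truth = study.gene_class.loc[eval_genes].to_numpy()
    # balanced evaluation of gene-class recovery
    pos = np.flatnonzero(truth)
    neg = np.random.default_rng(0).choice(np.flatnonzero(~truth), size=pos.size,
                                          replace=False)
    idx = np.concatenate([pos, neg])
    y = np.where(truth[idx], "c1", "c0")
    # stage 1 readout: the assigned tissue's single model
    single = np.array([v.predictions[0] for v in vectors])[idx]
    acc1 = (np.where(single > 0.5, "c1", "c0") == y).mean()
    # stage 2: BN over all slots, trained on the other half's vectors
    train_genes = sorted(set(genes) - eval_half)
    train_vectors = build_feature_vectors(models, study.sequences, train_genes,
                                          tissues[0], tissues)
    truth_tr = study.gene_class.loc[train_genes].to_numpy()
    clf = train_phase2(train_vectors, np.where(truth_tr, "c1", "c0"),
                       algorithm="BN", tissues=tissues)
    acc2 = (predict_phase2(clf, [vectors[i] for i in idx]) == y).mean()
    assert acc2 >= 0.9
    assert acc2 >= acc1 - 0.02
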