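import hashlib
from pathlib import Path

import numpy as np
import pytest

from adrpair import rank_pairs, score_pair
from adrpair.model import AdrPairModel
from adrpair.synthetic import (
    ConfigError,
    GeneratorConfig,
    expected_separation,
    generate,
)


def dir_hash(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def test_deterministic_tables(tmp_path):
    generate(GeneratorConfig(seed=5)).write(tmp_path / "a")
    generate(GeneratorConfig(seed=5)).write(tmp_path / "b")
    assert dir_hash(tmp_path / "a") == dir_hash(tmp_path / "b")
    generate(GeneratorConfig(seed=6)).write(tmp_path / "c")
    assert dir_hash(tmp_path / "a") != dir_hash(tmp_path / "c")


def test_ddaa_bookkeeping(fixture_data):
    cfg = fixture_data.config
    assert len(fixture_data.ddaa) == cfg.n_adrs * cfg.positives_per_adr
    assert fixture_data.ddaa["adr"].nunique() == cfg.n_adrs


def test_positives_subset_of_planted(fixture_data):
    truth = fixture_data.truth
    for pos in truth.adr_positive_pairs.values():
        assert pos <= truth.interacting_pairs


def test_planted_pairs_share_gene_disease_and_bridge(fixture_data):
    net = fixture_data.network()
    for a, b in sorted(fixture_data.truth.interacting_pairs)[:20]:
        g_shared = net.genes_of(a) & net.genes_of(b)
        d_shared = net.diseases_of(a) & net.diseases_of(b)
        assert g_shared and d_shared
        assert any(g_shared & net.genes_of_disease(k) for k in d_shared)


def test_explicit_pair_budget_and_score_split():
    """With n_interacting_pairs given, exactly that many pairs are planted;
    noise-free planted pairs score > 0 and non-planted exactly 0."""
    data = generate(GeneratorConfig(n_drugs=40, n_interacting_pairs=30, seed=2))
    assert len(data.truth.interacting_pairs) == 30
    net = data.network()
    planted = data.truth.interacting_pairs
    scores = rank_pairs(net)
    for a, b, s in zip(scores.drug_a, scores.drug_b, scores.inter_score):
        if (a, b) in planted:
            assert s > 0
        else:
            assert s == 0.0


def test_ranking_recovery_noise_free(fixture_data):
    """Ascending ranking puts every non-planted pair before every planted
    pair when noise is off."""
    ranked = rank_pairs(fixture_data.network())
    planted = fixture_data.truth.interacting_pairs
    flags = [(a, b) in planted for a, b in zip(ranked.drug_a, ranked.drug_b)]
    first_planted = flags.index(True)
    assert all(flags[first_planted:])
    assert not any(flags[:first_planted])


def test_expected_separation_is_a_valid_lower_bound(fixture_data):
    gap = expected_separation(fixture_data.config)
    assert gap > 0
    net = fixture_data.network()
    planted_scores = [
        score_pair(a, b, net).inter_score
        for a, b in sorted(fixture_data.truth.interacting_pairs)
    ]
    assert min(planted_scores) >= gap - 1e-12


def test_expected_separation_rejects_noise():
    with pytest.raises(ValueError):
        expected_separation(GeneratorConfig(noise_rate=0.05))


def test_noisy_ranking_bottom_quartile_mostly_non_planted():
    """With additive noise <= 0.05 the bottom quartile of the ascending
    ranking stays >= 90% non-planted (averaged over 5 seeds)."""
    fracs = []
    for seed in range(5):
        data = generate(GeneratorConfig(noise_rate=0.05, seed=seed))
        ranked = rank_pairs(data.network())
        q = len(ranked) // 4
        planted = data.truth.interacting_pairs
        bottom = list(zip(ranked.drug_a[:q], ranked.drug_b[:q]))
        fracs.append(np.mean([p not in planted for p in bottom]))
    assert np.mean(fracs) >= 0.9


def test_infeasible_configs_raise():
    with pytest.raises(ConfigError):
        generate(GeneratorConfig(n_drugs=5, community_size=4, n_adrs=2))
    with pytest.raises(ConfigError):
        generate(GeneratorConfig(positives_per_adr=1000))
    with pytest.raises(ConfigError):
        GeneratorConfig(signal_strength=1.5)
    with pytest.raises(ConfigError):
        generate(GeneratorConfig(n_genes=3))


def test_end_to_end_direction_vs_rgns(fixture_model):
    """Credible negatives beat random negatives on the planted fixture."""
    from adrpair import baselines

    hc = fixture_model.fit(seed=0).macro
    rg = baselines.run_rgns(fixture_model, repeats=3, seed=0).macro
    assert hc["f1"] >= rg["f1"]
    assert hc["auc"] >= rg["auc"]
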