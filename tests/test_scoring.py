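import itertools

import numpy as np
import pytest

from dcascape import (
    CouplingModel,
    ScoringError,
    enumerate_paths,
    hamiltonian,
    hamiltonian_effective,
    hamiltonian_many,
    mutation_scan,
    rank_variants,
)
from dcascape.scoring import decode, optimize_sequence
from dcascape.synthetic import PlantedModelSpec, gibbs_sample, make_planted_model

Q = 4


def brute_force_H(model, s):
    """Independent double-loop oracle for the Hamiltonian."""
    H = 0.0
    L = model.L
    for i in range(L):
        H -= model.fields[i, s[i]]
        for j in range(i + 1, L):
            H -= model.couplings[i, j, s[i], s[j]]
    return H


def test_hamiltonian_trivial_cases(model_factory):
    zero = model_factory(L=4).zeros_like()
    assert hamiltonian(zero, [0, 1, 2, 3]) == 0.0
    single = zero.zeros_like()
    single.fields[0, 0] = 2.0
    assert hamiltonian(single, "AUUU") == -2.0


def test_hamiltonian_matches_brute_force(model_factory, rng):
    model = model_factory(L=4, seed=5)
    for _ in range(20):
        s = rng.integers(0, 4, size=4)
        assert hamiltonian(model, s) == pytest.approx(brute_force_H(model, s), abs=1e-12)


def test_hamiltonian_many_matches_scalar(model_factory, rng):
    model = model_factory(L=7, seed=6)
    table = rng.integers(0, 4, size=(30, 7))
    H = hamiltonian_many(model, table)
    for a in range(30):
        assert H[a] == pytest.approx(hamiltonian(model, table[a]), abs=1e-10)


def test_hamiltonian_accepts_strings_and_rejects_bad_length(model_factory):
    model = model_factory(L=4, seed=7)
    assert hamiltonian(model, "ACGU") == pytest.approx(hamiltonian(model, [0, 1, 2, 3]))
    assert hamiltonian(model, "acgt") == pytest.approx(hamiltonian(model, "ACGU"))
    with pytest.raises(ScoringError):
        hamiltonian(model, "ACG")


def test_scoring_is_linear_in_parameters(model_factory, rng):
    m1 = model_factory(L=5, seed=8)
    m2 = model_factory(L=5, seed=9)
    a, b = 0.7, -1.3
    combo = CouplingModel(couplings=a * m1.couplings + b * m2.couplings,
                          fields=a * m1.fields + b * m2.fields, gauge_tag="test")
    for _ in range(20):
        s = rng.integers(0, 4, size=5)
        expect = a * hamiltonian(m1, s) + b * hamiltonian(m2, s)
        assert hamiltonian(combo, s) == pytest.approx(expect, abs=1e-10)


def test_effective_hamiltonian_routes_agree(model_factory, rng):
    target = model_factory(L=6, seed=10)
    background = model_factory(L=6, seed=11)
    s = rng.integers(0, 4, size=6)
    assert hamiltonian_effective(target, target, s) == 0.0
    assert hamiltonian_effective(target, target.zeros_like(), s) == hamiltonian(target, s)
    for _ in range(50):
        s = rng.integers(0, 4, size=6)
        assert hamiltonian_effective(target, background, s) == pytest.approx(
            hamiltonian(target, s) - hamiltonian(background, s), abs=1e-12)


# -------------------------------------------------------------- mutation scan

def test_mutation_scan_incremental_equals_full_rescore(model_factory, rng):
    model = model_factory(L=6, seed=12)
    wt = rng.integers(0, 4, size=6)
    scan = mutation_scan(model, wt, tau=0.1)
    href = hamiltonian(model, wt)
    for i in range(6):
        for x in range(Q):
            mut = wt.copy()
            mut[i] = x
            assert scan.delta[i, x] == pytest.approx(
                hamiltonian(model, mut) - href, abs=1e-10)
    assert np.all(scan.delta[np.arange(6), wt] == 0.0)


def test_mutation_scan_fields_only_limit(model_factory, rng):
    model = model_factory(L=5, seed=13, coupling_scale=0.0)
    wt = rng.integers(0, 4, size=5)
    scan = mutation_scan(model, wt, tau=0.0)
    expect = -(model.fields - model.fields[np.arange(5), wt][:, None])
    assert np.allclose(scan.delta, expect, atol=1e-12)


def test_mutation_scan_classes_and_default_tau(model_factory, rng):
    model = model_factory(L=6, seed=14)
    wt = rng.integers(0, 4, size=6)
    scan = mutation_scan(model, wt)
    assert scan.tau > 0  # shuffled-model control SD
    cls = scan.classes
    assert set(np.unique(cls)) <= {"enhancer", "neutral", "inhibitor"}
    assert np.all(cls[np.arange(6), wt] == "neutral")
    assert np.all((scan.delta < -scan.tau) == (cls == "enhancer"))


def test_mutation_scan_tsv(tmp_path, model_factory, rng):
    model = model_factory(L=4, seed=15)
    scan = mutation_scan(model, rng.integers(0, 4, size=4), tau=0.5)
    scan.to_tsv(tmp_path / "scan.tsv")
    lines = (tmp_path / "scan.tsv").read_text().splitlines()
    assert lines[0].split("\t") == ["pos", "wt", "A", "C", "G", "U"]
    assert len(lines) == 5


# -------------------------------------------------------------- rank variants

def test_rank_variants_single_mutant_count(model_factory, rng):
    model = model_factory(L=6, seed=16)
    df = rank_variants(model, rng.integers(0, 4, size=6), max_mutations=1)
    assert len(df) == 3 * 6 + 1


def test_rank_variants_zero_model_tie_break(model_factory):
    model = model_factory(L=4).zeros_like()
    wt = "GGGG"
    df = rank_variants(model, wt, max_mutations=1)
    assert df.sequence.iloc[0] == wt  # Hamming tie-break puts wild type first
    assert np.all(df.H == 0.0)


def test_rank_variants_matches_exhaustive_oracle(model_factory):
    model = model_factory(L=5, seed=17)
    wt = np.array([0, 1, 2, 3, 0])
    df = rank_variants(model, wt, max_mutations=2)
    # oracle: enumerate every sequence in 4^5 within Hamming <= 2, score, sort
    rows = []
    for seq in itertools.product(range(4), repeat=5):
        ham = sum(a != b for a, b in zip(seq, wt))
        if ham <= 2:
            rows.append((hamiltonian(model, list(seq)), ham, decode(np.array(seq))))
    rows.sort()
    assert list(df.sequence.head(10)) == [r[2] for r in rows[:10]]
    assert np.allclose(df.H.head(10), [r[0] for r in rows[:10]])


def test_rank_variants_enumeration_guard(model_factory):
    model = model_factory(L=20, seed=18)
    with pytest.raises(ScoringError, match="candidate list"):
        rank_variants(model, "A" * 20, max_mutations=8)


def test_rank_variants_candidate_list(model_factory):
    model = model_factory(L=4, seed=19)
    df = rank_variants(model, "ACGU", candidates=["ACGU", "UGCA", "AAAA"])
    assert len(df) == 3
    assert df.H.is_monotonic_increasing


# ------------------------------------------------------------------- paths

def test_enumerate_paths_matches_exhaustive_oracle(model_factory):
    model = model_factory(L=6, seed=20)
    start, end = "ACGUAC", "AUGCAA"  # differs at positions 1, 3, 5
    paths, best, worst = enumerate_paths(model, start, end)
    assert len(paths) == 6  # 3!
    # oracle: recompute every ordering with plain loops
    s = np.array([0, 1, 2, 3, 0, 1])
    t = np.array([0, 3, 2, 1, 0, 0])
    diff = [i for i in range(6) if s[i] != t[i]]
    oracle = []
    for order in itertools.permutations(diff):
        cur = s.copy()
        inter = []
        for pos in order:
            cur[pos] = t[pos]
            inter.append(brute_force_H(model, cur))
        oracle.append((max(inter), sum(inter), order))
    assert {p.order for p in paths} == {o[2] for o in oracle}
    oracle.sort()
    assert best.order == oracle[0][2]
    assert worst.order == oracle[-1][2]
    assert best.bottleneck == pytest.approx(oracle[0][0], abs=1e-10)


def test_enumerate_paths_single_and_degenerate(model_factory):
    model = model_factory(L=4, seed=21)
    paths, best, worst = enumerate_paths(model, "ACGU", "ACGA")
    assert len(paths) == 1
    assert paths[0].intermediates[-1] == pytest.approx(hamiltonian(model, "ACGA"))
    with pytest.raises(ScoringError, match="identical"):
        enumerate_paths(model, "ACGU", "ACGU")
    with pytest.raises(ScoringError, match="guard"):
        enumerate_paths(model_factory(L=10, seed=22), "A" * 10, "C" * 9 + "A")


def test_path_endpoint_is_order_independent(model_factory):
    model = model_factory(L=7, seed=23)
    paths, _, _ = enumerate_paths(model, "ACGUACG", "UGCAACG")
    finals = {round(p.intermediates[-1], 10) for p in paths}
    assert len(finals) == 1
    assert finals.pop() == round(hamiltonian(model, "UGCAACG"), 10)


# ----------------------------------------------------------- sampled vs random

def test_gibbs_samples_outscore_random_sequences():
    """Boltzmann samples of a high-specificity binder model score >= 3 null
    SDs better on average than composition-matched random sequences.

    Composition matching absorbs the field contribution, so the separation
    is carried by the couplings; a strong stem-rich model (five
    Watson-Crick pairs at 2.5, fields 0.8) represents the high-affinity
    regime where that margin is expected."""
    pairs = [(2, 14, 2.5), (4, 12, 2.5), (5, 11, 2.5), (3, 6, 2.5), (9, 13, 2.5)]
    spec = PlantedModelSpec(L=20, coupled_pairs=pairs, fields=0.8,
                            background_coupling_scale=0.15, seed=24)
    model = make_planted_model(spec)
    pool = gibbs_sample(model, 1000, burn_in=80, thin=2, seed=25)
    H_pool = hamiltonian_many(model, pool.data.astype(int))
    rng = np.random.default_rng(26)
    comp = np.bincount(pool.data.reshape(-1), minlength=4) / pool.data.size
    rand = rng.choice(4, size=(1000, 20), p=comp)
    H_rand = hamiltonian_many(model, rand)
    assert H_pool.mean() < H_rand.mean() - 3 * H_rand.std()


def test_optimize_sequence_reaches_single_mutant_optimum(model_factory, rng):
    model = model_factory(L=8, seed=27)
    opt = optimize_sequence(model, rng.integers(0, 4, size=8))
    scan = mutation_scan(model, opt, tau=0.0)
    assert scan.delta.min() >= -1e-10
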