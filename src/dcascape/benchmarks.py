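"""Canonical synthetic study systems for benchmarking the full pipeline.

These functions freeze the conditions of the package's reference studies —
a ground-truth specificity model with five strong stem-like coupled pairs,
Gibbs-sampled pools for parameter recovery, and a five-round simulated
selection feeding genome-wide discovery — so that the test suite and the
reproduction script exercise exactly the same systems.

Study design notes:

* The planted model carries five Watson–Crick-style coupled pairs (three at
  strength 1.5, two at 1.0), weak zero-sum residual couplings on every pair
  (scale 0.15, emulating the diffuse correlations a selected pool carries at
  all positions), and per-position field biases (scale 0.3).
* Parameter recovery samples M = 50,000 sequences from the planted
  Boltzmann distribution and refits with pseudocount 0.1.
* Genome discovery simulates five selection rounds of a 100,000-read random
  library at capture strength τ = 3 — strong enrichment (mean Hamiltonian
  drops by several null SDs) while keeping the pool diverse, as real
  selected pools are; τ = 1 over-concentrates the pool to a handful of
  unique reads against a model this strong, which no experiment produces.
* Null distributions use n = 200,000 random sequences: the one-tailed
  z-test consumes only the null mean and SD, whose standard errors at this
  n are negligible against the effects measured.
* For the planted-genome AUC the positive set is the planted window itself
  (overlap = L): windows merely brushing the planted element share bases at
  the wrong model positions and carry no signal under a position-specific
  model.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .dca import coupling_norms, effective_model, fit_model
from .genome_scan import attach_pvalues, attach_qvalues, auc, build_null, genome_composition, scan, top_hits
from .landscape import direct_information, top_di_pairs
from .scoring import decode, hamiltonian_many, optimize_sequence
from .dca import compute_frequencies
from .synthetic import (
    PlantedModelSpec,
    gibbs_sample,
    make_genome,
    make_planted_model,
    random_library,
    simulate_selection,
)

#: stem-like coupled position pairs (0-based) with Watson-Crick strengths
STUDY_PAIRS: tuple[tuple[int, int, float], ...] = (
    (2, 14, 1.5),
    (4, 12, 1.5),
    (5, 11, 1.5),
    (3, 6, 1.0),
    (9, 13, 1.0),
)

STUDY_L = 20
FIELD_SCALE = 0.3
BACKGROUND_COUPLING_SCALE = 0.15
PSEUDOCOUNT = 0.1


def _subseeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def planted_study_model(seed: int = 0):
    spec = PlantedModelSpec(
        L=STUDY_L,
        coupled_pairs=STUDY_PAIRS,
        fields=FIELD_SCALE,
        background_coupling_scale=BACKGROUND_COUPLING_SCALE,
        seed=seed,
    )
    return make_planted_model(spec)


def recovery_study(seed: int = 0, M: int = 50_000) -> dict:
    """Planted model → Gibbs pool → refit → DI/coupling-norm recovery.

    Returns the number of planted pairs among the top-5 DI pairs and the
    Spearman rank correlation between planted and inferred coupling
    Frobenius norms (zero-sum gauge) over all position pairs.
    """
    s_model, s_pool = _subseeds(seed, 2)
    planted = planted_study_model(s_model)
    pool = gibbs_sample(planted, M, burn_in=100, thin=3, seed=s_pool)
    fitted = fit_model(pool, PSEUDOCOUNT)
    freqs = compute_frequencies(pool, PSEUDOCOUNT)
    di = direct_information(fitted, freqs)
    top5 = top_di_pairs(di, 5)
    found = {(int(r.i) - 1, int(r.j) - 1) for r in top5.itertuples()}
    planted_set = {(i, j) for i, j, _ in STUDY_PAIRS}
    pn = coupling_norms(planted)
    fn = coupling_norms(fitted)
    iu, ju = np.triu_indices(STUDY_L, 1)
    rho = float(stats.spearmanr(pn[iu, ju], fn[iu, ju]).statistic)
    return {
        "n_planted_in_top5_di": len(found & planted_set),
        "norm_rank_correlation": rho,
        "top5_pairs": sorted(found),
        "planted_pairs": sorted(planted_set),
    }


def discovery_study(
    seed: int = 0,
    M: int = 100_000,
    rounds: int = 5,
    capture_strength: float = 3.0,
    genome_length: int = 50_000,
    null_n: int = 200_000,
    n_calibration: int = 10_000,
) -> dict:
    """Five-round selection → effective model → genome scan → discovery stats.

    Plants the effective model's greedy-optimal 20-mer in a random genome
    and reports its rank, full-overlap AUC, lower-tail z-test p-value, plus
    null-calibration statistics (KS of null p-values against uniform, and
    the p-value at the null mean).
    """
    s_model, s_lib, s_sel, s_gen, s_null, s_cal = _subseeds(seed, 6)
    planted = planted_study_model(s_model)
    library = random_library(M, L=STUDY_L, seed=s_lib)
    pools = simulate_selection(library, planted, rounds=rounds,
                               capture_strength=capture_strength, seed=s_sel)
    mean_h = [float(hamiltonian_many(planted, p.data.astype(np.intp)).mean())
              for p in [library] + pools]
    target = fit_model(pools[-1], PSEUDOCOUNT)
    background = fit_model(library, PSEUDOCOUNT)
    eff = effective_model(target, background)
    pool_scores = hamiltonian_many(eff, pools[-1].data.astype(np.intp))
    optimal = optimize_sequence(eff, pools[-1].data[int(np.argmin(pool_scores))])
    plant_at = genome_length // 2
    genome, truth = make_genome(genome_length, planted=[(decode(optimal), plant_at)],
                                seed=s_gen)
    profile = scan(eff, genome)
    null = build_null(eff, genome_composition(genome), n=null_n, seed=s_null)
    profile = attach_pvalues(profile, null)
    profile = attach_qvalues(profile)
    order = np.argsort(profile.scores, kind="mergesort")
    planted_idx = int(np.flatnonzero(profile.starts == plant_at)[0])
    planted_rank = int(np.flatnonzero(order == planted_idx)[0]) + 1
    # null calibration: p-values of fresh null draws should be uniform
    rng = np.random.default_rng(s_cal)
    cal_seqs = rng.choice(eff.q, size=(n_calibration, eff.L), p=null.composition)
    cal_p = stats.norm.cdf((hamiltonian_many(eff, cal_seqs) - null.mean) / null.sd)
    ks = float(stats.kstest(cal_p, "uniform").statistic)
    p_at_mean = float(stats.norm.cdf((null.mean - null.mean) / null.sd))
    return {
        "planted_rank": planted_rank,
        "auc_planted_window": float(auc(profile, truth, min_overlap=STUDY_L)),
        "planted_window_pvalue": float(profile.pvalues[planted_idx]),
        "planted_window_qvalue": float(profile.qvalues[planted_idx]),
        "n_windows": int(profile.n_windows),
        "mean_H_per_round": mean_h,
        "null_pvalue_ks": ks,
        "p_at_null_mean": p_at_mean,
        "optimal_sequence": decode(optimal),
        "top_hit_start": int(top_hits(profile, 1).start.iloc[0]),
    }


def calibration_study(seed: int = 0, M: int = 50_000, null_n: int = 200_000,
                      n_calibration: int = 10_000) -> dict:
    """Null calibration of the z-test machinery under the no-signal condition.

    Fits target and background models to two independent unselected random
    libraries (a control-vs-control effective model: pure finite-sample
    noise, the class for which the z-test's normality assumption holds),
    builds the null, and checks that p-values of fresh null draws are
    uniform.  Effective models from strong selection carry mild skew
    (|skewness| ~ 0.2-0.3) that shifts the KS statistic toward ~0.02; see
    the methods note.
    """
    s1, s2, s3, s4 = _subseeds(seed, 4)
    lib_a = random_library(M, L=STUDY_L, seed=s1)
    lib_b = random_library(M, L=STUDY_L, seed=s2)
    eff = effective_model(fit_model(lib_a, PSEUDOCOUNT), fit_model(lib_b, PSEUDOCOUNT))
    comp = np.full(4, 0.25)
    null = build_null(eff, comp, n=null_n, seed=s3)
    rng = np.random.default_rng(s4)
    seqs = rng.choice(eff.q, size=(n_calibration, eff.L), p=comp)
    p = stats.norm.cdf((hamiltonian_many(eff, seqs) - null.mean) / null.sd)
    return {
        "null_pvalue_ks": float(stats.kstest(p, "uniform").statistic),
        "p_at_null_mean": float(stats.norm.cdf(0.0)),
    }


def selection_sanity_study(seed: int = 0, M: int = 20_000, rounds: int = 5) -> dict:
    """Mean pool Hamiltonian trajectory under planted vs. zero fitness."""
    s_model, s_lib, s_sel1, s_sel2 = _subseeds(seed, 4)
    planted = planted_study_model(s_model)
    flat = planted.zeros_like()
    library = random_library(M, L=STUDY_L, seed=s_lib)
    sel = simulate_selection(library, planted, rounds=rounds,
                             capture_strength=3.0, seed=s_sel1)
    null_sel = simulate_selection(library, flat, rounds=rounds,
                                  capture_strength=3.0, seed=s_sel2)
    mh = [float(hamiltonian_many(planted, p.data.astype(np.intp)).mean())
          for p in [library] + sel]
    mh_flat = [float(hamiltonian_many(planted, p.data.astype(np.intp)).mean())
               for p in [library] + null_sel]
    return {"mean_H_selected": mh, "mean_H_flat_model": mh_flat}
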