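"""Synthetic study systems: planted Potts models, Gibbs-sampled pools,
simulated multi-round selection, and genomes with planted binding elements.

These generators emulate the structure of an in vitro selection experiment
against a protein with a known (planted) specificity model, so that every
inference and discovery stage can be benchmarked against ground truth:

* a planted coupling model with Watson–Crick-style strong pairs (stem-like
  complementary preferences) plus optional weak residual couplings on all
  pairs and per-position field biases;
* pools Gibbs-sampled from the planted Boltzmann distribution P ∝ exp(−H);
* round-by-round selection modeled as weighted resampling of a library with
  retention weight ∝ exp(−H/τ);
* random-background genomes with binding elements spliced at known
  coordinates (truth intervals in BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dca import CouplingModel
from .scoring import hamiltonian_many
from .sequence_io import ALPHABET, EncodedSequenceSet, GenomeSequence


class SyntheticError(ValueError):
    pass


#: complementary index pairs under ACGU ordering: A-U, C-G, G-C, U-A
_WC_PARTNER = (3, 2, 1, 0)


def watson_crick_block(strength: float, q: int = 4) -> np.ndarray:
    """q x q coupling block favoring complementary nucleotide combinations."""
    block = np.zeros((q, q))
    for x in range(q):
        block[x, _WC_PARTNER[x]] = strength
    return block


@dataclass
class PlantedModelSpec:
    """Recipe for a ground-truth coupling model.

    ``coupled_pairs`` lists (i, j, template) with 0-based positions and a
    template that is either a q x q array or a scalar strength (expanded to
    a Watson–Crick block).  ``fields`` may be an L x q array or a scalar
    scale for random per-position biases.  ``background_coupling_scale``
    adds weak zero-sum random couplings to every pair, emulating the
    residual correlations a real selected pool carries on all positions
    (default 0: only the listed pairs are coupled).
    """

    L: int = 20
    alphabet: tuple[str, ...] = ALPHABET
    coupled_pairs: Sequence[tuple] = ()
    fields: Union[np.ndarray, float, None] = None
    background_coupling_scale: float = 0.0
    seed: int = 0


def make_planted_model(spec: PlantedModelSpec) -> CouplingModel:
    """Build the deterministic ground-truth model described by a spec."""
    L, q = spec.L, len(spec.alphabet)
    rng = np.random.default_rng(spec.seed)
    e = np.zeros((L, L, q, q))
    if spec.background_coupling_scale:
        from .dca import zero_sum_gauge

        noise = rng.normal(0.0, spec.background_coupling_scale, size=(L, L, q, q))
        noise = zero_sum_gauge((noise + noise.transpose(1, 0, 3, 2)) / 2)
        e += noise
    for pair in spec.coupled_pairs:
        i, j, template = pair
        if not (0 <= i < L and 0 <= j < L) or i == j:
            raise SyntheticError(f"coupled pair ({i}, {j}) out of range or degenerate")
        block = (watson_crick_block(float(template), q)
                 if np.isscalar(template) else np.asarray(template, dtype=float))
        if block.shape != (q, q):
            raise SyntheticError("coupling template must be q x q or a scalar strength")
        e[i, j] += block
        e[j, i] += block.T
    eye = np.arange(L)
    e[eye, eye] = 0.0
    if spec.fields is None:
        h = np.zeros((L, q))
    elif np.isscalar(spec.fields):
        h = rng.normal(0.0, float(spec.fields), size=(L, q))
    else:
        h = np.asarray(spec.fields, dtype=float)
        if h.shape != (L, q):
            raise SyntheticError("fields must be L x q")
    return CouplingModel(couplings=e, fields=h, alphabet=spec.alphabet,
                         gauge_tag="planted", pseudocount=0.0)


def gibbs_sample(model: CouplingModel, n: int, burn_in: int = 100,
                 thin: int = 3, seed: int = 0, chains: int = 1024) -> EncodedSequenceSet:
    """Sample sequences from P(σ) ∝ exp(−H(σ)) by single-site Gibbs updates.

    Runs ``min(n, chains)`` parallel chains; after ``burn_in`` full sweeps,
    one sequence per chain is collected every ``thin`` sweeps until ``n``
    rows accumulate.  The conditional at site i is
    P(x | rest) ∝ exp(h̄_i(x) + Σ_{j≠i} ē_ij(x, σ_j)).
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    L, q = model.L, model.q
    rng = np.random.default_rng(seed)
    n_chains = min(n, chains)
    sigma = rng.integers(0, q, size=(n_chains, L), dtype=np.intp)

    def sweep() -> None:
        for i in range(L):
            logits = np.broadcast_to(model.fields[i], (n_chains, q)).copy()
            for j in range(L):
                if j == i:
                    continue
                logits += model.couplings[i, j][:, sigma[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n_chains)
            sigma[:, i] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    for _ in range(burn_in):
        sweep()
    collected = [sigma.copy()]
    got = n_chains
    while got < n:
        for _ in range(max(thin, 1)):
            sweep()
        collected.append(sigma.copy())
        got += n_chains
    data = np.concatenate(collected, axis=0)[:n].astype(np.uint8)
    return EncodedSequenceSet(data, model.alphabet)


def random_library(M: int, L: int = 20, composition: Optional[Sequence[float]] = None,
                   seed: int = 0) -> EncodedSequenceSet:
    """Unselected random library with the given ACGU composition (uniform default)."""
    rng = np.random.default_rng(seed)
    comp = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    data = rng.choice(4, size=(M, L), p=comp / comp.sum()).astype(np.uint8)
    return EncodedSequenceSet(data, ALPHABET)


def simulate_selection(library: EncodedSequenceSet, model: CouplingModel,
                       rounds: int = 5, capture_strength: float = 1.0,
                       seed: int = 0) -> list[EncodedSequenceSet]:
    """Multi-round selection as weighted resampling with weight ∝ exp(−H/τ).

    Each round resamples M reads (with replacement) from the previous pool;
    smaller ``capture_strength`` τ means sharper selection.  Returns the
    pool after each round; mean H is non-increasing across rounds in
    expectation.
    """
    if rounds < 1:
        raise SyntheticError("rounds must be >= 1")
    if capture_strength <= 0:
        raise SyntheticError("capture_strength must be positive")
    rng = np.random.default_rng(seed)
    pools = []
    current = library
    M = library.M
    for _ in range(rounds):
        H = hamiltonian_many(model, current.data.astype(np.intp))
        logw = -H / capture_strength
        if current.counts is not None:
            logw = logw + np.log(current.counts)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        idx = rng.choice(current.n_rows, size=M, replace=True, p=w)
        current = EncodedSequenceSet(current.data[idx], library.alphabet)
        pools.append(current)
    return pools


def make_genome(length: int, composition: Optional[Sequence[float]] = None,
                planted: Sequence[tuple[str, int]] = (), seed: int = 0,
                identifier: str = "synthetic") -> tuple[GenomeSequence, list[tuple[str, int, int, str]]]:
    """Random genome with binding elements spliced at known 0-based positions.

    Returns the genome and truth intervals (chrom, start, end, name) in BED
    convention.  Planted elements must fit inside the genome and must not
    overlap one another.
    """
    rng = np.random.default_rng(seed)
    comp = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    comp = comp / comp.sum()
    alphabet_dna = "ACGT"
    idx = rng.choice(4, size=length, p=comp)
    residues = list("".join(alphabet_dna[i] for i in idx))
    occupied: list[tuple[int, int]] = []
    truth = []
    for n, (seq, pos) in enumerate(planted):
        s = seq.upper().replace("U", "T")
        end = pos + len(s)
        if pos < 0 or end > length:
            raise SyntheticError(f"planted element {n} at {pos} falls outside the genome")
        for a, b in occupied:
            if pos < b and a < end:
                raise SyntheticError(f"planted elements overlap at [{pos}, {end})")
        occupied.append((pos, end))
        residues[pos:end] = s
        truth.append((identifier, pos, end, f"planted{n + 1}"))
    return GenomeSequence(identifier, "".join(residues)), truth
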