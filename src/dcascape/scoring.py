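"""Hamiltonian scoring, single-mutant landscapes, variant ranking and
mutational trajectories.

The Hamiltonian H(σ) = −Σ_{i<j} ē_ij(σ_i,σ_j) − Σ_i h̄_i(σ_i) is the
binding-specificity score of a sequence under a coupling model; more
negative means more favorable predicted binding.  The effective Hamiltonian
H_eff = H − H_bg subtracts a control-selection background.  Because H is
linear in the parameters, H_eff can be computed either from two models or
from their parameter difference — both routes agree exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .dca import CouplingModel, effective_model
from .sequence_io import ALPHABET, NT_TO_IDX


class ScoringError(ValueError):
    pass


def _as_encoded(seq, L: int, alphabet=ALPHABET) -> np.ndarray:
    if isinstance(seq, str):
        try:
            seq = [NT_TO_IDX[c] for c in seq.upper()]
        except KeyError as exc:
            raise ScoringError(f"sequence contains unsupported character {exc.args[0]!r}")
    arr = np.asarray(seq, dtype=np.intp)
    if arr.shape != (L,):
        raise ScoringError(f"sequence length {arr.shape} does not match model L={L}")
    if arr.min() < 0 or arr.max() >= len(alphabet):
        raise ScoringError("sequence indices out of alphabet range")
    return arr


def decode(seq: np.ndarray, alphabet=ALPHABET) -> str:
    return "".join(alphabet[i] for i in seq)


def hamiltonian(model: CouplingModel, seq) -> float:
    """H(σ) = −Σ_{i<j} ē_ij(σ_i,σ_j) − Σ_i h̄_i(σ_i)."""
    s = _as_encoded(seq, model.L, model.alphabet)
    iu, ju = np.triu_indices(model.L, k=1)
    pair = model.couplings[iu, ju, s[iu], s[ju]].sum()
    field = model.fields[np.arange(model.L), s].sum()
    return float(-pair - field)


def hamiltonian_many(model: CouplingModel, seqs: np.ndarray) -> np.ndarray:
    """Vectorized H over an (n, L) index table."""
    seqs = np.asarray(seqs, dtype=np.intp)
    L = model.L
    H = -model.fields[np.arange(L), seqs].sum(axis=1)
    for i in range(L - 1):
        for j in range(i + 1, L):
            H -= model.couplings[i, j, seqs[:, i], seqs[:, j]]
    return H


def hamiltonian_effective(target: CouplingModel, background: CouplingModel, seq) -> float:
    """H_eff(σ) = H(σ) − H_bg(σ); equals scoring with the subtracted model."""
    return hamiltonian(target, seq) - hamiltonian(background, seq)


@dataclass
class MutationScan:
    """ΔH of every single mutant of a wild-type sequence.

    ``delta[i, x]`` = H(σ^{i→x}) − H(σ); zero at the wild-type base.
    ``classes`` labels each entry enhancer (ΔH < −τ), neutral (|ΔH| ≤ τ) or
    inhibitor (ΔH > τ).
    """

    wildtype: np.ndarray
    delta: np.ndarray
    reference_score: float
    tau: float
    alphabet: tuple[str, ...] = ALPHABET

    @property
    def classes(self) -> np.ndarray:
        out = np.where(self.delta < -self.tau, "enhancer",
                       np.where(self.delta > self.tau, "inhibitor", "neutral"))
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.delta, columns=list(self.alphabet))
        df.insert(0, "pos", np.arange(1, len(self.wildtype) + 1))
        df.insert(1, "wt", [self.alphabet[i] for i in self.wildtype])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def shuffled_model_tau(model: CouplingModel, wildtype, seed: int = 0) -> float:
    """Neutral-band width: SD of single-mutant ΔH under a parameter-shuffled control.

    Shuffling destroys sequence-specific structure while preserving the
    parameter magnitude distribution, giving a data-driven scale for
    "no effect".
    """
    rng = np.random.default_rng(seed)
    e = model.couplings.copy()
    h = model.fields.copy()
    rng.shuffle(e.reshape(-1))
    rng.shuffle(h.reshape(-1))
    # resymmetrize and zero the diagonal so the control is a valid model
    e = (e + e.transpose(1, 0, 3, 2)) / 2
    e[np.arange(model.L), np.arange(model.L)] = 0.0
    ctrl = CouplingModel(couplings=e, fields=h, alphabet=model.alphabet,
                         gauge_tag=model.gauge_tag, pseudocount=model.pseudocount)
    scan = mutation_scan(ctrl, wildtype, tau=0.0)
    off = scan.delta[scan.delta != 0.0]
    return float(np.std(off)) if off.size else 0.0


def mutation_scan(model: CouplingModel, wildtype, tau: Optional[float] = None) -> MutationScan:
    """ΔH for all single mutants, computed incrementally.

    ΔH(i, x) = −(h̄_i(x) − h̄_i(σ_i)) − Σ_{j≠i} (ē_ij(x, σ_j) − ē_ij(σ_i, σ_j));
    identical to full rescoring of each mutant but O(L²q) instead of O(L³q).
    """
    s = _as_encoded(wildtype, model.L, model.alphabet)
    L, q = model.L, model.q
    # field term
    delta = -(model.fields - model.fields[np.arange(L), s][:, None])
    # coupling term: for each i, sum over j != i of e_ij(x, s_j) - e_ij(s_i, s_j)
    ctx = model.couplings[np.arange(L)[:, None], np.arange(L)[None, :], :,
                          s[None, :]]               # (L_i, L_j, q_x) after fancy indexing
    # ctx[i, j, x] = e[i, j, x, s_j]; diagonal j == i contributes 0 since e_ii = 0
    ctx_sum = ctx.sum(axis=1)                        # (L, q)
    wt_ctx = ctx_sum[np.arange(L), s][:, None]
    delta -= ctx_sum - wt_ctx
    if tau is None:
        tau = shuffled_model_tau(model, s)
    return MutationScan(wildtype=s, delta=delta, reference_score=hamiltonian(model, s),
                        tau=float(tau), alphabet=model.alphabet)


def rank_variants(
    model: CouplingModel,
    wildtype,
    max_mutations: int = 1,
    candidates: Optional[Iterable] = None,
    limit: int = 10_000_000,
):
    """Score and rank sequence variants, best (lowest H) first.

    Without an explicit candidate list, all sequences within Hamming
    distance ``max_mutations`` of the wild type are enumerated (refusing
    enumerations beyond ``limit``).  Ties are broken by Hamming distance to
    the wild type, then lexicographically.  Returns a pandas DataFrame with
    sequence, H, ΔH and Hamming distance.
    """
    import pandas as pd

    s = _as_encoded(wildtype, model.L, model.alphabet)
    L, q = model.L, model.q
    if max_mutations < 1:
        raise ScoringError("max_mutations must be >= 1")
    if candidates is None:
        k = min(max_mutations, L)
        n_var = sum(
            _comb(L, m) * (q - 1) ** m for m in range(0, k + 1)
        )
        if n_var > limit:
            raise ScoringError(
                f"enumeration of {n_var} variants exceeds the guard ({limit}); "
                "pass an explicit candidate list"
            )
        rows = [s.copy()]
        for m in range(1, k + 1):
            for pos in itertools.combinations(range(L), m):
                alt = [[x for x in range(q) if x != s[p]] for p in pos]
                for combo in itertools.product(*alt):
                    v = s.copy()
                    v[list(pos)] = combo
                    rows.append(v)
        table = np.asarray(rows, dtype=np.intp)
    else:
        table = np.asarray([_as_encoded(c, L, model.alphabet) for c in candidates])
    H = hamiltonian_many(model, table)
    href = hamiltonian(model, s)
    hamming = (table != s[None, :]).sum(axis=1)
    seq_str = ["".join(model.alphabet[i] for i in row) for row in table]
    df = pd.DataFrame({
        "sequence": seq_str,
        "H": H,
        "delta_H": H - href,
        "hamming": hamming,
    })
    df = df.sort_values(["H", "hamming", "sequence"], kind="mergesort").reset_index(drop=True)
    return df


def _comb(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


@dataclass
class MutationalPath:
    """One ordered trajectory of single substitutions between two sequences.

    ``order`` lists the differing positions in the order mutated;
    ``intermediates`` holds H_eff after each substitution (the last entry is
    H_eff of the end sequence).  ``bottleneck`` is the worst (max)
    intermediate; ``total`` the sum of intermediates.
    """

    start: np.ndarray
    end: np.ndarray
    order: tuple[int, ...]
    intermediates: np.ndarray

    @property
    def bottleneck(self) -> float:
        return float(self.intermediates.max())

    @property
    def total(self) -> float:
        return float(self.intermediates.sum())


def enumerate_paths(model: CouplingModel, start, end, max_positions: int = 8):
    """Enumerate all substitution orders between two sequences.

    Returns ``(paths, best, worst)``: every k! ordering of the k differing
    positions, the most favorable path (minimal bottleneck, then minimal
    total) and the least favorable (maximal bottleneck, then maximal total).
    A single unbindable intermediate breaks an evolutionary bridge, hence
    bottleneck is the primary criterion.
    """
    s = _as_encoded(start, model.L, model.alphabet)
    t = _as_encoded(end, model.L, model.alphabet)
    diff = np.flatnonzero(s != t)
    k = diff.size
    if k == 0:
        raise ScoringError("start and end sequences are identical")
    if k > max_positions:
        raise ScoringError(
            f"{k} differing positions exceed the {max_positions}! enumeration guard"
        )
    paths = []
    for order in itertools.permutations(diff.tolist()):
        cur = s.copy()
        scores = np.empty(k)
        for step, pos in enumerate(order):
            cur[pos] = t[pos]
            scores[step] = hamiltonian(model, cur)
        paths.append(MutationalPath(start=s, end=t, order=order, intermediates=scores))
    best = min(paths, key=lambda p: (p.bottleneck, p.total))
    worst = max(paths, key=lambda p: (p.bottleneck, p.total))
    return paths, best, worst


def paths_to_tsv(paths: Sequence[MutationalPath], path, alphabet=ALPHABET) -> None:
    import pandas as pd

    rows = []
    for p in paths:
        rows.append({
            "order": ",".join(str(i + 1) for i in p.order),
            "bottleneck": p.bottleneck,
            "total": p.total,
            "intermediates": ",".join(f"{v:.6g}" for v in p.intermediates),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def optimize_sequence(model: CouplingModel, start, max_rounds: int = 100) -> np.ndarray:
    """Greedy Hamiltonian descent: repeatedly apply the best single mutation.

    Deterministic; stops at a local optimum of the single-mutation
    neighborhood (ties broken by position then nucleotide index).
    """
    cur = _as_encoded(start, model.L, model.alphabet).copy()
    for _ in range(max_rounds):
        scan = mutation_scan(model, cur, tau=0.0)
        i, x = np.unravel_index(np.argmin(scan.delta), scan.delta.shape)
        if scan.delta[i, x] >= 0:
            break
        cur[i] = x
    return cur
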