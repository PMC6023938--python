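"""Mean-field direct coupling analysis for fixed-length nucleotide pools.

A selected pool of L-mers is modeled with a Potts (maximum-entropy pairwise)
distribution

    P(x_1..x_L) ∝ exp( Σ_{i<j} e_ij(x_i, x_j) + Σ_i h_i(x_i) )

whose parameters are estimated by the mean-field approximation: couplings are
the negative inverse of the connected correlation matrix of single- and
two-site nucleotide frequencies, and fields follow from the mean-field
self-consistency relation.  The Potts parameterization is redundant; we fix
the gauge by zeroing all parameters touching one reference nucleotide N_k,
repeat the inference for each of the four choices of N_k, and average the
four gauge-fixed parameter sets.  A background (control-selection) model fit
with the identical pipeline can be subtracted parameter-wise to form the
effective binding-specificity model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sequence_io import ALPHABET, EncodedSequenceSet


class InferenceError(ValueError):
    """Fatal problem during model inference."""


@dataclass
class FrequencyModel:
    """Single- and two-site nucleotide frequencies of a pool.

    ``f1[i, x]`` is the (pseudocount-regularized) frequency of nucleotide x
    at position i; ``f2[i, j, x, y]`` the joint frequency for i != j.  The
    diagonal blocks ``f2[i, i]`` hold ``f1[i, x] * δ_xy`` (the same-site
    "joint" is the marginal concentrated on x == y), which is what the
    connected-correlation matrix construction expects.
    """

    f1: np.ndarray
    f2: np.ndarray
    pseudocount: float
    M: int
    alphabet: tuple[str, ...] = ALPHABET

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


@dataclass
class CouplingModel:
    """Gauge-averaged pairwise couplings and local fields.

    ``couplings[i, j, x, y]`` is ē_ij(x, y) with ē_ij(x, y) = ē_ji(y, x) and
    ē_ii ≡ 0; ``fields[i, x]`` is h̄_i(x).  Lower Hamiltonian
    H(σ) = −Σ_{i<j} ē_ij(σ_i, σ_j) − Σ_i h̄_i(σ_i) means more favorable
    predicted binding.
    """

    couplings: np.ndarray
    fields: np.ndarray
    alphabet: tuple[str, ...] = ALPHABET
    gauge_tag: str = "mean-of-four-single-state-gauges"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.couplings = np.asarray(self.couplings, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        L, q = self.fields.shape
        if self.couplings.shape != (L, L, q, q):
            raise InferenceError("couplings must be L x L x q x q")
        if not (np.isfinite(self.couplings).all() and np.isfinite(self.fields).all()):
            raise InferenceError("model parameters must be finite")

    @property
    def L(self) -> int:
        return self.fields.shape[0]

    @property
    def q(self) -> int:
        return self.fields.shape[1]

    @property
    def sequence_space_size(self) -> int:
        """Number of distinct L-mers the model scores (q**L; 4^20 ≈ 1.1e12)."""
        return self.q ** self.L

    def zeros_like(self) -> "CouplingModel":
        return replace(self, couplings=np.zeros_like(self.couplings),
                       fields=np.zeros_like(self.fields))


def _one_hot_counts(seqs: EncodedSequenceSet) -> tuple[np.ndarray, np.ndarray]:
    """Weighted single and pairwise counts via a one-hot design matrix."""
    M_rows, L = seqs.data.shape
    q = len(seqs.alphabet)
    X = np.zeros((M_rows, L * q), dtype=np.float64)
    cols = np.arange(L) * q + seqs.data
    X[np.arange(M_rows)[:, None], cols] = 1.0
    if seqs.counts is not None:
        c1 = (seqs.counts[:, None] * X).sum(axis=0)
        c2 = X.T @ (seqs.counts[:, None] * X)
    else:
        c1 = X.sum(axis=0)
        c2 = X.T @ X
    return c1.reshape(L, q), c2.reshape(L, q, L, q).transpose(0, 2, 1, 3)


def compute_frequencies(seqs: EncodedSequenceSet, pseudocount: float = 0.1) -> FrequencyModel:
    """Pseudocount-regularized marginal frequencies of a pool.

    f_i(x)      = (1−α)·c_i(x)/M   + α/q
    f_ij(x, y)  = (1−α)·c_ij(x,y)/M + α/q²      (i ≠ j)

    Duplicate reads contribute with their multiplicity.  Diagonal blocks of
    f2 are set to f_i(x)·δ_xy.
    """
    alpha = pseudocount
    if not (0 <= alpha < 1):
        raise InferenceError(f"pseudocount must lie in [0, 1), got {alpha}")
    L, q = seqs.L, len(seqs.alphabet)
    M = seqs.M
    c1, c2 = _one_hot_counts(seqs)
    f1 = (1 - alpha) * c1 / M + alpha / q
    f2 = (1 - alpha) * c2 / M + alpha / q**2
    # diagonal convention: f2[i,i,x,y] = f1[i,x] if x == y else 0
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return FrequencyModel(f1=f1, f2=f2, pseudocount=alpha, M=M, alphabet=seqs.alphabet)


def infer_single_gauge(freqs: FrequencyModel, gauge_state: int | str) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field inference in the gauge where one nucleotide N_k is zeroed.

    Builds the connected correlation matrix C over the L·(q−1) coordinates
    excluding N_k at every position, with
    C[(i,x),(j,y)] = f_ij(x,y) − f_i(x)·f_j(y), inverts it, and reads off
    e_ij(x,y) = −(C⁻¹)[(i,x),(j,y)] for i ≠ j.  Fields follow from the
    mean-field self-consistency
    h_i(x) = ln(f_i(x)/f_i(N_k)) − Σ_{j≠i} Σ_y e_ij(x,y)·f_j(y).
    All parameters touching N_k are identically zero.
    """
    if isinstance(gauge_state, str):
        gauge_state = freqs.alphabet.index(gauge_state.upper().replace("T", "U"))
    k = int(gauge_state)
    L, q = freqs.L, freqs.q
    if not (0 <= k < q):
        raise InferenceError(f"gauge state must index the alphabet, got {k}")
    keep = [x for x in range(q) if x != k]
    d = q - 1
    # C over reduced coordinates
    C = (freqs.f2 - np.einsum("ix,jy->ijxy", freqs.f1, freqs.f1))
    C = C[:, :, keep][:, :, :, keep]             # L x L x d x d
    C = C.transpose(0, 2, 1, 3).reshape(L * d, L * d)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        raise InferenceError(
            "connected correlation matrix is singular; use a positive pseudocount"
        ) from None
    e_red = -Cinv.reshape(L, d, L, d).transpose(0, 2, 1, 3)
    e = np.zeros((L, L, q, q))
    ix = np.ix_(range(L), range(L), keep, keep)
    e[ix] = e_red
    eye = np.arange(L)
    e[eye, eye] = 0.0
    # fields: h_i(x) = ln(f_i(x)/f_i(k)) − Σ_{j≠i} Σ_y e_ij(x,y) f_j(y)
    h = np.log(freqs.f1 / freqs.f1[:, [k]])
    h -= np.einsum("ijxy,jy->ix", e, freqs.f1)
    h[:, k] = 0.0
    return e, h


def average_gauges(per_gauge: Sequence[tuple[np.ndarray, np.ndarray]],
                   alphabet: tuple[str, ...] = ALPHABET,
                   pseudocount: float = 0.0) -> CouplingModel:
    """Average the four single-state gauge parameter sets elementwise."""
    if len(per_gauge) != len(alphabet):
        raise InferenceError(f"expected {len(alphabet)} gauge parameter sets")
    shapes_e = {e.shape for e, _ in per_gauge}
    shapes_h = {h.shape for _, h in per_gauge}
    if len(shapes_e) != 1 or len(shapes_h) != 1:
        raise InferenceError("gauge parameter sets have mismatched shapes")
    e_bar = np.mean([e for e, _ in per_gauge], axis=0)
    h_bar = np.mean([h for _, h in per_gauge], axis=0)
    return CouplingModel(couplings=e_bar, fields=h_bar, alphabet=alphabet,
                         pseudocount=pseudocount)


def fit_model(
    seqs: EncodedSequenceSet,
    pseudocount: float = 0.1,
    log_path: Optional[str | Path] = None,
) -> CouplingModel:
    """Full inference: frequencies → four single-state gauges → average.

    Deterministic given the pool.  ``log_path`` optionally writes a fit log
    (M, dropped reads, pseudocount, condition number of C per gauge).
    """
    freqs = compute_frequencies(seqs, pseudocount)
    per_gauge = []
    conds = []
    L, q = freqs.L, freqs.q
    for k in range(q):
        e, h = infer_single_gauge(freqs, k)
        per_gauge.append((e, h))
        if log_path is not None:
            keep = [x for x in range(q) if x != k]
            C = (freqs.f2 - np.einsum("ix,jy->ijxy", freqs.f1, freqs.f1))
            C = C[:, :, keep][:, :, :, keep].transpose(0, 2, 1, 3).reshape(L * (q - 1), -1)
            conds.append(np.linalg.cond(C))
    model = average_gauges(per_gauge, seqs.alphabet, pseudocount)
    if log_path is not None:
        lines = [
            "dcascape fit log",
            f"M\t{seqs.M}",
            f"rows\t{seqs.n_rows}",
            f"dropped_reads\t{seqs.dropped}",
            f"L\t{seqs.L}",
            f"pseudocount\t{pseudocount}",
        ]
        for k, c in enumerate(conds):
            lines.append(f"cond_C_gauge_{seqs.alphabet[k]}\t{c:.6g}")
        Path(log_path).write_text("\n".join(lines) + "\n")
    return model


def effective_model(target: CouplingModel, background: CouplingModel) -> CouplingModel:
    """Background-subtracted model: ē_eff = ē − ē_bg, h̄_eff = h̄ − h̄_bg.

    Scoring with the result equals H(σ) − H_bg(σ) for every σ (the
    Hamiltonian is linear in the parameters).
    """
    if target.alphabet != background.alphabet or target.L != background.L:
        raise InferenceError("target and background models are incompatible")
    if target.gauge_tag != background.gauge_tag:
        raise InferenceError("target and background use different gauge schemes")
    return CouplingModel(
        couplings=target.couplings - background.couplings,
        fields=target.fields - background.fields,
        alphabet=target.alphabet,
        gauge_tag=target.gauge_tag,
        pseudocount=target.pseudocount,
    )


def zero_sum_gauge(couplings: np.ndarray) -> np.ndarray:
    """Project couplings into the zero-sum (Ising) gauge per pair block.

    Gauge-invariant comparisons of coupling magnitude (Frobenius norms,
    planted-vs-inferred rank correlations) should be made in this gauge.
    """
    e = np.asarray(couplings, dtype=float)
    row = e.mean(axis=3, keepdims=True)
    col = e.mean(axis=2, keepdims=True)
    tot = e.mean(axis=(2, 3), keepdims=True)
    return e - row - col + tot


def coupling_norms(model: CouplingModel) -> np.ndarray:
    """L x L Frobenius norms of zero-sum-gauged coupling blocks (diag 0)."""
    e = zero_sum_gauge(model.couplings)
    n = np.sqrt((e ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(n, 0.0)
    return n
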