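"""Genome-wide binding-site discovery with effective-Hamiltonian profiles.

Every length-L window of a genome (step 1) is scored with the effective
Hamiltonian; a null distribution of H over random composition-matched
sequences gives each window a one-tailed z-test p-value (lower tail: more
negative scores are more binding-like) and Storey q-values control the FDR.
AUC against truth intervals quantifies discovery performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .dca import CouplingModel
from .scoring import hamiltonian_many
from .sequence_io import GenomeSequence


class ScanError(ValueError):
    pass


@dataclass
class HamiltonianProfile:
    """Per-window effective-Hamiltonian scores along a genome.

    Coordinates are 0-based half-open window starts; windows containing
    ambiguity codes carry NaN scores and are excluded from ranking.  The
    reverse-strand block (if scanned) reports windows on original forward
    coordinates with strand "-".
    """

    sequence_id: str
    starts: np.ndarray
    scores: np.ndarray
    strand: np.ndarray
    L: int
    genome: Optional[GenomeSequence] = None
    pvalues: Optional[np.ndarray] = None
    qvalues: Optional[np.ndarray] = None

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def window_sequence(self, idx: int) -> str:
        if self.genome is None:
            return ""
        s = int(self.starts[idx])
        seq = self.genome.residues[s : s + self.L]
        return seq.replace("T", "U")


def scan(model_eff: CouplingModel, genome: GenomeSequence,
         strands: Iterable[str] = ("+",)) -> HamiltonianProfile:
    """Score all step-1 sliding windows of a genome, per requested strand."""
    L = model_eff.L
    if genome.length < L:
        raise ScanError(f"genome {genome.identifier} shorter than window size {L}")
    strands = tuple(strands)
    for st in strands:
        if st not in ("+", "-"):
            raise ScanError(f"unknown strand {st!r}")

    def _scan_forward(g: GenomeSequence) -> np.ndarray:
        idx, valid = g.encode()
        wins = sliding_window_view(idx, L)
        ok = sliding_window_view(valid, L).all(axis=1)
        scores = np.full(wins.shape[0], np.nan)
        if ok.any():
            scores[ok] = hamiltonian_many(model_eff, wins[ok].astype(np.intp))
        return scores

    starts_all, scores_all, strand_all = [], [], []
    n_win = genome.length - L + 1
    fwd_starts = np.arange(n_win)
    if "+" in strands:
        starts_all.append(fwd_starts)
        scores_all.append(_scan_forward(genome))
        strand_all.append(np.full(n_win, "+"))
    if "-" in strands:
        rc_scores = _scan_forward(genome.reverse_complement())
        # RC window p covers forward coordinates [G - p - L, G - p)
        starts = genome.length - L - np.arange(n_win)
        order = np.argsort(starts)
        starts_all.append(starts[order])
        scores_all.append(rc_scores[order])
        strand_all.append(np.full(n_win, "-"))
    return HamiltonianProfile(
        sequence_id=genome.identifier,
        starts=np.concatenate(starts_all),
        scores=np.concatenate(scores_all),
        strand=np.concatenate(strand_all),
        L=L,
        genome=genome,
    )


@dataclass
class NullDistribution:
    """Moments of H over random composition-matched L-mers."""

    n: int
    mean: float
    sd: float
    composition: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "composition": list(map(float, self.composition)), "seed": self.seed,
        }, indent=1) + "\n")


def genome_composition(genome: GenomeSequence) -> np.ndarray:
    """Global ACGU proportions of a genome (ambiguity codes excluded)."""
    idx, valid = genome.encode()
    counts = np.bincount(idx[valid], minlength=4).astype(float)
    if counts.sum() == 0:
        raise ScanError("genome has no unambiguous bases")
    return counts / counts.sum()


def build_null(model_eff: CouplingModel, composition, n: int = 1_000_000,
               seed: int = 0, batch: int = 200_000) -> NullDistribution:
    """Null H distribution from i.i.d.-per-position random L-mers.

    Positions are drawn independently from the given ACGU composition
    (matching the genome under study); only the mean and SD are retained,
    as the one-tailed z-test needs nothing more.
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (model_eff.q,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
        raise ScanError("composition must be q non-negative proportions summing to 1")
    if n < 1000:
        raise ScanError("null sample count must be >= 1000")
    rng = np.random.default_rng(seed)
    total, total2, m = 0.0, 0.0, 0
    while m < n:
        b = min(batch, n - m)
        seqs = rng.choice(model_eff.q, size=(b, model_eff.L), p=comp)
        H = hamiltonian_many(model_eff, seqs)
        total += H.sum()
        total2 += (H ** 2).sum()
        m += b
    mean = total / n
    var = total2 / n - mean ** 2
    sd = float(np.sqrt(max(var, 0.0)))
    if sd == 0.0:
        raise ScanError("null scores are degenerate (zero variance); "
                        "model or composition admits a single score")
    return NullDistribution(n=n, mean=float(mean), sd=sd, composition=comp, seed=seed)


def attach_pvalues(profile: HamiltonianProfile, null: NullDistribution) -> HamiltonianProfile:
    """Lower-tail z-test p-values: p = Φ((H_eff − μ)/s). NaN scores propagate."""
    if null.sd <= 0:
        raise ScanError("null SD must be positive")
    z = (profile.scores - null.mean) / null.sd
    p = stats.norm.cdf(z)
    p = np.where(np.isnan(profile.scores), np.nan, p)
    return replace(profile, pvalues=p)


def storey_qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey's FDR q-values with π̂₀ = min(1, #{p > λ} / (m(1−λ))).

    q_(i) = min_{j ≥ i} π̂₀ · m · p_(j) / j over the sorted p-values; NaN
    entries are passed through.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return p.copy()
    pi0 = min(1.0, np.count_nonzero(ps > lam) / (m * (1.0 - lam)))
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    out = np.full(p.shape, np.nan)
    out[mask] = q
    return out


def attach_qvalues(profile: HamiltonianProfile, lam: float = 0.5) -> HamiltonianProfile:
    if profile.pvalues is None:
        raise ScanError("attach p-values before q-values")
    return replace(profile, qvalues=storey_qvalues(profile.pvalues, lam))


def _positive_mask(profile: HamiltonianProfile, truth: Sequence[tuple], min_overlap: int = 1) -> np.ndarray:
    """Window is positive iff it overlaps a truth interval by >= min_overlap bases."""
    pos = np.zeros(profile.n_windows, dtype=bool)
    for iv in truth:
        chrom, t0, t1 = iv[0], int(iv[1]), int(iv[2])
        if chrom != profile.sequence_id:
            continue
        w0 = profile.starts
        w1 = profile.starts + profile.L
        overlap = np.minimum(w1, t1) - np.maximum(w0, t0)
        pos |= overlap >= min_overlap
    return pos


def auc(profile: HamiltonianProfile, truth: Sequence[tuple], min_overlap: int = 1) -> float:
    """Probability a random positive window outscores (more negative H) a
    random negative one; ties credit 0.5.  Rank-statistic (Mann–Whitney) form.
    """
    valid = ~np.isnan(profile.scores)
    pos = _positive_mask(profile, truth, min_overlap) & valid
    neg = valid & ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ScanError("AUC needs at least one positive and one negative window")
    # lower score = better binder; rank ascending so positives should rank low
    ranks = stats.rankdata(profile.scores[valid], method="average")
    pos_in_valid = pos[valid]
    u = n_pos * n_neg + n_pos * (n_pos + 1) / 2 - ranks[pos_in_valid].sum()
    return float(u / (n_pos * n_neg))


def top_hits(profile: HamiltonianProfile, k: int = 10):
    """The k best windows (lowest H_eff; ties by coordinate) as a DataFrame."""
    import pandas as pd

    valid = np.flatnonzero(~np.isnan(profile.scores))
    order = valid[np.lexsort((profile.starts[valid], profile.scores[valid]))]
    order = order[: min(k, order.size)]
    return pd.DataFrame({
        "sequence_id": profile.sequence_id,
        "start": profile.starts[order],
        "end": profile.starts[order] + profile.L,
        "strand": profile.strand[order],
        "sequence": [profile.window_sequence(int(i)) for i in order],
        "H_eff": profile.scores[order],
        "pvalue": profile.pvalues[order] if profile.pvalues is not None else np.nan,
        "qvalue": profile.qvalues[order] if profile.qvalues is not None else np.nan,
    })


def write_bedgraph(profile: HamiltonianProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="H_eff {profile.sequence_id}"\n')
        for s, sc, st in zip(profile.starts, profile.scores, profile.strand):
            if np.isnan(sc):
                continue
            if st != "+":
                continue
            fh.write(f"{profile.sequence_id}\t{s}\t{s + profile.L}\t{sc:.6g}\n")


def write_top_hits_bed(profile: HamiltonianProfile, path: str | Path, k: int = 10) -> None:
    hits = top_hits(profile, k)
    with open(path, "w") as fh:
        for rank, row in hits.iterrows():
            fh.write(f"{row.sequence_id}\t{row.start}\t{row.end}\t"
                     f"hit{rank + 1}\t{row.H_eff:.6g}\t{row.strand}\n")
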