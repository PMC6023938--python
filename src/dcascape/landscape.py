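"""Direct information and the pairwise coupling landscape (DCA-scape).

Direct information treats each position pair in isolation: the two-site
"direct" distribution P^dir(x, y) ∝ exp(ē_ij(x, y)) with auxiliary single
-site factors fitted so that its marginals reproduce the empirical f_i and
f_j.  DI_ij is the mutual information of that distribution — the
Kullback–Leibler divergence between P^dir and the independent product
f_i·f_j.  The landscape matrix lays out all ē_ij(x, y) as an (L·q)×(L·q)
grid of q×q blocks (80×80 for 20-mers), the direct visual map of which
nucleotide combinations couple.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dca import CouplingModel, FrequencyModel


class LandscapeError(ValueError):
    pass


@dataclass
class DIMatrix:
    """L x L symmetric direct-information scores, zero diagonal."""

    values: np.ndarray

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = [str(i + 1) for i in range(self.L)]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def _direct_pair_distribution(block: np.ndarray, fi: np.ndarray, fj: np.ndarray,
                              tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Two-site direct distribution by iterative proportional fitting.

    Finds positive factors a, b with P = a_x · exp(e_xy) · b_y (normalized)
    matching marginals fi, fj to within ``tol`` (max absolute deviation).
    """
    W = np.exp(block)
    a = np.ones_like(fi)
    b = np.ones_like(fj)
    for _ in range(max_iter):
        P = a[:, None] * W * b[None, :]
        P /= P.sum()
        resid = max(np.abs(P.sum(1) - fi).max(), np.abs(P.sum(0) - fj).max())
        if resid < tol:
            return P
        a *= fi / P.sum(1)
        P = a[:, None] * W * b[None, :]
        P /= P.sum()
        b *= fj / P.sum(0)
    P = a[:, None] * W * b[None, :]
    P /= P.sum()
    resid = max(np.abs(P.sum(1) - fi).max(), np.abs(P.sum(0) - fj).max())
    if resid >= tol:
        raise LandscapeError(
            f"direct-distribution fitting did not converge (residual {resid:.3g})"
        )
    return P


def direct_information(model: CouplingModel, freqs: FrequencyModel,
                       mode: str = "direct", tol: float = 1e-6,
                       max_iter: int = 500) -> DIMatrix:
    """DI for all position pairs.

    ``mode="direct"`` (default): DI_ij = Σ_xy P^dir ln(P^dir / (f_i f_j)),
    the mutual information of the direct distribution.  ``mode="empirical"``
    instead computes KL(f_ij ‖ P^dir), comparing the empirical joint counts
    to the pairwise direct distribution.
    """
    if model.L != freqs.L or model.alphabet != freqs.alphabet:
        raise LandscapeError("model and frequencies are incompatible")
    if mode not in ("direct", "empirical"):
        raise LandscapeError(f"unknown DI mode {mode!r}")
    L = model.L
    di = np.zeros((L, L))
    tiny = 1e-300
    for i in range(L - 1):
        for j in range(i + 1, L):
            fi, fj = freqs.f1[i], freqs.f1[j]
            try:
                P = _direct_pair_distribution(model.couplings[i, j], fi, fj,
                                              tol=tol, max_iter=max_iter)
            except LandscapeError as exc:
                raise LandscapeError(f"pair ({i + 1},{j + 1}): {exc}") from None
            indep = np.outer(fi, fj)
            if mode == "direct":
                val = np.sum(P * np.log((P + tiny) / (indep + tiny)))
            else:
                fij = freqs.f2[i, j]
                val = np.sum(fij * np.log((fij + tiny) / (P + tiny)))
            di[i, j] = di[j, i] = max(val, 0.0) if val > -1e-12 else val
    return DIMatrix(values=di)


def top_di_pairs(di: DIMatrix, k: int = 10) -> pd.DataFrame:
    """Pairs sorted descending by DI; ties by (i, j) lexicographic. 1-based."""
    if k < 1:
        raise LandscapeError("k must be >= 1")
    L = di.L
    iu, ju = np.triu_indices(L, k=1)
    vals = di.values[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    order = order[: min(k, order.size)]
    return pd.DataFrame({
        "i": iu[order] + 1,
        "j": ju[order] + 1,
        "DI": vals[order],
    })


@dataclass
class LandscapeMatrix:
    """(L·q) x (L·q) labeled matrix of ē_ij(x, y): q x q block per pair."""

    values: np.ndarray
    labels: list[str]

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def export_landscape(model: CouplingModel, path: Optional[str | Path] = None) -> LandscapeMatrix:
    """Lay out couplings as the (L·q)×(L·q) DCA-scape matrix.

    Row/column order is position-major, nucleotide-minor (1A 1C 1G 1U 2A …);
    block (i, i) is identically zero and block (i, j) is the transpose of
    block (j, i).
    """
    L, q = model.L, model.q
    values = model.couplings.transpose(0, 2, 1, 3).reshape(L * q, L * q)
    labels = [f"{i + 1}{nt}" for i in range(L) for nt in model.alphabet]
    out = LandscapeMatrix(values=values, labels=labels)
    if path is not None:
        out.to_tsv(path)
    return out


def read_landscape(path: str | Path) -> LandscapeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return LandscapeMatrix(values=df.to_numpy(dtype=float),
                           labels=[str(c) for c in df.columns])


def plot_landscape(matrix: LandscapeMatrix, path: str | Path, cmap: str = "RdBu_r") -> None:
    """Heatmap of the DCA-scape (diverging colors centered at zero)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lim = np.abs(matrix.values).max() or 1.0
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(matrix.values, cmap=cmap, vmin=-lim, vmax=lim)
    step = max(1, matrix.dim // 20)
    ax.set_xticks(range(0, matrix.dim, step))
    ax.set_xticklabels(matrix.labels[::step], rotation=90, fontsize=6)
    ax.set_yticks(range(0, matrix.dim, step))
    ax.set_yticklabels(matrix.labels[::step], fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label="coupling")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_di(di: DIMatrix, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(di.values, cmap="viridis")
    ax.set_xlabel("position")
    ax.set_ylabel("position")
    fig.colorbar(im, ax=ax, label="direct information (nats)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
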