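"""Reading, validating and encoding fixed-length nucleotide pools and genomes.

Selected-pool reads (20-mers by default) are encoded as an M x L integer
table over the four-letter RNA alphabet; T and U are a single state.  Model
parameters are serialized to a self-describing text format (versioned header
plus TSV blocks) so that fits can be diffed and round-tripped bit-exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

ALPHABET: tuple[str, ...] = ("A", "C", "G", "U")
Q = len(ALPHABET)

#: canonical base -> index; T and U share one state
NT_TO_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

_AMBIGUITY = set("NRYSWKMBDHV")

_MODEL_MAGIC = "# dcascape coupling model"
_MODEL_VERSION = 1


class SequencePoolError(ValueError):
    """Fatal problem with an input pool or genome file."""


@dataclass
class EncodedSequenceSet:
    """An M x L table of nucleotide indices (the read pool).

    ``data[a, i]`` is the index of the nucleotide at position ``i`` of read
    ``a``.  ``counts`` optionally carries per-row multiplicities; absent
    counts mean every row has multiplicity one.  ``dropped`` reports how
    many input reads were filtered (wrong length or ambiguity codes).
    """

    data: np.ndarray
    alphabet: tuple[str, ...] = ALPHABET
    counts: Optional[np.ndarray] = None
    dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise SequencePoolError("pool must be a non-empty 2-D table of reads")
        if self.data.size and self.data.max() >= len(self.alphabet):
            raise SequencePoolError("encoded entries must lie in {0..q-1}")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (self.data.shape[0],):
                raise SequencePoolError("counts must parallel the rows")
            if (self.counts < 1).any():
                raise SequencePoolError("counts must all be >= 1")

    @property
    def M(self) -> int:
        """Number of reads counting multiplicity."""
        if self.counts is None:
            return self.data.shape[0]
        return int(self.counts.sum())

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    def decode(self, row: int) -> str:
        return "".join(self.alphabet[i] for i in self.data[row])

    def iter_sequences(self) -> Iterator[str]:
        for a in range(self.n_rows):
            yield self.decode(a)

    def collapse(self) -> "EncodedSequenceSet":
        """Collapse identical rows into unique rows with counts (memory mode)."""
        base = self.counts if self.counts is not None else np.ones(self.n_rows, dtype=np.int64)
        uniq, inverse = np.unique(self.data, axis=0, return_inverse=True)
        counts = np.zeros(uniq.shape[0], dtype=np.int64)
        np.add.at(counts, inverse, base)
        return EncodedSequenceSet(uniq, self.alphabet, counts, self.dropped)


@dataclass
class GenomeSequence:
    """A named nucleotide sequence to be scanned (DNA or RNA, ambiguity allowed)."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise SequencePoolError("genome record must have a non-empty identifier")
        self.residues = self.residues.upper()

    @property
    def length(self) -> int:
        return len(self.residues)

    def encode(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (indices, valid) with T normalized to U; ambiguity -> invalid."""
        idx = np.full(self.length, 255, dtype=np.uint8)
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        for base, code in NT_TO_IDX.items():
            idx[arr == ord(base)] = code
        valid = idx != 255
        return idx, valid

    def reverse_complement(self) -> "GenomeSequence":
        comp = str.maketrans("ACGTUNRYSWKMBDHV", "UGCAANYRSWMKVHDB")
        return GenomeSequence(self.identifier, self.residues.translate(comp)[::-1])


def encode_sequences(seqs: Iterable[str], alphabet: tuple[str, ...] = ALPHABET) -> np.ndarray:
    """Encode clean same-length sequences (no filtering) into an index table."""
    rows = []
    for s in seqs:
        rows.append([NT_TO_IDX[c] for c in s.upper()])
    return np.asarray(rows, dtype=np.uint8)


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            return "plain"
    raise SequencePoolError(f"{path}: empty input file")


def _iter_raw_reads(path: Path) -> Iterator[str]:
    fmt = _sniff_format(path)
    if fmt == "plain":
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s:
                    yield s
    else:
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq)


def read_pool(
    path: str | Path,
    expected_length: int = 20,
    on_ambiguous: str = "drop",
) -> EncodedSequenceSet:
    """Read a selected pool (FASTA/FASTQ/one-per-line) into an encoded table.

    Reads of the wrong length are always dropped.  Reads containing
    ambiguity codes are dropped under the default policy, or abort the run
    under ``on_ambiguous="strict"``.  Duplicate reads are kept as separate
    rows: multiplicity in a selected pool is the enrichment signal.
    """
    if expected_length < 2:
        raise SequencePoolError("expected_length must be >= 2")
    if on_ambiguous not in ("drop", "strict"):
        raise SequencePoolError(f"unknown ambiguity policy {on_ambiguous!r}")
    path = Path(path)
    rows: list[list[int]] = []
    dropped = 0
    n_input = 0
    for seq in _iter_raw_reads(path):
        n_input += 1
        s = seq.upper()
        if len(s) != expected_length:
            dropped += 1
            continue
        try:
            rows.append([NT_TO_IDX[c] for c in s])
        except KeyError as exc:
            bad = exc.args[0]
            if on_ambiguous == "strict" or bad not in _AMBIGUITY:
                raise SequencePoolError(
                    f"{path}: read {n_input} contains unsupported character {bad!r}"
                ) from None
            dropped += 1
    if n_input == 0:
        raise SequencePoolError(f"{path}: empty input file")
    if not rows:
        raise SequencePoolError(
            f"{path}: no reads survived the length-{expected_length}/ambiguity filter "
            f"({dropped} dropped)"
        )
    return EncodedSequenceSet(np.asarray(rows, dtype=np.uint8), ALPHABET, None, dropped)


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read one or more genome records from FASTA, in file order."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SequencePoolError(
                    f"{path}: malformed FASTA at line {lineno}: expected '>' header"
                )
            break
        else:
            raise SequencePoolError(f"{path}: empty FASTA")
    records = [GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SequencePoolError(f"{path}: no FASTA records")
    return records


def write_pool_fasta(pool: EncodedSequenceSet, path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for a in range(pool.n_rows):
            n = 1 if pool.counts is None else int(pool.counts[a])
            for r in range(n):
                fh.write(f">{prefix}{a}" + (f"_{r}" if n > 1 else "") + "\n")
                fh.write(pool.decode(a) + "\n")


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.residues[i : i + width] + "\n")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# model serialization: versioned header + TSV blocks, bit-exact round trip
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path, provenance: str = "") -> None:
    """Serialize a coupling model to the text format (header + TSV blocks).

    Floats are written with %.17g, which round-trips IEEE doubles exactly.
    """
    L, q = model.L, len(model.alphabet)
    lines = [
        f"{_MODEL_MAGIC} v{_MODEL_VERSION}",
        f"L\t{L}",
        f"alphabet\t{''.join(model.alphabet)}",
        f"gauge\t{model.gauge_tag}",
        f"pseudocount\t{model.pseudocount:.17g}",
        f"provenance\t{provenance}",
        "[fields]",
        "pos\t" + "\t".join(model.alphabet),
    ]
    for i in range(L):
        lines.append(str(i) + "\t" + "\t".join(f"{v:.17g}" for v in model.fields[i]))
    lines.append("[couplings]")
    lines.append("i\tj\tx\ty\tvalue")
    for i in range(L):
        for j in range(i + 1, L):
            for x in range(q):
                for y in range(q):
                    lines.append(f"{i}\t{j}\t{x}\t{y}\t{model.couplings[i, j, x, y]:.17g}")
    lines.append("[end]")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`; truncation or version drift is fatal."""
    from .dca import CouplingModel  # local import to avoid a cycle

    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith(_MODEL_MAGIC):
        raise SequencePoolError(f"{path}: not a dcascape model file")
    version = text[0].rsplit("v", 1)[-1]
    if int(version) != _MODEL_VERSION:
        raise SequencePoolError(f"{path}: unsupported model format version {version}")
    header: dict[str, str] = {}
    it = iter(enumerate(text[1:], 2))
    for _, line in it:
        if line == "[fields]":
            break
        key, _, val = line.partition("\t")
        header[key] = val
    else:
        raise SequencePoolError(f"{path}: truncated model file (no [fields] block)")
    try:
        L = int(header["L"])
        alphabet = tuple(header["alphabet"])
        gauge_tag = header["gauge"]
        pseudocount = float(header["pseudocount"])
    except KeyError as exc:
        raise SequencePoolError(f"{path}: missing header field {exc}") from None
    q = len(alphabet)
    fields = np.zeros((L, q))
    couplings = np.zeros((L, L, q, q))
    try:
        next(it)  # column header of [fields]
        for i in range(L):
            _, line = next(it)
            parts = line.split("\t")
            fields[int(parts[0])] = [float(v) for v in parts[1:]]
        _, line = next(it)
        if line != "[couplings]":
            raise SequencePoolError(f"{path}: expected [couplings] block")
        next(it)  # column header
        for _ in range(L * (L - 1) // 2 * q * q):
            _, line = next(it)
            i, j, x, y, v = line.split("\t")
            i, j, x, y = int(i), int(j), int(x), int(y)
            couplings[i, j, x, y] = float(v)
            couplings[j, i, y, x] = float(v)
        _, line = next(it)
        if line != "[end]":
            raise SequencePoolError(f"{path}: missing [end] marker")
    except StopIteration:
        raise SequencePoolError(f"{path}: truncated model file") from None
    return CouplingModel(
        couplings=couplings,
        fields=fields,
        alphabet=alphabet,
        gauge_tag=gauge_tag,
        pseudocount=pseudocount,
    )
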