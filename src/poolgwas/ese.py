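"""Position-weight-matrix scanning for exonic splicing enhancer motifs.

SR-protein binding sites such as SC35 are modelled as additive
position-weight matrices: each window of width L scores
sum over positions of weight(position, base), and windows at or above the
matrix's score threshold are reported as hits.  ``allele_contrast`` rescans
the windows overlapping a variant under both alleles and reports hits gained
or lost — the in-silico prediction of whether a risk allele creates or
destroys a splicing-enhancer site.

Matrices are read from a TSV with a ``#name=<motif> threshold=<t>`` header
and four rows (A, C, G, T) of L weights.  Sequences come from FASTA via
Biopython.  Forward strand only: ESE context is the pre-mRNA sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["MotifMatrix", "MotifHit", "scan", "allele_contrast", "synthetic_sc35_like_matrix"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MotifMatrix:
    """Additive PWM: ``weights[pos, base]`` over bases A, C, G, T."""

    name: str
    weights: np.ndarray  # shape (L, 4)
    threshold: float = 2.383

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("weights must have shape (L, 4) with L >= 1")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_tsv(cls, path) -> "MotifMatrix":
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0]
        if not header.startswith("#"):
            raise ValueError("matrix file must start with '#name=... threshold=...'")
        meta = dict(tok.split("=", 1) for tok in header.lstrip("#").split())
        rows = {}
        for line in lines[1:]:
            parts = line.split("\t")
            rows[parts[0].upper()] = [float(x) for x in parts[1:]]
        missing = set(_BASES) - set(rows)
        if missing:
            raise ValueError(f"matrix missing base rows: {sorted(missing)}")
        weights = np.array([rows[b] for b in _BASES]).T
        return cls(meta.get("name", "motif"), weights, float(meta.get("threshold", 2.383)))

    def to_tsv(self, path) -> None:
        lines = [f"#name={self.name} threshold={self.threshold}"]
        for i, b in enumerate(_BASES):
            lines.append("\t".join([b] + [f"{w:g}" for w in self.weights[:, i]]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 1-based
    window: str
    score: float


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    return np.array([_BASE_INDEX.get(ch, -1) for ch in seq], dtype=int)


def scan(sequence: str, matrix: MotifMatrix, seq_id: str = "seq") -> list[MotifHit]:
    """All windows scoring at or above the matrix threshold, in position
    order.  Windows containing N are skipped; a sequence shorter than the
    motif yields no hits."""
    codes = _encode(sequence)
    L = matrix.width
    n_win = len(codes) - L + 1
    hits: list[MotifHit] = []
    for start in range(max(n_win, 0)):
        win = codes[start : start + L]
        if (win < 0).any():
            continue
        score = float(matrix.weights[np.arange(L), win].sum())
        if score >= matrix.threshold:
            hits.append(
                MotifHit(seq_id, start + 1, sequence[start : start + L].upper(), score)
            )
    return hits


def allele_contrast(
    sequence: str,
    position: int,
    ref_base: str,
    alt_base: str,
    matrix: MotifMatrix,
    seq_id: str = "seq",
) -> dict:
    """Compare motif hits between the two alleles of a substitution.

    Scans both allelic sequences over the windows overlapping ``position``
    (1-based), i.e. the slice [position - L + 1, position + L - 1], and
    reports hits unique to each allele as ``gained`` (alt-only) and ``lost``
    (ref-only).
    """
    seq = sequence.upper()
    if not 1 <= position <= len(seq):
        raise IndexError(f"position {position} outside sequence of length {len(seq)}")
    if seq[position - 1] != ref_base.upper():
        raise ValueError(
            f"reference mismatch at {position}: sequence has {seq[position - 1]!r}, "
            f"expected {ref_base!r}"
        )
    L = matrix.width
    lo = max(position - L, 0)  # 0-based start of window region
    hi = min(position - 1 + L, len(seq))

    def region_hits(s: str) -> list[MotifHit]:
        local = scan(s[lo:hi], matrix, seq_id)
        return [MotifHit(h.seq_id, h.start + lo, h.window, h.score) for h in local]

    alt_seq = seq[: position - 1] + alt_base.upper() + seq[position:]
    hits_ref = region_hits(seq)
    hits_alt = region_hits(alt_seq)
    key = lambda h: (h.start, round(h.score, 9))
    ref_keys = {key(h) for h in hits_ref}
    alt_keys = {key(h) for h in hits_alt}
    return {
        "hits_ref": hits_ref,
        "hits_alt": hits_alt,
        "gained": [h for h in hits_alt if key(h) not in ref_keys],
        "lost": [h for h in hits_ref if key(h) not in alt_keys],
    }


def synthetic_sc35_like_matrix(seed: int = 7) -> MotifMatrix:
    """A synthetic stand-in for the SC35 splicing-factor PWM (the published
    scoring matrix is not redistributable): width 8, degenerate
    GC-rich consensus, threshold 2.383."""
    rng = np.random.default_rng(seed)
    consensus = "TGGCCGGG"
    weights = rng.normal(-0.8, 0.4, size=(8, 4))
    for i, b in enumerate(consensus):
        weights[i, _BASE_INDEX[b]] = rng.uniform(0.6, 1.2)
    return MotifMatrix("SC35_synthetic", np.round(weights, 3), threshold=2.383)
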