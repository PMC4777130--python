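"""Position weight matrices: MEME-format I/O, log-odds scanning, hit calls.

Scoring is the sum of per-position log2-odds against a uniform background,
computed on both strands; a promoter's score is the best window on either
strand, so hit decisions are invariant to reverse complementation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
from Bio import motifs as bio_motifs

__all__ = ["PWM", "write_meme", "read_meme", "encode_sequence"]

_ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class PWM:
    name: str
    #: probability matrix, shape (width, 4), columns ordered A C G T
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (width, 4)")
        colsums = self.probs.sum(axis=1)
        if np.any(self.probs < 0) or np.any(colsums <= 0):
            raise ValueError("PWM columns must have positive sums")
        self.probs = self.probs / colsums[:, None]

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       match_prob: float = 0.994) -> "PWM":
        """Near-deterministic PWM whose maximum-score word is `consensus`."""
        w = len(consensus)
        probs = np.full((w, 4), (1.0 - match_prob) / 3.0)
        for i, base in enumerate(consensus.upper()):
            probs[i, _INDEX[base]] = match_prob
        return cls(name, probs)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(np.maximum(self.probs, 1e-12) / 0.25)

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def window_scores(self, seq: str) -> np.ndarray:
        """Forward-strand log-odds score of every window of the sequence."""
        idx = encode_sequence(seq)
        n = idx.size - self.width + 1
        if n <= 0:
            return np.empty(0)
        lo = self.log_odds
        # non-ACGT positions score as background (log-odds 0)
        scores = np.zeros(n)
        for j in range(self.width):
            col = idx[j:j + n]
            valid = col >= 0
            scores[valid] += lo[j, col[valid]]
        return scores

    def best_score(self, seq: str) -> float:
        """Best window score over both strands."""
        from .genome import reverse_complement
        fwd = self.window_scores(seq)
        rev = self.window_scores(reverse_complement(seq))
        best = -np.inf
        if fwd.size:
            best = max(best, float(fwd.max()))
        if rev.size:
            best = max(best, float(rev.max()))
        return best

    def best_scores(self, seqs: Sequence[str]) -> np.ndarray:
        return np.array([self.best_score(s) for s in seqs])

    def has_hit(self, seq: str, threshold: float) -> bool:
        return self.best_score(seq) >= threshold


def write_meme(pwms: Iterable[PWM], path) -> None:
    """Write motifs in minimal MEME text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            # large nsites: Bio.motifs reconstructs integer counts from the
            # probabilities, so a small nsites would round them
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 1000000 E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> List[PWM]:
    """Parse a MEME motif file (minimal format) via Bio.motifs."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        probs = np.array([[m.pwm[ltr][i] for ltr in _ALPHABET]
                          for i in range(m.length)])
        out.append(PWM(m.name, probs))
    return out
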