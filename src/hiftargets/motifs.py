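"""Hypoxia-response-element consensus scanning in peak windows.

HIF binds a short core element (HRE) with consensus RCGTG (R = A/G).
Windows of +/- ``flank_bp`` around each peak center are extracted (masked
bases stay N and never match), scanned on both strands for all — possibly
overlapping — matches of an IUPAC consensus, and tested for enrichment
against per-window mononucleotide-shuffled sequences with an add-one
permutation p-value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from pyfaidx import Fasta

from .core import Peak, ValidationError

DEFAULT_PATTERN = "RCGTG"

# IUPAC nucleotide codes -> the concrete bases they match (N excluded from
# every class on purpose: masked bases never match).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_pattern(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValidationError(f"invalid IUPAC letter {ch!r} in pattern {pattern!r}")
        parts.append(f"[{_IUPAC[ch]}]")
    # lookahead so overlapping matches are all counted
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class MotifHits:
    peak_id: str
    plus_hits: int
    minus_hits: int
    positions: tuple[tuple[int, str], ...]  # (offset, strand)


def scan_consensus(sequence: str, pattern: str = DEFAULT_PATTERN, peak_id: str = "") -> MotifHits:
    """Count all overlapping matches of an IUPAC consensus on both strands.

    Minus-strand hits are matches of the reverse-complement pattern in the
    given (plus-strand) sequence; offsets are reported in plus-strand
    coordinates.  Ns never match.
    """
    seq = sequence.upper()
    plus = [(m.start(1), "+") for m in _pattern_regex(pattern).finditer(seq)]
    minus = [
        (m.start(1), "-")
        for m in _pattern_regex(reverse_complement_pattern(pattern)).finditer(seq)
    ]
    positions = tuple(sorted(plus + minus))
    return MotifHits(peak_id, len(plus), len(minus), positions)


def extract_windows(
    peaks: Sequence[Peak], genome_fasta: str | Path | Mapping[str, str], flank_bp: int
) -> dict[str, str]:
    """+/- flank windows around peak centers, clipped at chromosome ends.

    ``genome_fasta`` may be a FASTA path (read through pyfaidx) or a
    chromosome->sequence mapping.  A chromosome missing from the source
    raises a lookup error.
    """
    if isinstance(genome_fasta, (str, Path)):
        fa = Fasta(str(genome_fasta))

        def get(chrom: str) -> str:
            if chrom not in fa:
                raise KeyError(f"chromosome {chrom!r} absent from FASTA")
            return str(fa[chrom][:])
    else:
        def get(chrom: str) -> str:
            if chrom not in genome_fasta:
                raise KeyError(f"chromosome {chrom!r} absent from sequence mapping")
            return genome_fasta[chrom]

    out = {}
    for p in peaks:
        seq = get(p.chromosome)
        lo = max(0, p.center - flank_bp)
        hi = min(len(seq), p.center + flank_bp + 1)
        out[p.peak_id] = seq[lo:hi].upper()
    return out


def motif_enrichment(
    windows: Mapping[str, str],
    pattern: str = DEFAULT_PATTERN,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Shuffle-null enrichment of total consensus hits across windows.

    Each permutation mononucleotide-shuffles every window independently
    (base composition preserved exactly) and recounts.  Returns
    ``fold = (observed + 1) / (null_mean + 1)`` and the add-one p-value
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValidationError("motif_enrichment: n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def total(ws: Mapping[str, str]) -> int:
        return sum(
            h.plus_hits + h.minus_hits for h in (scan_consensus(s, pattern) for s in ws.values())
        )

    observed = total(windows)
    arrays = [np.frombuffer(s.encode(), dtype=np.uint8) for s in windows.values()]
    null_counts = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        shuffled = {
            str(i): rng.permutation(a).tobytes().decode() for i, a in enumerate(arrays)
        }
        null_counts[b] = total(shuffled)
    null_mean = float(null_counts.mean())
    fold = (observed + 1) / (null_mean + 1)
    p = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
    return float(fold), float(p)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
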