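"""Prophage discovery from attachment-site direct repeats.

Temperate phages of the family studied here integrate at a single
conserved attachment site marked by a 12-bp motif: the integrated prophage
is flanked by the motif as a direct repeat (attL/attR), and phage-free
strains carry one copy (attB) inside a tRNA-Leu locus.  This module finds
motif hits on both strands, pairs same-strand hits at prophage-like
separations into prophage calls, annotates attB sites with tRNA context,
and rotates excised circular prophage sequences to a reference origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from rhizophage.io import Feature, GenomeRecord

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start`` is on the forward strand."""

    genome_id: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class ProphageCall:
    """One detected prophage.

    ``prophage_interval`` spans attL through attR inclusive of both motif
    copies; ``excised_seq`` is the circularised excision product carrying
    one motif copy (attL start to attR start), mirroring the circular
    phage; ``length`` is its length.
    """

    genome_id: str
    attL: tuple[int, int]
    attR: tuple[int, int]
    prophage_interval: tuple[int, int]
    excised_seq: str
    length: int
    strand: str
    mismatches: tuple[int, int]

    @property
    def interior_seq(self) -> str:
        """Sequence strictly between the two att copies."""
        return self.excised_seq[self.attL[1] - self.attL[0]:]


@dataclass(frozen=True)
class AttBSite:
    """A candidate bacterial attachment site."""

    genome_id: str
    position: int
    strand: str
    within_tRNA: bool
    tRNA_label: str | None


def _scan_motif_array(
    arr: np.ndarray, motif: str, max_mismatch: int
) -> list[tuple[int, str, int]]:
    """Vectorised double-strand Hamming scan of a byte array.

    Returns ``(start, strand, mismatches)`` triples sorted by start; the
    start is always the forward-strand coordinate of the matched window.
    """
    a = arr.view(np.uint8)
    n, m = len(a), len(motif)
    if n < m:
        return []
    hits = []
    for strand, pat in (("+", motif), ("-", _revcomp(motif))):
        pat_b = np.frombuffer(pat.encode(), dtype=np.uint8)
        mm = np.zeros(n - m + 1, dtype=np.int32)
        for j in range(m):
            mm += a[j:n - m + 1 + j] != pat_b[j]
        for start in np.nonzero(mm <= max_mismatch)[0]:
            hits.append((int(start), strand, int(mm[start])))
    hits.sort()
    return hits


def find_motif(
    genome: GenomeRecord, motif: str, max_mismatch: int = 1
) -> list[MotifHit]:
    """All occurrences of ``motif`` on either strand within a Hamming
    distance of ``max_mismatch``, sorted by start coordinate."""
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over ACGT")
    if len(motif) < 8:
        raise ValueError("motif must be at least 8 bp")
    if max_mismatch > 2:
        raise ValueError("max_mismatch above 2 makes a 12-mer uninformative")
    arr = np.frombuffer(genome.seq.encode(), dtype="S1")
    return [
        MotifHit(genome.id, start, strand, mm)
        for start, strand, mm in _scan_motif_array(arr, motif, max_mismatch)
    ]


def call_prophages(
    genome: GenomeRecord,
    motif: str,
    size_window: tuple[int, int] = (30_000, 60_000),
    max_mismatch: int = 1,
) -> list[ProphageCall]:
    """Pair same-strand direct-repeat motif hits into prophage calls.

    Every pair of same-strand hits whose separation (attL start to attR
    start, i.e. the excised length) lies inside ``size_window`` is a
    candidate.  Overlap resolution keeps the shortest call per attL, then
    greedily discards calls overlapping an already-accepted one (nested
    repeats otherwise create spurious giant calls).  Opposite-strand
    (inverted-repeat) pairings at the same separations are logged as
    warnings, not called: att sites are direct repeats by integrase
    biology.
    """
    lo, hi = size_window
    if not lo < hi:
        raise ValueError("size_window must satisfy min < max")
    m = len(motif)
    hits = find_motif(genome, motif, max_mismatch)
    candidates = []
    for i, h1 in enumerate(hits):
        for h2 in hits[i + 1:]:
            sep = h2.start - h1.start
            if sep > hi:
                break
            if sep < lo:
                continue
            if h1.strand != h2.strand:
                logger.warning(
                    "%s: inverted-repeat motif pair at %d/%d ignored",
                    genome.id, h1.start, h2.start,
                )
                continue
            candidates.append((h1, h2, sep))
    # shortest call per attL
    by_attL: dict[int, tuple] = {}
    for h1, h2, sep in candidates:
        cur = by_attL.get(h1.start)
        if cur is None or sep < cur[2]:
            by_attL[h1.start] = (h1, h2, sep)
    calls: list[ProphageCall] = []
    occupied: list[tuple[int, int]] = []
    for start in sorted(by_attL):
        h1, h2, sep = by_attL[start]
        interval = (h1.start, h2.start + m)
        if any(interval[0] < e and s < interval[1] for s, e in occupied):
            continue
        occupied.append(interval)
        calls.append(
            ProphageCall(
                genome_id=genome.id,
                attL=(h1.start, h1.start + m),
                attR=(h2.start, h2.start + m),
                prophage_interval=interval,
                excised_seq=genome.seq[h1.start:h2.start],
                length=sep,
                strand=h1.strand,
                mismatches=(h1.mismatches, h2.mismatches),
            )
        )
    return calls


def find_attB(
    genome: GenomeRecord,
    motif: str,
    trna_features: list[Feature] | None = None,
    max_mismatch: int = 1,
) -> list[AttBSite]:
    """Annotate motif hits with tRNA context.

    ``within_tRNA`` is true when the hit overlaps an intact tRNA feature
    (features labelled ``*_interrupted`` by prophage integration do not
    count).  Features default to the genome's own annotation.
    """
    feats = genome.features if trna_features is None else trna_features
    trnas = [f for f in feats if f.type == "tRNA"]
    m = len(motif)
    sites = []
    for hit in find_motif(genome, motif, max_mismatch):
        overlapping = [
            f for f in trnas if f.start < hit.start + m and hit.start < f.end
        ]
        intact = [f for f in overlapping if not f.label.endswith("_interrupted")]
        sites.append(
            AttBSite(
                genome_id=genome.id,
                position=hit.start,
                strand=hit.strand,
                within_tRNA=bool(intact),
                tRNA_label=(intact or overlapping)[0].label if overlapping else None,
            )
        )
    return sites


class RotationResult(NamedTuple):
    seq: str
    offset: int
    strand: str
    votes: int


def rotate_to_reference(
    excised_seq: str,
    reference: GenomeRecord | str,
    k: int = 13,
    min_votes: int = 5,
) -> RotationResult:
    """Rotate a circular excised prophage to a reference origin.

    Shared k-mers vote for the circular offset aligning the excision to
    the reference start; the winning offset (on whichever strand scores
    higher) is applied.  Robust to point divergence at the few-percent
    level since only a fraction of k-mers need to survive.  Raises
    ``ValueError`` when too few k-mers agree (unrelated sequence).
    """
    ref_seq = reference.seq if isinstance(reference, GenomeRecord) else reference
    if not excised_seq or not ref_seq:
        raise ValueError("both sequences must be non-empty")
    index: dict[str, list[int]] = {}
    for j in range(len(ref_seq) - k + 1):
        index.setdefault(ref_seq[j:j + k], []).append(j)

    def best_offset(seq: str) -> tuple[int, int]:
        L = len(seq)
        doubled = seq + seq[:k - 1]
        votes: dict[int, int] = {}
        for i in range(L):
            for j in index.get(doubled[i:i + k], ()):
                off = (i - j) % L
                votes[off] = votes.get(off, 0) + 1
        if not votes:
            return 0, 0
        off = min(votes, key=lambda o: (-votes[o], o))
        return off, votes[off]

    fwd_off, fwd_votes = best_offset(excised_seq)
    rc = _revcomp(excised_seq)
    rev_off, rev_votes = best_offset(rc)
    if max(fwd_votes, rev_votes) < min_votes:
        raise ValueError(
            "unrelated sequence: too few shared k-mers with the reference"
        )
    if fwd_votes >= rev_votes:
        seq, off, strand = excised_seq, fwd_off, "+"
    else:
        seq, off, strand = rc, rev_off, "-"
    return RotationResult(seq[off:] + seq[:off], off, strand,
                          max(fwd_votes, rev_votes))
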