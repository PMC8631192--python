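"""Pairwise intergenomic nucleotide similarity and threshold clustering.

A VIRIDIC-style measure: each genome is cut into non-overlapping
fragments; each fragment is aligned to the other genome (k-mer seeding to
pick a strand and diagonal, then a banded edit-distance alignment of the
candidate window); the directional similarity is the percent identity over
aligned columns scaled by the fraction of the genome that aligned, and the
reported value averages both directions.  The measure is self-contained
and declared "VIRIDIC-style": it follows VIRIDIC's intergenomic-similarity
definition in spirit but is not bit-identical to its BLASTN backend.

Thresholds follow phage taxonomy practice: genomes sharing >= 70%
intergenomic similarity fall in one genus-level cluster, < 95-97%
separates species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimilarityMatrix:
    """Symmetric intergenomic similarity in percent, with aligned fractions."""

    ids: list[str]
    matrix: np.ndarray
    aligned_fraction: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - k + 1):
        index.setdefault(seq[j:j + k], []).append(j)
    return index


def _align_fragment(
    frag: str,
    target: str,
    index: dict[str, list[int]],
    k: int,
    max_divergence: float,
    pad: int,
    seed_stride: int,
) -> tuple[int, int] | None:
    """Best (identities, columns) for one fragment against one strand
    of the target, or ``None`` if unaligned."""
    votes: Counter = Counter()
    for i in range(0, len(frag) - k + 1, seed_stride):
        for j in index.get(frag[i:i + k], ()):
            votes[(j - i) // pad] += 1
    if not votes:
        return None
    bucket = min(votes, key=lambda b: (-votes[b], b))
    diag = bucket * pad
    lo = max(0, diag - pad)
    hi = min(len(target), diag + len(frag) + 2 * pad)
    window = target[lo:hi]
    if len(window) < k:
        return None
    max_dist = int(max_divergence * len(frag))
    res = edlib.align(frag, window, mode="HW", task="distance", k=max_dist)
    if res["editDistance"] < 0:
        return None
    cols = len(frag)
    return cols - res["editDistance"], cols


def _directional(
    query: str,
    target: str,
    fragment_len: int,
    k: int,
    max_divergence: float,
    seed_stride: int,
) -> tuple[float, float]:
    """(similarity %, aligned fraction) of query fragments against target."""
    pad = 150
    idx_fwd = _kmer_index(target, k)
    target_rc = _revcomp(target)
    idx_rev = _kmer_index(target_rc, k)
    identities = 0
    aligned_cols = 0
    total = 0
    for s in range(0, len(query), fragment_len):
        frag = query[s:s + fragment_len]
        if len(frag) < k:
            continue
        total += len(frag)
        best = None
        for tgt, idx in ((target, idx_fwd), (target_rc, idx_rev)):
            res = _align_fragment(
                frag, tgt, idx, k, max_divergence, pad, seed_stride
            )
            if res is not None and (best is None or res[0] > best[0]):
                best = res
        if best is not None:
            identities += best[0]
            aligned_cols += best[1]
    if total == 0 or aligned_cols == 0:
        return 0.0, 0.0
    identity_frac = identities / aligned_cols
    aligned_frac = aligned_cols / total
    return 100.0 * identity_frac * aligned_frac, aligned_frac


def pair_similarity(
    a, b,
    fragment_len: int = 1000,
    k: int = 11,
    max_divergence: float = 0.4,
    seed_stride: int = 7,
) -> tuple[float, float]:
    """Intergenomic similarity (percent) and aligned fraction of two genomes.

    Fragments whose best window alignment exceeds ``max_divergence``
    (edit distance per fragment base) count as unaligned, which drives
    the similarity of unrelated sequences toward zero through the
    aligned-fraction weighting.  Accepts :class:`~rhizophage.io.GenomeRecord`
    or plain sequences.
    """
    seq_a = a.seq if hasattr(a, "seq") else a
    seq_b = b.seq if hasattr(b, "seq") else b
    if len(seq_a) < fragment_len or len(seq_b) < fragment_len:
        raise ValueError("both genomes must be at least one fragment long")
    s_ab, f_ab = _directional(
        seq_a, seq_b, fragment_len, k, max_divergence, seed_stride
    )
    s_ba, f_ba = _directional(
        seq_b, seq_a, fragment_len, k, max_divergence, seed_stride
    )
    return 0.5 * (s_ab + s_ba), 0.5 * (f_ab + f_ba)


def similarity_matrix(genomes, **kwargs) -> SimilarityMatrix:
    """All-pairs intergenomic similarity, symmetrised by construction."""
    ids = [g.id for g in genomes]
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(genomes)
    mat = np.full((n, n), 100.0)
    frac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim, af = pair_similarity(genomes[i], genomes[j], **kwargs)
            mat[i, j] = mat[j, i] = sim
            frac[i, j] = frac[j, i] = af
    return SimilarityMatrix(ids, mat, frac)


def cluster_at(matrix: SimilarityMatrix, threshold: float) -> list[list[str]]:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever similarity >= threshold."""
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    n = len(matrix.ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.matrix[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(matrix.ids[i])
    return sorted(groups.values(), key=lambda g: (-len(g), g))
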