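"""GC-content windowing and the early-vs-rest-of-genome comparison.

T7-like phage genomes are organised into early, middle and late gene
classes by transcription timing.  In the family analysed here the early
region is hypervariable and markedly GC-poor relative to the rest of the
genome — the signature of recent horizontal acquisition.  This module
computes binned GC profiles, per-region GC means, and a paired t-test of
early vs rest across a panel of genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rhizophage.io import GenomeRecord

logger = logging.getLogger(__name__)

REGION_LABELS = ("early", "middle", "late")


@dataclass
class RegionModel:
    """Labelled early/middle/late intervals on one genome.

    Intervals are 0-based half-open and must not overlap; at least one
    ``early`` interval is required.  A label may own several disjoint
    intervals (split genes); its GC is computed over their union.
    """

    genome_id: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.intervals) - set(REGION_LABELS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")
        if "early" not in self.intervals or not self.intervals["early"]:
            raise ValueError(f"{self.genome_id}: region model lacks an early interval")
        spans = sorted(
            iv for ivs in self.intervals.values() for iv in ivs
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.genome_id}: overlapping region intervals "
                    f"({s1},{e1}) and ({s2},{e2})"
                )

    @classmethod
    def from_features(cls, genome: GenomeRecord) -> "RegionModel":
        """Build from a genome's ``region``-type features."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        for f in genome.features:
            if f.type == "region" and f.label in REGION_LABELS:
                intervals.setdefault(f.label, []).append((f.start, f.end))
        return cls(genome.id, intervals)


@dataclass
class GCProfile:
    """Binned GC fractions for one genome.

    N bases are excluded from both numerator and denominator; a bin of
    all-N bases has GC ``nan``.  ``genome_mean`` is the GC over all non-N
    bases and equals the weight-averaged bin values.
    """

    genome_id: str
    bin_size: int
    bin_gc: np.ndarray
    bin_weights: np.ndarray  # non-N bases per bin
    genome_mean: float


def _gc_mask(seq: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (a == b"G") | (a == b"C")
    informative = a != b"N"
    return is_gc, informative


def gc_windows(genome: GenomeRecord, bin_size: int = 250) -> GCProfile:
    """GC fraction in consecutive ``bin_size``-bp windows.

    The trailing partial bin is included and carries its own (smaller)
    weight in the genome mean.
    """
    if bin_size < 10:
        raise ValueError("bin_size must be >= 10")
    is_gc, informative = _gc_mask(genome.seq)
    if not informative.any():
        raise ValueError(f"{genome.id}: all-N sequence has undefined GC")
    n = len(genome.seq)
    edges = list(range(0, n, bin_size)) + [n]
    gc = np.empty(len(edges) - 1)
    weights = np.empty(len(edges) - 1)
    for i, (s, e) in enumerate(zip(edges, edges[1:])):
        w = informative[s:e].sum()
        weights[i] = w
        gc[i] = is_gc[s:e].sum() / w if w else np.nan
    mean = float(is_gc[informative].sum() / informative.sum())
    return GCProfile(genome.id, bin_size, gc, weights, mean)


def region_gc(genome: GenomeRecord, model: RegionModel) -> dict[str, float]:
    """Per-label GC means, plus ``rest`` = complement of the early region.

    Labels whose intervals contain no informative bases are omitted with
    a warning.
    """
    is_gc, informative = _gc_mask(genome.seq)
    n = len(genome.seq)
    out: dict[str, float] = {}
    early_mask = np.zeros(n, dtype=bool)
    for label, ivs in model.intervals.items():
        mask = np.zeros(n, dtype=bool)
        for s, e in ivs:
            if not (0 <= s < e <= n):
                raise ValueError(
                    f"{genome.id}: region interval ({s},{e}) outside genome"
                )
            mask[s:e] = True
        if label == "early":
            early_mask = mask
        sel = mask & informative
        if not sel.any():
            logger.warning("%s: region %r empty, omitted", genome.id, label)
            continue
        out[label] = float(is_gc[sel].sum() / sel.sum())
    rest = ~early_mask & informative
    if rest.any():
        out["rest"] = float(is_gc[rest].sum() / rest.sum())
    return out


@dataclass
class PairedGCTest:
    """Paired early-vs-rest comparison across a genome panel."""

    t: float
    df: int
    p: float
    per_genome: pd.DataFrame  # genome_id, early, rest
    early_mean: float
    early_sd: float
    rest_mean: float
    rest_sd: float


def compare_early_vs_rest(
    panel: list[tuple[GenomeRecord, RegionModel]]
) -> PairedGCTest:
    """Two-sided paired t-test of early-region vs rest-of-genome GC.

    One (early, rest) pair per genome; df = n - 1, matching the paired
    design.  The statistic is computed on rest minus early, so a GC-poor
    early region yields a positive t.  Genomes lacking an early interval
    or a non-empty rest are excluded with a warning; at least two usable
    genomes are required.
    """
    rows = []
    for genome, model in panel:
        gcs = region_gc(genome, model)
        if "early" not in gcs or "rest" not in gcs:
            logger.warning(
                "%s: missing early or rest GC, excluded from the paired test",
                genome.id,
            )
            continue
        rows.append((genome.id, gcs["early"], gcs["rest"]))
    if len(rows) < 2:
        raise ValueError("need at least 2 genomes with early and rest GC")
    df_tab = pd.DataFrame(rows, columns=["genome_id", "early", "rest"])
    early = df_tab["early"].to_numpy()
    rest = df_tab["rest"].to_numpy()
    if np.allclose(early, rest):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(rest, early)
    return PairedGCTest(
        t=float(t),
        df=len(rows) - 1,
        p=float(p),
        per_genome=df_tab,
        early_mean=float(early.mean()),
        early_sd=float(early.std(ddof=1)),
        rest_mean=float(rest.mean()),
        rest_sd=float(rest.std(ddof=1)),
    )
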