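"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of a temperate-phage
characterisation study on rhizobia: host chromosomes carrying a 12-bp
attachment motif inside a tRNA-Leu locus, 42-45 kb prophages flanked by
that motif as a direct repeat with a GC-poor early region, lysis/lysogeny
OD600 dynamics, step-shaped one-step PFU curves, and host/phage tree pairs
evolved under explicit cospeciation/transfer/duplication/loss dynamics.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rhizophage.io import AssayTable, Feature, GenomeRecord, TreeNode, TreePair

logger = logging.getLogger(__name__)

DEFAULT_ATT_MOTIF = "CAGATTTAGGTT"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Genomes


@dataclass
class ProphageTemplate:
    """Blueprint for a synthetic temperate-phage genome.

    ``length`` is drawn uniformly from ``length_range`` when ``None``.
    ``region_fracs`` partitions the genome into early/middle/late intervals
    as fractions of the length; ``gc_by_region`` gives the target GC
    fraction of each region (defaults: GC-poor early region at 0.5432,
    the rest at 0.5995, matching a T7-like genome whose early genes were
    recently acquired horizontally).
    """

    length: int | None = None
    length_range: tuple[int, int] = (42000, 45000)
    att_motif: str = DEFAULT_ATT_MOTIF
    region_fracs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "early": (0.0, 0.19),
            "middle": (0.19, 0.55),
            "late": (0.55, 1.0),
        }
    )
    gc_by_region: dict[str, float] = field(
        default_factory=lambda: {"early": 0.5432, "middle": 0.5995, "late": 0.5995}
    )

    def __post_init__(self) -> None:
        if len(self.att_motif) < 8:
            raise ValueError("att motif must be at least 8 bp")
        if set(self.att_motif) - set("ACGT"):
            raise ValueError("att motif must be over ACGT")
        bounds = sorted(self.region_fracs.values())
        if bounds[0][0] != 0.0 or bounds[-1][1] != 1.0:
            raise ValueError("region fractions must cover [0, 1)")
        for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
            if e1 != s2:
                raise ValueError("region fractions must partition [0, 1)")
        for label, gc in self.gc_by_region.items():
            if not 0 < gc < 1:
                raise ValueError(f"region {label!r}: GC must be in (0, 1)")
        if set(self.gc_by_region) != set(self.region_fracs):
            raise ValueError("gc_by_region labels must match region_fracs")

    def bounds_for(self, length: int) -> dict[str, tuple[int, int]]:
        out = {}
        for label, (f0, f1) in self.region_fracs.items():
            out[label] = (int(round(f0 * length)), int(round(f1 * length)))
        return out


def _random_seq_exact_gc(n: int, gc: float, rng) -> np.ndarray:
    """Length-n base array (bytes) whose GC count is round(gc * n)."""
    n_gc = int(round(gc * n))
    arr = np.empty(n, dtype="S1")
    gc_bases = rng.choice([b"G", b"C"], size=n_gc)
    at_bases = rng.choice([b"A", b"T"], size=n - n_gc)
    arr[:n_gc] = gc_bases
    arr[n_gc:] = at_bases
    rng.shuffle(arr)
    return arr


def _screen_motif(arr: np.ndarray, motif: str, rng, max_mismatch: int = 1,
                  keep: tuple[int, int] | None = None) -> None:
    """Shuffle away near-occurrences of ``motif`` (both strands), in place.

    Shuffling a window permutes its own bases, so regional GC content is
    preserved exactly.  ``keep`` protects one interval (an intended att
    site) from screening.
    """
    from rhizophage.prophage import _scan_motif_array

    for _ in range(200):
        hits = _scan_motif_array(arr, motif, max_mismatch)
        if keep is not None:
            hits = [h for h in hits if not (keep[0] <= h[0] < keep[1])]
        if not hits:
            return
        for start, _strand, _mm in hits:
            window = arr[start:start + len(motif)].copy()
            rng.shuffle(window)
            arr[start:start + len(motif)] = window
    raise RuntimeError("could not screen out att motif occurrences")


def gen_phage_genome(
    template: ProphageTemplate | None = None, seed: int = 0
) -> GenomeRecord:
    """Generate a phage genome with region-structured GC content.

    The per-region GC fraction equals the template target to within
    rounding; no internal occurrence of the att motif (within one
    mismatch, either strand) survives screening.  Region annotations are
    attached as features of type ``region``.
    """
    template = template or ProphageTemplate()
    rng = np.random.default_rng(seed)
    length = template.length
    if length is None:
        lo, hi = template.length_range
        length = int(rng.integers(lo, hi + 1))
    bounds = template.bounds_for(length)
    arr = np.empty(length, dtype="S1")
    for label, (s, e) in bounds.items():
        arr[s:e] = _random_seq_exact_gc(e - s, template.gc_by_region[label], rng)
    _screen_motif(arr, template.att_motif, rng)
    features = [
        Feature("region", s, e, "+", label)
        for label, (s, e) in sorted(bounds.items(), key=lambda kv: kv[1])
    ]
    return GenomeRecord(
        id=f"phage_seed{seed}",
        seq=arr.tobytes().decode(),
        circular=True,
        features=features,
    )


def gen_host_genome(
    length: int = 100_000,
    gc: float = 0.607,
    att_motif: str = DEFAULT_ATT_MOTIF,
    att_pos: int | None = None,
    trna_len: int = 85,
    seed: int = 0,
) -> GenomeRecord:
    """Generate a phage-free host chromosome segment.

    The genome carries the att motif exactly once (attB), inside a
    tRNA-Leu feature starting shortly before it; all other near-matches of
    the motif (within one mismatch, either strand) are screened out so the
    synthetic host has a single unambiguous attachment site.
    """
    rng = np.random.default_rng(seed)
    if att_pos is None:
        att_pos = int(rng.integers(length // 4, length // 2))
    m = len(att_motif)
    if not (trna_len // 3 <= att_pos and att_pos + m <= length):
        raise ValueError("att position outside genome")
    arr = _random_seq_exact_gc(length, gc, rng)
    arr[att_pos:att_pos + m] = np.frombuffer(att_motif.encode(), dtype="S1")
    _screen_motif(arr, att_motif, rng, keep=(att_pos, att_pos + m))
    trna_start = max(0, att_pos - (trna_len - m) // 2)
    trna_end = min(length, trna_start + trna_len)
    features = [Feature("tRNA", trna_start, trna_end, "+", "tRNA-Leu")]
    return GenomeRecord(
        id=f"host_seed{seed}", seq=arr.tobytes().decode(), circular=False,
        features=features,
    )


def implant_prophage(
    host: GenomeRecord,
    phage: GenomeRecord,
    att_motif: str = DEFAULT_ATT_MOTIF,
    site: int | None = None,
    att_mismatches: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> GenomeRecord:
    """Integrate a phage genome at the host att site.

    Emulates site-specific integration: the single host att motif (attB)
    becomes the left attachment site, and the phage sequence is inserted
    followed by a second motif copy (attR), so the lysogen carries the
    phage flanked by a direct repeat.  ``att_mismatches`` optionally
    substitutes that many bases into the attL/attR copies (to model
    slightly degenerate sites).  A tRNA feature overlapping the site is
    marked interrupted.
    """
    m = len(att_motif)
    occurrences = []
    start = host.seq.find(att_motif)
    while start != -1:
        occurrences.append(start)
        start = host.seq.find(att_motif, start + 1)
    if site is None:
        if len(occurrences) != 1:
            raise ValueError(
                f"host {host.id!r} carries {len(occurrences)} att motif "
                "occurrences; need exactly one"
            )
        site = occurrences[0]
    elif site not in occurrences:
        raise ValueError(f"no att motif at position {site} in host {host.id!r}")
    in_trna = any(
        f.type == "tRNA" and f.start <= site and site + m <= f.end
        for f in host.features
    )
    if not in_trna:
        logger.warning(
            "implant site %d in %s is not inside a tRNA feature", site, host.id
        )
    rng = np.random.default_rng(seed)

    def mutate(copy: str, n_mut: int) -> str:
        out = list(copy)
        for pos in rng.choice(m, size=n_mut, replace=False):
            out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
        return "".join(out)

    att_l = mutate(att_motif, att_mismatches[0])
    att_r = mutate(att_motif, att_mismatches[1])
    new_seq = (
        host.seq[:site] + att_l + phage.seq + att_r + host.seq[site + m:]
    )
    shift = len(phage.seq) + m
    features = []
    for f in host.features:
        if f.start < site + m and f.end > site:
            features.append(
                Feature(f.type, f.start, min(f.end, site + m), f.strand,
                        f.label + "_interrupted")
            )
        elif f.start >= site + m:
            features.append(
                Feature(f.type, f.start + shift, f.end + shift, f.strand, f.label)
            )
        else:
            features.append(f)
    return GenomeRecord(
        id=host.id + "_lysogen", seq=new_seq, circular=host.circular,
        features=features,
    )


# ---------------------------------------------------------------------------
# Infection dynamics (OD600)


@dataclass
class InfectionParams:
    """Kinetic parameters of the phage-bacteria OD model.

    Units: rates per hour; densities in OD600-equivalent units (free phage
    are carried in the same scaled units, with ``burst_size`` phage-unit
    yield per lysed cell-unit).  ``lysogenization_prob`` is the fraction of
    infections that lysogenise rather than lyse; 0 disables lysogeny.
    """

    growth_rate: float = 0.3          # r, 1/h
    carrying_capacity: float = 1.0    # K, OD600
    adsorption_rate: float = 5.0      # per (OD x h)
    burst_size: float = 50.0          # scaled yield per lysed unit
    latent_min: float = 50.0          # carried for reference; the 3-
                                      # compartment model has no delay term
    lysogenization_prob: float = 0.01  # q
    decay_rate: float = 0.05          # free-phage decay, 1/h
    s0: float = 0.05                  # initial susceptible density (OD)
    moi: float = 0.1                  # initial phage:bacteria ratio

    def __post_init__(self) -> None:
        for name in (
            "growth_rate", "carrying_capacity", "adsorption_rate",
            "burst_size", "decay_rate", "s0", "moi",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.lysogenization_prob <= 1:
            raise ValueError("lysogenization_prob must be in [0, 1]")


def _infection_rhs(state, p: InfectionParams):
    s, lg, ph = state
    total = s + lg
    logistic = 1.0 - total / p.carrying_capacity
    inf = p.adsorption_rate * s * ph
    ds = p.growth_rate * s * logistic - inf
    dlg = p.growth_rate * lg * logistic + p.lysogenization_prob * inf
    dph = (
        (1.0 - p.lysogenization_prob) * inf * p.burst_size
        - inf
        - p.decay_rate * ph
    )
    return np.array([ds, dlg, dph])


def sim_infection_od(
    params: InfectionParams | None = None,
    horizon_h: float = 72.0,
    step_min: float = 20.0,
    n_rep: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    phage_id: str = "phage",
    host_id: str = "host",
) -> AssayTable:
    """Simulate paired phage+/phage- OD600 growth series.

    Three-compartment model (susceptible cells, lysogens, free phage)
    integrated with fixed-step RK4; lysogens inherit the host growth rate
    and are immune to superinfection.  With lysogeny enabled the phage+
    culture crashes then recovers as lysogens take over; with
    ``lysogenization_prob = 0`` it crashes without recovery.  Observations
    carry multiplicative lognormal noise.
    """
    params = params or InfectionParams()
    if step_min <= 0:
        raise ValueError("step_min must be positive")
    rng = np.random.default_rng(seed)
    dt_h = 0.5 / 60.0
    times_min = np.arange(0.0, horizon_h * 60.0 + 1e-9, step_min)
    rows = []
    for rep in range(1, n_rep + 1):
        for treatment in ("phage+", "phage-"):
            p0 = params.s0 * params.moi if treatment == "phage+" else 0.0
            state = np.array([params.s0, 0.0, p0])
            traj = {0.0: state[0] + state[1]}
            t = 0.0
            next_idx = 1
            n_steps = int(round(horizon_h / dt_h))
            for _ in range(n_steps):
                k1 = _infection_rhs(state, params)
                k2 = _infection_rhs(state + 0.5 * dt_h * k1, params)
                k3 = _infection_rhs(state + 0.5 * dt_h * k2, params)
                k4 = _infection_rhs(state + dt_h * k3, params)
                state = state + (dt_h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                state = np.maximum(state, 0.0)
                t += dt_h
                while (
                    next_idx < len(times_min)
                    and t * 60.0 + 1e-6 >= times_min[next_idx]
                ):
                    traj[times_min[next_idx]] = state[0] + state[1]
                    next_idx += 1
            noise = np.exp(rng.normal(0.0, noise_sd, size=len(times_min)))
            series_id = f"{phage_id}_{host_id}_r{rep}_{treatment}"
            for (tm, od), eps in zip(sorted(traj.items()), noise):
                rows.append(
                    (series_id, phage_id, host_id, rep, tm, od * eps, treatment)
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "series_id", "phage_id", "host_id", "replicate", "time",
            "value", "treatment",
        ],
    )
    return AssayTable(df)


# ---------------------------------------------------------------------------
# One-step growth curves (PFU)


def sim_one_step(
    latent_min: float = 50.0,
    burst_size: float = 255.0,
    i0: float = 1e4,
    step_min: float = 30.0,
    horizon_min: float = 480.0,
    rise_min: float = 30.0,
    noise_sd: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
    phage_id: str = "phage",
    host_id: str = "host",
) -> AssayTable:
    """Simulate a one-step growth curve: flat at ``i0`` infected centres
    until the latent period ends, then a single lysis wave raising PFU to
    ``i0 * burst_size``.

    The rise follows a smooth sigmoidal step in log10 space over
    ``rise_min`` minutes, so the plateau/baseline ratio equals
    ``burst_size`` exactly in the noise-free limit.  Noise is
    multiplicative lognormal with sd ``noise_sd``.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    if burst_size < 1:
        raise ValueError("burst_size must be >= 1")
    if latent_min >= horizon_min:
        raise ValueError("latent period must be shorter than the horizon")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon_min + 1e-9, step_min)
    u = np.clip((times - latent_min) / rise_min, 0.0, 1.0)
    g = 3 * u**2 - 2 * u**3  # smooth step: 0 before lysis, 1 after
    expected = i0 * burst_size**g
    rows = []
    for rep in range(1, n_rep + 1):
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(times)))
        series_id = f"{phage_id}_onestep_r{rep}"
        for t, v, eps in zip(times, expected, noise):
            rows.append((series_id, phage_id, host_id, rep, t, v * eps, "phage+"))
    df = pd.DataFrame(
        rows,
        columns=[
            "series_id", "phage_id", "host_id", "replicate", "time",
            "value", "treatment",
        ],
    )
    return AssayTable(df)


# ---------------------------------------------------------------------------
# Cophylogeny scenarios


@dataclass
class CophyloSimParams:
    """Rates for the host/phage co-diversification simulator.

    ``transfer``, ``duplication`` and ``loss`` are per-edge-traversal
    probabilities (at most one event is drawn per phage lineage per host
    edge); their sum must not exceed 1.
    """

    n_host_tips: int = 8
    transfer: float = 0.0
    duplication: float = 0.0
    loss: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host_tips < 2:
            raise ValueError("need at least 2 host tips")
        for name in ("transfer", "duplication", "loss"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.transfer + self.duplication + self.loss > 1:
            raise ValueError("event probabilities must sum to <= 1")


@dataclass
class CophylogenyScenario:
    """A simulated tree pair plus its true event history (ground truth)."""

    pair: TreePair
    true_events: dict[str, int]
    event_log: list[tuple[str, str]]

    def true_cost(self, costs) -> float:
        return costs.of(self.true_events)


class _HostNode:
    __slots__ = ("name", "children", "t_start", "t_end")

    def __init__(self, name, t_start):
        self.name = name
        self.children: list[_HostNode] = []
        self.t_start = t_start
        self.t_end = None


def _yule_host_tree(n_tips: int, rng) -> tuple[_HostNode, list[_HostNode]]:
    """Timed pure-birth tree: each extant lineage splits at rate 1."""
    counter = [0]

    def new_node(t):
        counter[0] += 1
        return _HostNode(f"H{counter[0]}", t)

    root = new_node(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.t_end = t
        for _ in range(2):
            child = new_node(t)
            node.children.append(child)
            active.append(child)
    t_present = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.t_end = t_present
    return root, active


class _PhageLineage:
    __slots__ = ("kind", "children", "host", "tip_name")

    def __init__(self, kind, host, children=None):
        self.kind = kind      # cospeciation | duplication | transfer | tip | loss
        self.host = host      # _HostNode whose edge the event sits on
        self.children = children or []
        self.tip_name = None


def sim_cophylogeny(params: CophyloSimParams) -> CophylogenyScenario:
    """Evolve a phage lineage down a simulated host tree.

    The host tree is a timed pure-birth (Yule) tree.  A single phage
    lineage enters at the root and cospeciates at every host split; on
    each host edge it may (with the configured probabilities) be lost,
    duplicate, or transfer at a uniform time to a host edge alive at that
    moment, excluding the donor edge.  The full event history, including
    events on lineages that later die out, is recorded; extinct lineages
    are pruned from the returned phage tree.
    """
    rng = np.random.default_rng(params.seed)
    host_root, _tips = _yule_host_tree(params.n_host_tips, rng)
    all_nodes: list[_HostNode] = []

    def collect(n):
        all_nodes.append(n)
        for c in n.children:
            collect(c)

    collect(host_root)
    event_log: list[tuple[str, str]] = []

    def alive_at(t, exclude):
        return [
            n for n in all_nodes
            if n is not exclude and n.t_start <= t < n.t_end
        ]

    def edge_end(host: _HostNode) -> _PhageLineage:
        """Fate of a lineage that reached the end of a host edge."""
        if not host.children:
            node = _PhageLineage("tip", host)
            return node
        event_log.append(("cospeciation", host.name))
        kids = [evolve(c, c.t_start) for c in host.children]
        return _PhageLineage("cospeciation", host, kids)

    def evolve(host: _HostNode, t_enter: float) -> _PhageLineage:
        """One phage lineage entering the edge above ``host`` at t_enter."""
        u = rng.random()
        tau = rng.uniform(t_enter, host.t_end)
        if u < params.loss:
            event_log.append(("loss", host.name))
            return _PhageLineage("loss", host)
        if u < params.loss + params.transfer:
            recipients = alive_at(tau, exclude=host)
            if recipients:
                rec = recipients[int(rng.integers(len(recipients)))]
                event_log.append(("transfer", f"{host.name}->{rec.name}"))
                stay = edge_end(host)
                moved = evolve(rec, tau)
                return _PhageLineage("transfer", host, [stay, moved])
        elif u < params.loss + params.transfer + params.duplication:
            event_log.append(("duplication", host.name))
            return _PhageLineage(
                "duplication", host, [edge_end(host), edge_end(host)]
            )
        return edge_end(host)

    genealogy = evolve(host_root, 0.0)

    # prune extinct lineages and collapse unary passages
    def prune(n: _PhageLineage) -> _PhageLineage | None:
        if n.kind == "loss":
            return None
        if n.kind == "tip":
            return n
        kept = [prune(c) for c in n.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        n.children = kept
        return n

    pruned = prune(genealogy)
    if pruned is None:
        raise ValueError(
            "all phage lineages were lost; lower the loss rate"
        )

    tip_counter: dict[str, int] = {}
    tip_map: dict[str, str] = {}

    def to_tree(n: _PhageLineage) -> TreeNode:
        if n.kind == "tip":
            hname = n.host.name
            tip_counter[hname] = tip_counter.get(hname, 0) + 1
            name = f"{hname}_p{tip_counter[hname]}"
            tip_map[name] = hname
            return TreeNode(name)
        return TreeNode(children=[to_tree(c) for c in n.children])

    phage_root = to_tree(pruned)

    def host_to_tree(n: _HostNode) -> TreeNode:
        return TreeNode(
            n.name if not n.children else None,
            [host_to_tree(c) for c in n.children],
            length=n.t_end - n.t_start,
        )

    host_tree = host_to_tree(host_root)
    counts = {"cospeciation": 0, "duplication": 0, "transfer": 0, "loss": 0}
    for ev, _ in event_log:
        counts[ev] += 1
    pair = TreePair(host_tree, phage_root, tip_map)
    return CophylogenyScenario(pair, counts, event_log)
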