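"""Undated duplication-transfer-loss (DTL) maximum-parsimony reconciliation.

Maps a phage (symbiont) tree onto a host tree using four event types:

* **cospeciation** — a phage divergence mirrors a host divergence; the two
  phage children descend into the two distinct host child subtrees;
* **duplication** — both phage children remain within the current host
  subtree;
* **transfer** — one child remains within the current host subtree, the
  other jumps to a host node *incomparable* to the current one (neither
  ancestor nor descendant), with no timing constraint (undated model);
* **loss** — charged once per host edge a phage lineage passes through
  without an event ("loss-passage" accounting: the sister host lineage
  implied by each passed speciation lost the phage).

The minimum total cost, the number of distinct minimum-cost reconciliations
(MPRs), capped enumeration with deterministic ordering, k-medoids clustering
of MPR samples, a (transfer, loss) cost-space scan, and a permutation null
are provided.  The dynamic program is quadratic in tree size per phage node
and exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from rhizophage.io import TreeNode, TreePair, TreeError

INF = float("inf")

EVENT_TYPES = ("cospeciation", "duplication", "transfer", "loss")


@dataclass(frozen=True)
class DTLCosts:
    """Event costs for the parsimony reconciliation."""

    cospeciation: float = 0.0
    duplication: float = 2.0
    transfer: float = 1.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cospeciation", "duplication", "transfer", "loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be non-negative")

    def of(self, counts: dict[str, int] | tuple[int, int, int, int]) -> float:
        """Total cost of an event-count vector under these costs."""
        if isinstance(counts, dict):
            counts = tuple(counts.get(e, 0) for e in EVENT_TYPES)
        c, d, t, l = counts
        return (
            c * self.cospeciation
            + d * self.duplication
            + t * self.transfer
            + l * self.loss
        )


class _IndexedTree:
    """Array-indexed view of a rooted binary tree (postorder)."""

    def __init__(self, root: TreeNode, prefix: str):
        self.nodes: list[TreeNode] = list(root.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.names: list[str] = []
        seen: set[str] = set()
        for i, node in enumerate(self.nodes):
            name = node.name if node.name else f"{prefix}#{i}"
            if name in seen:
                raise TreeError(f"duplicate node label {name!r}")
            seen.add(name)
            self.names.append(name)
        self.children = [
            tuple(self.index[id(c)] for c in n.children) for n in self.nodes
        ]
        self.parent = [-1] * self.n
        for i, n in enumerate(self.nodes):
            for c in self.children[i]:
                self.parent[c] = i
        self.root = self.n - 1
        self.is_leaf = [not n.children for n in self.nodes]
        self.leaf_index = {
            self.names[i]: i for i in range(self.n) if self.is_leaf[i]
        }
        # ancestry: desc[a] = set of nodes in subtree of a (incl. a)
        self.desc: list[set[int]] = [set() for _ in range(self.n)]
        for i in range(self.n):  # postorder: children before parents
            self.desc[i].add(i)
            for c in self.children[i]:
                self.desc[i] |= self.desc[c]
        self.depth = [0] * self.n
        for i in reversed(range(self.n)):
            for c in self.children[i]:
                self.depth[c] = self.depth[i] + 1
        # incomparable[h] = postorder-sorted nodes neither ancestor nor
        # descendant of h
        anc = [set() for _ in range(self.n)]
        for i in reversed(range(self.n)):
            p = self.parent[i]
            if p >= 0:
                anc[i] = anc[p] | {p}
        self.incomparable: list[list[int]] = []
        for h in range(self.n):
            related = self.desc[h] | anc[h]
            self.incomparable.append(
                [x for x in range(self.n) if x not in related]
            )

    def path_down(self, top: int, bottom: int) -> list[int]:
        """Nodes strictly between ``top`` and ``bottom`` plus ``bottom``,
        walking rootward from ``bottom``; the edges entered (one per listed
        node) are the loss-passage edges."""
        path = []
        x = bottom
        while x != top:
            path.append(x)
            x = self.parent[x]
            if x < 0:
                raise ValueError("bottom is not a descendant of top")
        path.reverse()
        return path

    def dist_down(self, top: int, bottom: int) -> int:
        return self.depth[bottom] - self.depth[top]


@dataclass
class Reconciliation:
    """An event-annotated mapping of phage-tree nodes onto host-tree nodes.

    ``events`` is a list of ``(phage_node, event, host_node)`` tuples; for
    loss passages the host node named is the child end of the passed edge
    and the phage node is the lineage passing it.  The certificate is
    re-checkable bottom-up (see :func:`validate_reconciliation`).
    """

    node_map: dict[str, str]
    events: list[tuple[str, str, str]]
    counts: dict[str, int]
    total_cost: float

    def event_set(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self.events)

    def signature(self) -> tuple[int, int, int, int]:
        return tuple(self.counts.get(e, 0) for e in EVENT_TYPES)


@dataclass
class MPRSet:
    """A (possibly capped) sample of the minimum-cost reconciliations."""

    count: int
    sample: list[Reconciliation]
    min_cost: float
    clusters: list[list[int]] = field(default_factory=list)
    representatives: list[int] = field(default_factory=list)


class DTLTables:
    """Dynamic-program tables for one (tree pair, costs) instance.

    ``c[p][h]`` — minimum cost of the phage subtree rooted at ``p`` given
    that ``p``'s event happens at host node ``h``;
    ``inn[p][h]`` — minimum cost with ``p`` placed at ``h`` or anywhere in
    ``h``'s subtree, charging one loss per host edge descended;
    ``out[p][h]`` — minimum of ``c[p][h']`` over ``h'`` incomparable to
    ``h`` (transfer landing sites).  ``*_cnt`` hold exact solution counts.
    """

    def __init__(self, pair: TreePair, costs: DTLCosts):
        self.costs = costs
        self.H = _IndexedTree(pair.host, "H")
        self.P = _IndexedTree(pair.phage, "P")
        H, P = self.H, self.P
        self.tip_map_idx: dict[int, int] = {}
        for ptip, htip in pair.tip_map.items():
            if ptip in P.leaf_index:
                self.tip_map_idx[P.leaf_index[ptip]] = H.leaf_index[htip]
        for p in range(P.n):
            if P.is_leaf[p] and p not in self.tip_map_idx:
                raise TreeError(f"phage tip {P.names[p]!r} unmapped")

        nH = H.n
        self.c = [[INF] * nH for _ in range(P.n)]
        self.c_cnt = [[0] * nH for _ in range(P.n)]
        self.inn = [[INF] * nH for _ in range(P.n)]
        self.inn_cnt = [[0] * nH for _ in range(P.n)]
        self.out = [[INF] * nH for _ in range(P.n)]
        self.out_cnt = [[0] * nH for _ in range(P.n)]
        self._fill()

    def _fill(self) -> None:
        H, P, co = self.H, self.P, self.costs
        for p in range(P.n):
            if P.is_leaf[p]:
                h0 = self.tip_map_idx[p]
                self.c[p][h0] = 0.0
                self.c_cnt[p][h0] = 1
            else:
                p1, p2 = P.children[p]
                for h in range(H.n):
                    best, cnt = INF, 0
                    options = []
                    if not H.is_leaf[h]:
                        a, b = H.children[h]
                        options.append(
                            (co.cospeciation + self.inn[p1][a] + self.inn[p2][b],
                             self.inn_cnt[p1][a] * self.inn_cnt[p2][b])
                        )
                        options.append(
                            (co.cospeciation + self.inn[p1][b] + self.inn[p2][a],
                             self.inn_cnt[p1][b] * self.inn_cnt[p2][a])
                        )
                    options.append(
                        (co.duplication + self.inn[p1][h] + self.inn[p2][h],
                         self.inn_cnt[p1][h] * self.inn_cnt[p2][h])
                    )
                    options.append(
                        (co.transfer + self.inn[p1][h] + self.out[p2][h],
                         self.inn_cnt[p1][h] * self.out_cnt[p2][h])
                    )
                    options.append(
                        (co.transfer + self.inn[p2][h] + self.out[p1][h],
                         self.inn_cnt[p2][h] * self.out_cnt[p1][h])
                    )
                    for cost, n in options:
                        if cost < best - 1e-12:
                            best, cnt = cost, n
                        elif cost <= best + 1e-12:
                            cnt += n
                    self.c[p][h] = best
                    self.c_cnt[p][h] = cnt if best < INF else 0
            # inn: postorder over hosts guarantees children done first
            for h in range(H.n):
                best, cnt = self.c[p][h], self.c_cnt[p][h]
                if not H.is_leaf[h]:
                    for hc in H.children[h]:
                        cand = co.loss + self.inn[p][hc]
                        if cand < best - 1e-12:
                            best, cnt = cand, self.inn_cnt[p][hc]
                        elif cand <= best + 1e-12:
                            cnt += self.inn_cnt[p][hc]
                self.inn[p][h] = best
                self.inn_cnt[p][h] = cnt if best < INF else 0
            for h in range(H.n):
                best, cnt = INF, 0
                for hx in H.incomparable[h]:
                    v = self.c[p][hx]
                    if v < best - 1e-12:
                        best, cnt = v, self.c_cnt[p][hx]
                    elif v <= best + 1e-12:
                        cnt += self.c_cnt[p][hx]
                self.out[p][h] = best
                self.out_cnt[p][h] = cnt if best < INF else 0

    # -- results ----------------------------------------------------------

    def min_cost(self) -> float:
        return min(self.c[self.P.root])

    def count(self) -> int:
        row = self.c[self.P.root]
        best = min(row)
        return sum(
            n for v, n in zip(row, self.c_cnt[self.P.root])
            if v <= best + 1e-12
        )

    # -- enumeration (deterministic backtracking) --------------------------

    def _bt_c(self, p: int, h: int, target: float):
        """Yield (node_map, events) for subtree of p with p's event at h."""
        H, P, co = self.H, self.P, self.costs
        pname, hname = P.names[p], H.names[h]
        if P.is_leaf[p]:
            yield {pname: hname}, []
            return
        p1, p2 = P.children[p]
        # option order fixes the enumeration order: cospeciation first
        # (child-subtree assignments in host postorder), then duplication,
        # then transfer (staying child in phage-child order)
        if not H.is_leaf[h]:
            a, b = sorted(H.children[h])
            for (ha, hb) in ((a, b), (b, a)):
                cost = co.cospeciation + self.inn[p1][ha] + self.inn[p2][hb]
                if abs(cost - target) > 1e-9:
                    continue
                ev = (pname, "cospeciation", hname)
                for m1, e1 in self._bt_in(p1, ha):
                    for m2, e2 in self._bt_in(p2, hb):
                        yield {pname: hname, **m1, **m2}, [ev] + e1 + e2
        cost = co.duplication + self.inn[p1][h] + self.inn[p2][h]
        if abs(cost - target) <= 1e-9:
            ev = (pname, "duplication", hname)
            for m1, e1 in self._bt_in(p1, h):
                for m2, e2 in self._bt_in(p2, h):
                    yield {pname: hname, **m1, **m2}, [ev] + e1 + e2
        for stay, move in ((p1, p2), (p2, p1)):
            cost = co.transfer + self.inn[stay][h] + self.out[move][h]
            if abs(cost - target) > 1e-9:
                continue
            ev = (pname, "transfer", hname)
            for hx in H.incomparable[h]:
                if abs(self.c[move][hx] - self.out[move][h]) > 1e-9:
                    continue
                for m1, e1 in self._bt_in(stay, h):
                    for m2, e2 in self._bt_c(move, hx, self.c[move][hx]):
                        yield {pname: hname, **m1, **m2}, [ev] + e1 + e2

    def _bt_in(self, p: int, h: int):
        """Yield placements of p at-or-below h; loss passages as events."""
        H, co = self.H, self.costs
        target = self.inn[p][h]
        stack = [(h, 0, [])]  # (host node, losses so far, passed edges)
        while stack:
            hh, nloss, passed = stack.pop()
            if abs(self.c[p][hh] + nloss * co.loss - target) <= 1e-9:
                loss_events = [
                    (self.P.names[p], "loss", H.names[e]) for e in passed
                ]
                for m, e in self._bt_c(p, hh, self.c[p][hh]):
                    yield m, loss_events + e
            if not H.is_leaf[hh]:
                for hc in reversed(H.children[hh]):
                    if self.inn[p][hc] + (nloss + 1) * co.loss <= target + 1e-9:
                        stack.append((hc, nloss + 1, passed + [hc]))


def _require_pair(pair: TreePair) -> None:
    if not pair.host.is_binary() or not pair.phage.is_binary():
        raise TreeError("reconciliation requires binary trees")


def dtl_min_cost(pair: TreePair, costs: DTLCosts) -> tuple[float, DTLTables]:
    """Minimum total reconciliation cost and the filled DP tables."""
    _require_pair(pair)
    tables = DTLTables(pair, costs)
    return tables.min_cost(), tables


def count_mprs(pair: TreePair, costs: DTLCosts) -> int:
    """Number of distinct minimum-cost reconciliations (exact)."""
    return DTLTables(pair, costs).count()


def _tally(events: list[tuple[str, str, str]]) -> dict[str, int]:
    counts = {e: 0 for e in EVENT_TYPES}
    for _, ev, _ in events:
        counts[ev] += 1
    return counts


def enumerate_mprs(
    pair: TreePair, costs: DTLCosts, cap: int = 1000
) -> MPRSet:
    """Enumerate minimum-cost reconciliations in a deterministic order.

    At most ``cap`` certificates are materialised; ``count`` remains exact
    even when the sample is truncated.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    tables = DTLTables(pair, costs)
    best = tables.min_cost()
    row = tables.c[tables.P.root]
    sample: list[Reconciliation] = []

    def gen():
        for h in range(tables.H.n):
            if abs(row[h] - best) <= 1e-9:
                yield from tables._bt_c(tables.P.root, h, row[h])

    for node_map, events in itertools.islice(gen(), cap):
        counts = _tally(events)
        sample.append(
            Reconciliation(node_map, events, counts, costs.of(counts))
        )
    return MPRSet(count=tables.count(), sample=sample, min_cost=best)


def validate_reconciliation(
    pair: TreePair, rec: Reconciliation, costs: DTLCosts
) -> None:
    """Re-check a certificate bottom-up; raise ``ValueError`` if invalid.

    Verifies tip mapping, event validity at every internal phage node
    (cospeciation/duplication/transfer geometry), loss passages implied by
    child placements, and the stated total cost.
    """
    H = _IndexedTree(pair.host, "H")
    P = _IndexedTree(pair.phage, "P")
    name_to_h = {H.names[i]: i for i in range(H.n)}
    ev_by_p = {pn: (ev, hn) for pn, ev, hn in rec.events if ev != "loss"}
    losses = [(pn, hn) for pn, ev, hn in rec.events if ev == "loss"]
    n_loss_expected = 0
    for p in range(P.n):
        pname = P.names[p]
        h = name_to_h[rec.node_map[pname]]
        if P.is_leaf[p]:
            expect = pair.tip_map[pname]
            if rec.node_map[pname] != expect:
                raise ValueError(f"tip {pname!r} mapped off its host")
            continue
        ev, hname = ev_by_p[pname]
        if name_to_h[hname] != h:
            raise ValueError(f"event host for {pname!r} disagrees with map")
        ch = [name_to_h[rec.node_map[P.names[c]]] for c in P.children[p]]
        if ev == "cospeciation":
            if H.is_leaf[h]:
                raise ValueError("cospeciation at a host leaf")
            a, b = H.children[h]
            if ch[0] in H.desc[a] and ch[1] in H.desc[b]:
                tops = (a, b)
            elif ch[0] in H.desc[b] and ch[1] in H.desc[a]:
                tops = (b, a)
            else:
                raise ValueError("cospeciation children not in distinct host subtrees")
            n_loss_expected += H.dist_down(tops[0], ch[0])
            n_loss_expected += H.dist_down(tops[1], ch[1])
        elif ev == "duplication":
            if not all(c in H.desc[h] for c in ch):
                raise ValueError("duplication children escape host subtree")
            n_loss_expected += sum(H.dist_down(h, c) for c in ch)
        elif ev == "transfer":
            inc = set(H.incomparable[h])
            stays = [c in H.desc[h] for c in ch]
            moves = [c in inc for c in ch]
            if stays[0] and moves[1]:
                n_loss_expected += H.dist_down(h, ch[0])
            elif stays[1] and moves[0]:
                n_loss_expected += H.dist_down(h, ch[1])
            else:
                raise ValueError("transfer children not (stay, incomparable)")
        else:
            raise ValueError(f"unknown event {ev!r}")
    if len(losses) != n_loss_expected:
        raise ValueError(
            f"loss passages {len(losses)} != implied {n_loss_expected}"
        )
    counts = _tally(rec.events)
    if counts != rec.counts:
        raise ValueError("event counts disagree with event list")
    if abs(costs.of(counts) - rec.total_cost) > 1e-9:
        raise ValueError("total cost disagrees with event counts")


# ---------------------------------------------------------------------------
# MPR clustering


def _mpr_distance(a: Reconciliation, b: Reconciliation) -> int:
    return len(a.event_set() ^ b.event_set())


def cluster_mprs(sample: list[Reconciliation], k: int) -> MPRSet:
    """k-medoids clustering of an MPR sample.

    Distance is the size of the symmetric difference of the two event sets.
    Deterministic: medoids are seeded by a greedy farthest-first sweep from
    the first certificate and refined by alternating assignment/update.
    Returns an :class:`MPRSet` with ``clusters`` (lists of sample indices)
    and ``representatives`` (medoid indices) filled in.
    """
    n = len(sample)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    dist = [[_mpr_distance(sample[i], sample[j]) for j in range(n)] for i in range(n)]
    n_distinct = len({sample[i].event_set() for i in range(n)})
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct certificates"
        )
    medoids = [0]
    while len(medoids) < k:
        far = max(
            range(n),
            key=lambda i: (min(dist[i][m] for m in medoids), -i),
        )
        if min(dist[far][m] for m in medoids) == 0:
            far = next(
                i for i in range(n)
                if min(dist[i][m] for m in medoids) > 0
            )
        medoids.append(far)
    for _ in range(100):
        clusters: list[list[int]] = [[] for _ in medoids]
        for i in range(n):
            j = min(range(k), key=lambda j: (dist[i][medoids[j]], j))
            clusters[j].append(i)
        new_medoids = []
        for members in clusters:
            new_medoids.append(
                min(members, key=lambda m: (sum(dist[m][x] for x in members), m))
            )
        if new_medoids == medoids:
            break
        medoids = new_medoids
    out = MPRSet(
        count=n, sample=sample, min_cost=min(r.total_cost for r in sample)
    )
    out.clusters = clusters
    out.representatives = medoids
    return out


# ---------------------------------------------------------------------------
# Cost space


@dataclass
class CostSpaceMap:
    """Optimal outcomes over a (transfer cost, loss cost) grid.

    ``signatures[i][j]`` is the frozenset of optimal event-count signatures
    (cospeciation, duplication, transfer, loss) at ``transfer_values[i]``,
    ``loss_values[j]``; ``regions`` labels maximal 4-connected blocks of
    cells sharing a signature set.
    """

    transfer_values: list[float]
    loss_values: list[float]
    min_cost: np.ndarray
    signatures: list[list[frozenset]]
    regions: np.ndarray

    def n_regions(self) -> int:
        return int(self.regions.max()) + 1


def cost_space(
    pair: TreePair,
    transfer_range,
    loss_range,
    cospeciation: float = 0.0,
    duplication: float = 2.0,
    cap: int = 500,
) -> CostSpaceMap:
    """Scan the (transfer, loss) cost plane at fixed cospeciation and
    duplication costs, recording optimal cost and event signatures."""
    tvals = [float(t) for t in transfer_range]
    lvals = [float(l) for l in loss_range]
    if len(tvals) < 2 or len(lvals) < 2:
        raise ValueError("cost ranges need at least 2 grid points each")
    nt, nl = len(tvals), len(lvals)
    mc = np.zeros((nt, nl))
    sigs: list[list[frozenset]] = [[frozenset()] * nl for _ in range(nt)]
    for i, t in enumerate(tvals):
        for j, l in enumerate(lvals):
            costs = DTLCosts(cospeciation, duplication, t, l)
            mprs = enumerate_mprs(pair, costs, cap=cap)
            mc[i, j] = mprs.min_cost
            sigs[i] = list(sigs[i])
            sigs[i][j] = frozenset(r.signature() for r in mprs.sample)
    regions = np.full((nt, nl), -1, dtype=int)
    next_label = 0
    for i in range(nt):
        for j in range(nl):
            if regions[i, j] >= 0:
                continue
            stack = [(i, j)]
            regions[i, j] = next_label
            while stack:
                x, y = stack.pop()
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nx, ny = x + dx, y + dy
                    if (
                        0 <= nx < nt and 0 <= ny < nl
                        and regions[nx, ny] < 0
                        and sigs[nx][ny] == sigs[i][j]
                    ):
                        regions[nx, ny] = next_label
                        stack.append((nx, ny))
            next_label += 1
    return CostSpaceMap(tvals, lvals, mc, sigs, regions)


# ---------------------------------------------------------------------------
# Permutation null


def permutation_test(
    pair: TreePair,
    costs: DTLCosts,
    n_perm: int = 999,
    seed: int = 0,
    null: str = "tip_map",
) -> tuple[float, np.ndarray, float]:
    """Compare the observed reconciliation cost with a null distribution.

    ``null='tip_map'`` permutes the phage-to-host tip associations
    uniformly; ``null='topology'`` redraws the phage tree as a uniform
    random binary topology on the same tips.  Returns ``(observed cost,
    null costs, p)`` with ``p = (1 + #{null <= observed}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    tips = list(pair.tip_map)
    if len(tips) < 2:
        raise TreeError("permutation test needs at least 2 mapped tips")
    observed = dtl_min_cost(pair, costs)[0]
    rng = np.random.default_rng(seed)
    hosts = [pair.tip_map[t] for t in tips]
    null_costs = np.empty(n_perm)
    for i in range(n_perm):
        if null == "tip_map":
            perm = rng.permutation(len(tips))
            tm = {tips[j]: hosts[perm[j]] for j in range(len(tips))}
            null_pair = TreePair(pair.host, pair.phage, tm)
        elif null == "topology":
            ptree = _random_binary_topology(tips, rng)
            null_pair = TreePair(pair.host, ptree, dict(pair.tip_map))
        else:
            raise ValueError(f"unknown null {null!r}")
        null_costs[i] = dtl_min_cost(null_pair, costs)[0]
    p = (1 + int((null_costs <= observed + 1e-12).sum())) / (n_perm + 1)
    return observed, null_costs, p


def _random_binary_topology(tips: list[str], rng) -> TreeNode:
    """Uniform rooted binary topology by random sequential pair joins."""
    nodes = [TreeNode(t) for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]
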