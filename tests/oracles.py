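"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming machinery of the package:
the DTL oracle enumerates every complete event history (an assignment of
each phage node to a host node plus an event label per internal node) and
scores it directly from the event definitions.
"""

from __future__ import annotations

import itertools

from rhizophage.io import TreeNode, TreePair


def _index(root: TreeNode):
    nodes = list(root.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    children = [tuple(idx[id(c)] for c in n.children) for n in nodes]
    parent = [-1] * len(nodes)
    for i, ch in enumerate(children):
        for c in ch:
            parent[c] = i
    desc = [set() for _ in nodes]
    for i in range(len(nodes)):
        desc[i].add(i)
        for c in children[i]:
            desc[i] |= desc[c]
    depth = [0] * len(nodes)
    for i in reversed(range(len(nodes))):
        for c in children[i]:
            depth[c] = depth[i] + 1
    anc = [set() for _ in nodes]
    for i in reversed(range(len(nodes))):
        if parent[i] >= 0:
            anc[i] = anc[parent[i]] | {parent[i]}
    incomparable = [
        set(range(len(nodes))) - desc[i] - anc[i] for i in range(len(nodes))
    ]
    leaf_idx = {nodes[i].name: i for i in range(len(nodes)) if not children[i]}
    return nodes, children, desc, depth, incomparable, leaf_idx


def brute_force_dtl(pair: TreePair, cost_settings):
    """Exhaustive minimum cost and solution count for each cost setting.

    ``cost_settings`` is a list of (cospeciation, duplication, transfer,
    loss) tuples.  Returns a list of ``(min_cost, count)`` pairs, where the
    count is over distinct (node assignment, event labelling) histories.
    """
    (h_nodes, h_children, h_desc, h_depth, h_inc, h_leaf) = _index(pair.host)
    (p_nodes, p_children, p_desc, p_depth, p_inc, p_leaf) = _index(pair.phage)
    nP, nH = len(p_nodes), len(h_nodes)
    internal = [p for p in range(nP) if p_children[p]]
    fixed = {
        p: h_leaf[pair.tip_map[p_nodes[p].name]]
        for p in range(nP) if not p_children[p]
    }

    def node_options(h, g1, g2):
        """Valid (event, loss_count) labellings of one internal node."""
        opts = []
        if h_children[h]:
            a, b = h_children[h]
            if g1 in h_desc[a] and g2 in h_desc[b]:
                opts.append(("cospeciation",
                             (h_depth[g1] - h_depth[a])
                             + (h_depth[g2] - h_depth[b])))
            elif g1 in h_desc[b] and g2 in h_desc[a]:
                opts.append(("cospeciation",
                             (h_depth[g1] - h_depth[b])
                             + (h_depth[g2] - h_depth[a])))
        if g1 in h_desc[h] and g2 in h_desc[h]:
            opts.append(("duplication",
                         (h_depth[g1] - h_depth[h])
                         + (h_depth[g2] - h_depth[h])))
        if g1 in h_desc[h] and g2 in h_inc[h]:
            opts.append(("transfer", h_depth[g1] - h_depth[h]))
        elif g2 in h_desc[h] and g1 in h_inc[h]:
            opts.append(("transfer", h_depth[g2] - h_depth[h]))
        return opts

    results = [[float("inf"), 0] for _ in cost_settings]
    for combo in itertools.product(range(nH), repeat=len(internal)):
        assign = dict(fixed)
        assign.update(dict(zip(internal, combo)))
        per_node = []
        ok = True
        for p in internal:
            g1, g2 = (assign[c] for c in p_children[p])
            opts = node_options(assign[p], g1, g2)
            if not opts:
                ok = False
                break
            per_node.append(opts)
        if not ok:
            continue
        for ci, (c_co, c_du, c_tr, c_lo) in enumerate(cost_settings):
            ev_cost = {"cospeciation": c_co, "duplication": c_du,
                       "transfer": c_tr}
            total_min = 0.0
            n_ways = 1
            for opts in per_node:
                costs = [ev_cost[e] + l * c_lo for e, l in opts]
                m = min(costs)
                total_min += m
                n_ways *= sum(1 for c in costs if abs(c - m) <= 1e-9)
            if total_min < results[ci][0] - 1e-9:
                results[ci] = [total_min, n_ways]
            elif total_min <= results[ci][0] + 1e-9:
                results[ci][1] += n_ways
    return [(mc, n) for mc, n in results]


def tree_shapes(n: int):
    """All rooted binary tree shapes with n tips, as nested tuples."""
    if n == 1:
        return [0]
    shapes = set()
    for i in range(1, n // 2 + 1):
        for left in tree_shapes(i):
            for right in tree_shapes(n - i):
                shapes.add(tuple(sorted((left, right), key=repr)))
    return sorted(shapes, key=repr)


def shape_to_tree(shape, prefix: str) -> TreeNode:
    """Materialise a shape with canonical tip labels prefix1, prefix2, ..."""
    counter = [0]

    def build(s):
        if s == 0:
            counter[0] += 1
            return TreeNode(f"{prefix}{counter[0]}")
        return TreeNode(children=[build(s[0]), build(s[1])])

    return build(shape)


def paired_t_oracle(x, y):
    """Textbook paired t statistic: closed form, no scipy."""
    import math

    d = [b - a for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n)


def two_way_anova_oracle(values, a, b):
    """Closed-form balanced two-way ANOVA with interaction.

    Returns dict of (F, df1, df2) per term.  Requires a complete balanced
    design (equal cell counts).
    """
    import numpy as np

    values = np.asarray(values, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    a_levels = sorted(set(a.tolist()))
    b_levels = sorted(set(b.tolist()))
    n = len(values)
    grand = values.mean()
    r = n / (len(a_levels) * len(b_levels))
    ss_a = sum(
        (values[a == lv].mean() - grand) ** 2 * (values[a == lv]).size
        for lv in a_levels
    )
    ss_b = sum(
        (values[b == lv].mean() - grand) ** 2 * (values[b == lv]).size
        for lv in b_levels
    )
    ss_cells = 0.0
    ss_err = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = values[(a == la) & (b == lb)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = n - len(a_levels) * len(b_levels)
    mse = ss_err / df_err
    return {
        "A": (ss_a / df_a / mse, df_a, df_err),
        "B": (ss_b / df_b / mse, df_b, df_err),
        "A:B": (ss_ab / df_ab / mse, df_ab, df_err),
    }


# ---------------------------------------------------------------------------
# Shared test utilities


def congruent_pair(n_tips: int) -> TreePair:
    """A host caterpillar tree and an isomorphic phage tree, tip-mapped."""

    def caterpillar(prefix):
        node = TreeNode(f"{prefix}1")
        for i in range(2, n_tips + 1):
            node = TreeNode(children=[node, TreeNode(f"{prefix}{i}")])
        return node

    host = caterpillar("H")
    phage = caterpillar("p")
    tip_map = {f"p{i}": f"H{i}" for i in range(1, n_tips + 1)}
    return TreePair(host, phage, tip_map)


def mutate_seq(seq: str, rate: float, rng) -> str:
    """Point-mutate a fraction ``rate`` of positions (never silently)."""
    import numpy as np

    arr = list(seq)
    bases = "ACGT"
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        arr[i] = bases[(bases.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def random_genome(n: int, rng, gc: float = 0.5) -> str:
    import numpy as np

    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def naive_motif_scan(seq: str, motif: str, max_mismatch: int):
    """O(n*m) double-strand Hamming scan, the slow way."""
    comp = str.maketrans("ACGT", "TGCA")
    rc = motif.translate(comp)[::-1]
    hits = []
    m = len(motif)
    for strand, pat in (("+", motif), ("-", rc)):
        for start in range(len(seq) - m + 1):
            mm = sum(1 for x, y in zip(seq[start:start + m], pat) if x != y)
            if mm <= max_mismatch:
                hits.append((start, strand, mm))
    hits.sort()
    return hits
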