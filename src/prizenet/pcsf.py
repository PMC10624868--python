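"""Prize-collecting Steiner forest solvers.

The PCSF objective over a forest F in graph G with node prizes p, edge costs
c, prize scale beta and per-tree penalty omega is

    beta * sum_{v not in F} p(v)  +  sum_{e in F} c(e)  +  omega * kappa(F)

where kappa is the number of trees.  Two solvers are provided:

* :func:`solve_exact` — enumeration over node subsets with a minimum spanning
  forest per subset (the per-tree penalty is realized exactly by a virtual
  root joined to every node with an omega-cost edge).  Guarded to <= 14 nodes;
  serves as the oracle.
* :func:`solve_heuristic` — a Goemans-Williamson-style primal-dual moat
  growth on the rooted transformation (virtual root connected to every prized
  node at cost omega), followed by strong pruning and a split pass that
  removes any tree edge costing more than omega.  Deterministic by fixed
  tie-breaking; no randomness involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SizeError
from .prize_network import PCSFInstance, ROLE_STEINER

Edge = tuple[str, str]
Tree = tuple[frozenset, frozenset]

_EXACT_GUARD = 14
_EPS = 1e-9


def _ekey(u, v) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ForestSolution:
    """A recovered forest: vertex-disjoint trees with node roles.

    ``node_roles`` labels every forest node as a terminal (by evidence layer)
    or a Steiner connector; ``objective`` always equals the value recomputed
    from the parts.
    """

    trees: tuple[Tree, ...]
    kappa: int
    objective: float
    node_roles: dict

    @property
    def nodes(self) -> set:
        out: set = set()
        for ns, _ in self.trees:
            out |= ns
        return out

    @property
    def edges(self) -> set:
        out: set = set()
        for _, es in self.trees:
            out |= es
        return out

    @property
    def n_nodes(self) -> int:
        return sum(len(ns) for ns, _ in self.trees)


def _roles_for(instance: PCSFInstance, nodes) -> dict:
    return {
        v: (
            instance.node_roles.get(v, "terminal_proteome")
            if instance.prize(v) > 0
            else ROLE_STEINER
        )
        for v in nodes
    }


def _validate_forest(instance: PCSFInstance, trees) -> None:
    seen: set = set()
    for nodes, edges in trees:
        if seen & set(nodes):
            raise ValueError("trees must be vertex-disjoint")
        seen |= set(nodes)
        if len(edges) != len(nodes) - 1:
            raise ValueError("each tree must be acyclic and connected")
        adj: dict = {v: [] for v in nodes}
        for u, v in edges:
            if not instance.graph.has_edge(u, v):
                raise ValueError(f"edge ({u}, {v}) not in the instance graph")
            if u not in adj or v not in adj:
                raise ValueError(f"edge ({u}, {v}) leaves the tree's node set")
            adj[u].append(v)
            adj[v].append(u)
        if nodes:
            stack = [next(iter(nodes))]
            reach = set(stack)
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in reach:
                        reach.add(y)
                        stack.append(y)
            if reach != set(nodes):
                raise ValueError("tree is not connected")


def objective_value(instance: PCSFInstance, trees) -> float:
    """Objective of a candidate forest; validates structure first."""
    trees = [(frozenset(ns), frozenset(_ekey(*e) for e in es)) for ns, es in trees]
    _validate_forest(instance, trees)
    included: set = set()
    for ns, _ in trees:
        included |= ns
    excluded = sum(
        p for v, p in instance.prizes.items() if v not in included
    )
    edge_cost = sum(
        instance.cost(u, v) for _, es in trees for u, v in es
    )
    return instance.beta * excluded + edge_cost + instance.omega * len(trees)


def _solution_from_trees(instance: PCSFInstance, trees) -> ForestSolution:
    trees = tuple(
        sorted(
            (
                (frozenset(ns), frozenset(_ekey(*e) for e in es))
                for ns, es in trees
            ),
            key=lambda t: sorted(t[0]),
        )
    )
    obj = objective_value(instance, trees)
    roles = _roles_for(instance, {v for ns, _ in trees for v in ns})
    return ForestSolution(trees, len(trees), obj, roles)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def solve_exact(instance: PCSFInstance) -> ForestSolution:
    """Globally optimal forest by subset enumeration (<= 14 nodes).

    For each candidate node set S the cheapest forest spanning S is the
    minimum spanning tree of S plus a virtual root joined to every node at
    cost omega: deleting the root leaves kappa trees and the MST cost equals
    forest cost + omega * kappa.  Ties are broken toward fewer nodes, then
    lexicographically smaller node sets.
    """
    nodes = sorted(instance.graph.nodes)
    n = len(nodes)
    if n > _EXACT_GUARD:
        raise SizeError(
            f"exact solver is limited to {_EXACT_GUARD} nodes "
            f"(got {n}); use solve_heuristic"
        )
    idx = {v: i for i, v in enumerate(nodes)}
    prize = np.array([instance.prize(v) for v in nodes])
    beta, omega = instance.beta, instance.omega
    total_prize = beta * prize.sum()

    # augmented edge list sorted by cost: real edges plus root edges (cost omega)
    aug = [
        (instance.cost(u, v), idx[u], idx[v])
        for u, v in instance.graph.edges
    ]
    aug += [(omega, i, n) for i in range(n)]  # n = virtual root
    aug.sort(key=lambda t: (t[0], t[1], t[2]))

    # prize sum per subset via lowest-bit DP
    prize_in = np.zeros(1 << n)
    for mask in range(1, 1 << n):
        low = (mask & -mask).bit_length() - 1
        prize_in[mask] = prize_in[mask & (mask - 1)] + prize[low]

    best = (float("inf"), -1, ())
    for mask in range(1 << n):
        if mask == 0:
            mst = 0.0
        else:
            uf = _UnionFind(n + 1)
            k = bin(mask).count("1")  # nodes to connect (plus root)
            mst = 0.0
            joined = 0
            for cost, a, b in aug:
                if a != n and not (mask >> a) & 1:
                    continue
                if b != n and not (mask >> b) & 1:
                    continue
                if uf.union(a, b):
                    mst += cost
                    joined += 1
                    if joined == k:
                        break
        obj = total_prize - beta * prize_in[mask] + mst
        names = None
        if obj < best[0] - _EPS:
            names = tuple(nodes[i] for i in range(n) if (mask >> i) & 1)
            best = (obj, mask, names)
        elif abs(obj - best[0]) <= _EPS:
            names = tuple(nodes[i] for i in range(n) if (mask >> i) & 1)
            if (len(names), names) < (len(best[2]), best[2]):
                best = (obj, mask, names)

    # reconstruct the forest for the winning subset
    mask = best[1]
    members = [i for i in range(n) if (mask >> i) & 1]
    uf = _UnionFind(n + 1)
    chosen: list[tuple[int, int]] = []
    for cost, a, b in aug:
        if a != n and not (mask >> a) & 1:
            continue
        if b != n and not (mask >> b) & 1:
            continue
        if uf.union(a, b):
            if a != n and b != n:
                chosen.append((a, b))
    comp: dict[int, int] = {}
    comp_uf = _UnionFind(n)
    for a, b in chosen:
        comp_uf.union(a, b)
    trees: dict[int, tuple[set, set]] = {}
    for i in members:
        root = comp_uf.find(i)
        trees.setdefault(root, (set(), set()))[0].add(nodes[i])
    for a, b in chosen:
        trees[comp_uf.find(a)][1].add(_ekey(nodes[a], nodes[b]))
    return _solution_from_trees(instance, list(trees.values()))


# ---------------------------------------------------------------------------
# Goemans-Williamson primal-dual heuristic
# ---------------------------------------------------------------------------


def _strong_prune(adj, root, prizes, beta):
    """Strong-pruning DP from ``root``; returns (kept node set, net value).

    A child subtree is removed when its net beta-scaled prize minus internal
    cost falls below the cost of its attaching edge.
    """
    order = [root]
    parent = {root: None}
    for x in order:
        for y, _ in adj[x]:
            if y not in parent:
                parent[y] = x
                order.append(y)
    net = {}
    kept_children: dict = {x: [] for x in order}
    for x in reversed(order):
        value = beta * prizes.get(x, 0.0)
        for y, cost in adj[x]:
            if parent.get(y) != x:
                continue
            if net[y] - cost >= 0.0:
                value += net[y] - cost
                kept_children[x].append(y)
        net[x] = value
    kept = set()
    stack = [root]
    while stack:
        x = stack.pop()
        kept.add(x)
        stack.extend(kept_children[x])
    return kept, net[root]


def _prune_tree(instance: PCSFInstance, nodes, edges, root=None):
    """Strong-prune one tree; drop it entirely if its net value < omega.

    Returns a list of (nodes, edges) trees (empty when dropped).
    """
    nodes = set(nodes)
    edges = {_ekey(*e) for e in edges}
    if not nodes:
        return []
    adj: dict = {v: [] for v in nodes}
    for u, v in edges:
        c = instance.cost(u, v)
        adj[u].append((v, c))
        adj[v].append((u, c))
    if root is None:
        root = max(nodes, key=lambda v: (instance.prize(v), v))
    kept, net = _strong_prune(adj, root, instance.prizes, instance.beta)
    if net < instance.omega:
        return []
    kept_edges = {e for e in edges if e[0] in kept and e[1] in kept}
    return [(kept, kept_edges)]


def _split_expensive_edges(instance: PCSFInstance, trees):
    """Remove tree edges costing more than omega; re-prune the fragments.

    Trading one edge above omega for one extra tree penalty strictly lowers
    the objective, so this pass never hurts; it runs to a fixed point.
    """
    out = []
    queue = list(trees)
    while queue:
        nodes, edges = queue.pop()
        expensive = sorted(
            e for e in edges if instance.cost(*e) > instance.omega
        )
        if not expensive:
            out.append((nodes, edges))
            continue
        cut = expensive[0]
        rest = set(edges) - {cut}
        # split into the two components around the cut edge
        adj: dict = {v: [] for v in nodes}
        for u, v in rest:
            adj[u].append(v)
            adj[v].append(u)
        side = set()
        stack = [cut[0]]
        while stack:
            x = stack.pop()
            if x in side:
                continue
            side.add(x)
            stack.extend(adj[x])
        for part in (side, set(nodes) - side):
            part_edges = {e for e in rest if e[0] in part and e[1] in part}
            for pruned in _prune_tree(instance, part, part_edges):
                queue.append(pruned)
    return out


def prune(instance: PCSFInstance, forest: ForestSolution) -> ForestSolution:
    """Strong pruning of an existing forest.

    Per tree, every subtree whose beta-scaled prize sum (net of internal
    costs) is below its attaching edge's cost is removed, and a tree whose
    remaining net value is below omega is dropped outright.  The objective
    never increases; every surviving leaf has a positive prize.  Idempotent.
    """
    pruned = []
    for nodes, edges in forest.trees:
        pruned.extend(_prune_tree(instance, nodes, edges))
    return _solution_from_trees(instance, pruned)


def solve_heuristic(instance: PCSFInstance) -> ForestSolution:
    """Primal-dual (moat-growing) PCSF heuristic with strong pruning.

    The forest problem is reduced to rooted prize-collecting Steiner tree by
    adding a virtual root with an omega-cost edge to every prized node; moats
    grow around active clusters until they touch (merge) or exhaust their
    beta-scaled prize budget (die).  The merge tree reachable from the root
    is kept, strong-pruned against omega, and split at any edge costing more
    than omega.  Fully deterministic: ties resolve by fixed edge order.
    """
    nodes = sorted(instance.graph.nodes)
    n = len(nodes)
    if n == 0:
        return _solution_from_trees(instance, [])
    idx = {v: i for i, v in enumerate(nodes)}
    beta, omega = instance.beta, instance.omega
    prize = np.array([beta * instance.prize(v) for v in nodes])
    root = n

    real_edges = sorted(
        (_ekey(u, v) for u, v in instance.graph.edges),
    )
    eu = [idx[u] for u, v in real_edges]
    ev = [idx[v] for u, v in real_edges]
    ec = [instance.cost(u, v) for u, v in real_edges]
    n_real = len(real_edges)
    prized = [i for i in range(n) if prize[i] > 0]
    eu = np.array(eu + prized, dtype=np.int64)
    ev = np.array(ev + [root] * len(prized), dtype=np.int64)
    ec = np.array(ec + [omega] * len(prized))
    if not len(prized):
        return _solution_from_trees(instance, [])

    max_cluster = 2 * (n + 1) + 1
    comp = np.arange(n + 1, dtype=np.int64)
    active = np.zeros(max_cluster, dtype=bool)
    remaining = np.zeros(max_cluster)
    has_root = np.zeros(max_cluster, dtype=bool)
    members: dict[int, list[int]] = {i: [i] for i in range(n + 1)}
    active[:n] = prize > 0
    remaining[:n] = prize
    has_root[root] = True
    moat = np.zeros(n + 1)
    next_cid = n + 1
    merges: list[int] = []

    max_iter = 4 * (n + len(ec)) + 16
    for _ in range(max_iter):
        live = np.array(sorted(members), dtype=np.int64)
        act_live = live[active[live]]
        if act_live.size == 0:
            break
        cu = comp[eu]
        cv = comp[ev]
        au = active[cu].astype(np.int64)
        av = active[cv].astype(np.int64)
        rate = au + av
        ok = (cu != cv) & (rate > 0)
        slack = np.maximum(ec - moat[eu] - moat[ev], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dt_edge = np.where(ok, slack / np.maximum(rate, 1), np.inf)
        j = int(np.argmin(dt_edge))
        edge_dt = float(dt_edge[j])
        death_i = int(np.argmin(remaining[act_live]))
        death_dt = float(remaining[act_live][death_i])
        dt = min(edge_dt, death_dt)
        if dt > 0.0:
            node_active = active[comp]
            moat[node_active] += dt
            remaining[act_live] -= dt
        if edge_dt <= death_dt:
            a, b = int(comp[eu[j]]), int(comp[ev[j]])
            if a == b:
                continue
            cid = next_cid
            next_cid += 1
            members[cid] = members.pop(a) + members.pop(b)
            comp[np.array(members[cid], dtype=np.int64)] = cid
            has_root[cid] = has_root[a] or has_root[b]
            remaining[cid] = remaining[a] + remaining[b]
            active[cid] = not has_root[cid]
            active[a] = active[b] = False
            merges.append(j)
        else:
            dying = int(act_live[death_i])
            active[dying] = False
            remaining[dying] = 0.0

    # connect merge edges; keep the root component
    madj: dict[int, list[int]] = {}
    for j in merges:
        a, b = int(eu[j]), int(ev[j])
        madj.setdefault(a, []).append(j)
        madj.setdefault(b, []).append(j)
    reach = {root}
    stack = [root]
    kept_edges: set[int] = set()
    while stack:
        x = stack.pop()
        for j in madj.get(x, ()):
            y = int(eu[j]) if int(ev[j]) == x else int(ev[j])
            if y not in reach:
                reach.add(y)
                kept_edges.add(j)
                stack.append(y)

    # subtrees hanging off the root via omega edges
    attach = [j for j in kept_edges if j >= n_real and int(ev[j]) == root]
    trees = []
    for j in sorted(attach):
        v0 = int(eu[j])
        t_nodes = {v0}
        t_edges = set()
        stack = [v0]
        while stack:
            x = stack.pop()
            for k in madj.get(x, ()):
                if k not in kept_edges or k >= n_real:
                    continue
                y = int(eu[k]) if int(ev[k]) == x else int(ev[k])
                if y not in t_nodes:
                    t_nodes.add(y)
                    t_edges.add(k)
                    stack.append(y)
        name_nodes = {nodes[i] for i in t_nodes}
        name_edges = {
            _ekey(nodes[int(eu[k])], nodes[int(ev[k])]) for k in t_edges
        }
        trees.extend(
            _prune_tree(instance, name_nodes, name_edges, root=nodes[v0])
        )
    trees = _split_expensive_edges(instance, trees)
    return _solution_from_trees(instance, trees)
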