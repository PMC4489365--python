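"""(6,6) body-bar pebble game and rigid/flexible region decomposition.

Atoms are rigid bodies with 6 degrees of freedom; bars remove at most one
relative degree of freedom each.  A bar is independent iff 7 pebbles can be
gathered on its two endpoints; independent bars consume one pebble.  The
total independent count is the rank of the generic body-bar rigidity
matroid (order-independent), while per-bar labels follow the insertion
order — the model always inserts in preferential (ascending component
entropy) order so that the conformational entropy estimate is the lowest
upper bound attainable by bar exchange.

The decomposition yields, per constraint topology:

* rigid clusters — maximal sets of mutually rigid bodies (pairwise
  7-pebble-blocked, tested on bonded/H-bonded pairs with transitive
  closure);
* over-constrained (stressed) regions — unions of the vertex sets visited
  by failed pebble searches, merged when overlapping, with their redundant
  bar count B and locked rotatable bond count L;
* flexible regions — connected components of unlocked rotatable torsion
  sites, with their hinge count H and independent disordered torsion count
  A.

These are exactly the counts entering the flexibility index f = A/H − B/L
and the cooperativity correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constraint_network import BodyBarFramework

# --------------------------------------------------------------------------
# numba core
# --------------------------------------------------------------------------


@njit(cache=True)
def _find_pebble(root, ea, eb, free, epeb, visited, pred, stack):
    """Move one free pebble to ``root`` via directed-path reversal.

    Pebbles held by ``ea``/``eb`` (the endpoints of the bar being tested)
    are off-limits.  Returns True on success.
    """
    n = free.shape[0]
    for i in range(n):
        visited[i] = False
    visited[ea] = True
    visited[eb] = True
    visited[root] = True
    top = 0
    stack[top] = root
    top += 1
    pred[root] = -1
    while top > 0:
        top -= 1
        x = stack[top]
        for y in range(n):
            if epeb[x, y] > 0 and not visited[y]:
                if free[y] > 0:
                    free[y] -= 1
                    epeb[x, y] -= 1
                    epeb[y, x] += 1
                    c = x
                    while pred[c] >= 0:
                        p = pred[c]
                        epeb[p, c] -= 1
                        epeb[c, p] += 1
                        c = p
                    free[root] += 1
                    return True
                visited[y] = True
                pred[y] = x
                stack[top] = y
                top += 1
    return False


@njit(cache=True)
def _gather7(u, v, free, epeb, visited, pred, stack):
    """Try to gather 7 pebbles on the pair (u, v)."""
    if u == v:
        return False
    while free[u] < 6:
        if not _find_pebble(u, u, v, free, epeb, visited, pred, stack):
            break
    while free[u] + free[v] < 7:
        if not _find_pebble(v, u, v, free, epeb, visited, pred, stack):
            break
    return free[u] + free[v] >= 7


@njit(cache=True)
def _mark_reach(a, b, epeb, mask, stack):
    """Mark all vertices reachable from {a, b} along directed pebble edges."""
    n = epeb.shape[0]
    for i in range(n):
        mask[i] = False
    top = 0
    mask[a] = True
    stack[top] = a
    top += 1
    if not mask[b]:
        mask[b] = True
        stack[top] = b
        top += 1
    while top > 0:
        top -= 1
        x = stack[top]
        for y in range(n):
            if epeb[x, y] > 0 and not mask[y]:
                mask[y] = True
                stack[top] = y
                top += 1


@njit(cache=True)
def _uf_find(parent, x):
    r = x
    while parent[r] != r:
        r = parent[r]
    while parent[x] != r:
        nxt = parent[x]
        parent[x] = r
        x = nxt
    return r


@njit(cache=True)
def _run_game(n, us, vs):
    free = np.full(n, 6, np.int64)
    epeb = np.zeros((n, n), np.int16)
    m = us.shape[0]
    indep = np.zeros(m, np.bool_)
    visited = np.zeros(n, np.bool_)
    pred = np.full(n, -1, np.int64)
    stack = np.zeros(n + 1, np.int64)
    parent = np.arange(n)
    stressed = np.zeros(n, np.bool_)
    mask = np.zeros(n, np.bool_)
    for k in range(m):
        u = us[k]
        v = vs[k]
        if u != v and _gather7(u, v, free, epeb, visited, pred, stack):
            indep[k] = True
            free[u] -= 1
            epeb[u, v] += 1
        else:
            # redundant: the reachable set is the stressed support
            _mark_reach(u, v, epeb, mask, stack)
            ru = _uf_find(parent, u)
            for w in range(n):
                if mask[w]:
                    stressed[w] = True
                    rw = _uf_find(parent, w)
                    if rw != ru:
                        parent[rw] = ru
    return free, epeb, indep, parent, stressed


@njit(cache=True)
def _pair_rigid_many(pu, pv, free, epeb, visited, pred, stack):
    m = pu.shape[0]
    out = np.zeros(m, np.bool_)
    for k in range(m):
        out[k] = not _gather7(pu[k], pv[k], free, epeb, visited, pred, stack)
    return out


# --------------------------------------------------------------------------
# python layer
# --------------------------------------------------------------------------


@dataclass
class PebbleGameState:
    """Final pebble distribution and per-bar outcome of one game."""

    n_vertices: int
    free: np.ndarray          # free pebbles per vertex
    epeb: np.ndarray          # directed consumed-pebble counts
    independent: np.ndarray   # per bar, in the framework's bar order
    stressed_parent: np.ndarray
    stressed: np.ndarray
    order: np.ndarray         # insertion order used (indices into framework bars)

    @property
    def n_independent(self) -> int:
        return int(self.independent.sum())

    def used_preferential_order(self) -> bool:
        return bool(np.array_equal(self.order, np.arange(self.order.shape[0])))


def run_pebble_game(
    framework: BodyBarFramework, order: np.ndarray | None = None
) -> tuple[PebbleGameState, np.ndarray]:
    """Play the (6,6) pebble game, inserting bars in ``order``.

    ``order`` is a permutation of bar indices; ``None`` means the
    framework's stored preferential order.  Returns the final state and the
    per-bar independence flags (aligned with the framework's bar arrays).
    """
    m = framework.n_bars
    if order is None:
        order = np.arange(m)
    else:
        order = np.asarray(order, np.int64)
        if sorted(order.tolist()) != list(range(m)):
            raise ValueError("order must be a permutation of all bar indices")
    us = framework.us[order]
    vs = framework.vs[order]
    free, epeb, indep_perm, parent, stressed = _run_game(
        framework.n_vertices, us.astype(np.int64), vs.astype(np.int64)
    )
    indep = np.zeros(m, bool)
    indep[order] = indep_perm
    state = PebbleGameState(
        n_vertices=framework.n_vertices,
        free=free,
        epeb=epeb,
        independent=indep,
        stressed_parent=parent,
        stressed=stressed,
        order=order,
    )
    return state, indep


@dataclass
class RigidityReport:
    """Region decomposition and the counts behind the flexibility index."""

    rigid_cluster: np.ndarray        # per vertex: cluster label
    site_locked: np.ndarray          # per torsion site
    site_flex_region: np.ndarray     # per site: flexible-region id or -1
    site_over_region: np.ndarray     # per site: stressed-region id or -1 (isostatic)
    site_f: np.ndarray               # per site: h, -l, or 0 (isostatic)
    flex_H: dict = field(default_factory=dict)   # region -> hinge count
    flex_A: dict = field(default_factory=dict)   # region -> independent disordered torsions
    over_L: dict = field(default_factory=dict)   # region -> locked rotatable bonds
    over_B: dict = field(default_factory=dict)   # region -> redundant bar count
    independent: np.ndarray | None = None        # per bar

    def to_frames(self):
        """(per-atom, per-site) tables: rigid cluster ids; region id/kind/value."""
        import pandas as pd

        atoms = pd.DataFrame({
            "atom": np.arange(self.rigid_cluster.shape[0]),
            "rigid_cluster": self.rigid_cluster,
        })
        rows = []
        for s in range(self.site_locked.shape[0]):
            if self.site_locked[s]:
                kind = "over_constrained" if self.site_over_region[s] >= 0 else "isostatic"
                region = int(self.site_over_region[s])
            else:
                kind = "flexible"
                region = int(self.site_flex_region[s])
            rows.append({"site": s, "region": region, "region_kind": kind,
                         "f": float(self.site_f[s])})
        return atoms, pd.DataFrame(rows)


def decompose_regions(framework: BodyBarFramework, state: PebbleGameState) -> RigidityReport:
    """Rigid clusters, stressed regions and flexible regions from a finished game.

    The decomposition distinguishes the *structural* network (covalent and
    H-bond bars) from the torsion constraints: a torsion constraint is an
    entropy bookkeeping device, not a mechanical weld, so whether a
    rotatable bond is locked, which bodies form rigid clusters, and where
    redundant constraints (B) accumulate are all judged on a second pebble
    game over the structural bars alone.  The full preferential-order game
    (``state``) supplies the independent disordered torsion count A per
    flexible region — H rotatable bonds in an underconstrained loop then
    share A < H collective degrees of freedom, giving h = A/H < 1.

    Mutual-rigidity tests are run on covalently bonded and H-bonded vertex
    pairs only and closed transitively (equivalent to all-pairs testing on a
    connected framework).  Two unlocked torsion sites share a flexible
    region when their central bonds share an atom, are covalently bonded to
    each other, or are linked by a present H-bond.
    """
    n = framework.n_vertices
    indep = state.independent
    bonds = framework.bonds or []
    hbonds = framework.hbonds or []
    sites = framework.sites or []

    # pass 2: structural network only (everything except torsion bars)
    structural = framework.kinds != 2
    s_us = framework.us[structural].astype(np.int64)
    s_vs = framework.vs[structural].astype(np.int64)
    s_free, s_epeb, s_indep, s_parent, s_stressed = _run_game(n, s_us, s_vs)

    pairs = [(b.i, b.j) for b in bonds] + [(hb.donor, hb.acceptor) for hb in hbonds]
    if pairs:
        pu = np.array([p[0] for p in pairs], np.int64)
        pv = np.array([p[1] for p in pairs], np.int64)
        visited = np.zeros(n, bool)
        pred = np.full(n, -1, np.int64)
        stack = np.zeros(n + 1, np.int64)
        rigid = _pair_rigid_many(pu, pv, s_free, s_epeb, visited, pred, stack)
    else:
        rigid = np.zeros(0, bool)

    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bond_rigid = {}
    for (a, b), r in zip(pairs, rigid):
        bond_rigid[(a, b)] = bool(r)
        if r:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    rigid_cluster = np.array([find(i) for i in range(n)], np.int64)

    n_sites = len(sites)
    site_locked = np.zeros(n_sites, bool)
    for s_idx, s in enumerate(sites):
        site_locked[s_idx] = bond_rigid.get(tuple(s.central), False) or (
            rigid_cluster[s.central[0]] == rigid_cluster[s.central[1]]
        )

    # flexible regions: union-find over unlocked sites
    sparent = np.arange(n_sites)

    def sfind(x):
        while sparent[x] != x:
            sparent[x] = sparent[sparent[x]]
            x = sparent[x]
        return x

    def sunion(a, b):
        ra, rb = sfind(a), sfind(b)
        if ra != rb:
            sparent[max(ra, rb)] = min(ra, rb)

    at_atom: dict[int, list[int]] = {}
    for s_idx, s in enumerate(sites):
        if site_locked[s_idx]:
            continue
        for atom in s.central:
            at_atom.setdefault(atom, []).append(s_idx)
    for lst in at_atom.values():
        for k in range(1, len(lst)):
            sunion(lst[0], lst[k])
    for b in bonds:
        if b.i in at_atom and b.j in at_atom:
            sunion(at_atom[b.i][0], at_atom[b.j][0])
    for hb in hbonds:
        if hb.donor in at_atom and hb.acceptor in at_atom:
            sunion(at_atom[hb.donor][0], at_atom[hb.acceptor][0])

    # torsion-bar independence per site
    site_bar_indep = np.zeros(n_sites, bool)
    tors = framework.kinds == 2
    for bar_idx in np.nonzero(tors)[0]:
        if indep[bar_idx]:
            site_bar_indep[framework.owners[bar_idx]] = True
    native = (
        framework.native_flags
        if framework.native_flags is not None
        else np.zeros(n_sites, bool)
    )

    site_flex_region = np.full(n_sites, -1, np.int64)
    flex_H: dict[int, int] = {}
    flex_A: dict[int, int] = {}
    for s_idx in range(n_sites):
        if site_locked[s_idx]:
            continue
        r = sfind(s_idx)
        site_flex_region[s_idx] = r
        flex_H[r] = flex_H.get(r, 0) + 1
        if site_bar_indep[s_idx] and not native[s_idx]:
            flex_A[r] = flex_A.get(r, 0) + 1

    # stressed regions from the structural game's failed-search union-find
    def gfind(x):
        while s_parent[x] != x:
            x = s_parent[x]
        return int(x)

    over_B: dict[int, int] = {}
    for bar_idx in np.nonzero(~s_indep)[0]:
        u = int(s_us[bar_idx])
        region = gfind(u)
        over_B[region] = over_B.get(region, 0) + 1

    site_over_region = np.full(n_sites, -1, np.int64)
    over_L: dict[int, int] = {}
    for s_idx, s in enumerate(sites):
        if not site_locked[s_idx]:
            continue
        u, v = s.central
        if s_stressed[u]:
            region = gfind(u)
        elif s_stressed[v]:
            region = gfind(v)
        else:
            continue  # isostatically locked
        site_over_region[s_idx] = region
        over_L[region] = over_L.get(region, 0) + 1

    site_f = np.zeros(n_sites, float)
    for s_idx in range(n_sites):
        if site_locked[s_idx]:
            region = site_over_region[s_idx]
            if region >= 0:
                site_f[s_idx] = -over_B.get(int(region), 0) / over_L[int(region)]
        else:
            r = int(site_flex_region[s_idx])
            site_f[s_idx] = flex_A.get(r, 0) / flex_H[r]

    return RigidityReport(
        rigid_cluster=rigid_cluster,
        site_locked=site_locked,
        site_flex_region=site_flex_region,
        site_over_region=site_over_region,
        site_f=site_f,
        flex_H=flex_H,
        flex_A=flex_A,
        over_L=over_L,
        over_B=over_B,
        independent=indep,
    )


@dataclass
class EntropyCounts:
    """Independent-constraint counts feeding the conformational entropy.

    ``q`` holds, per present H-bond (framework order), how many of its 5
    bars came out independent; ``q_nat``/``q_dis`` count independent native
    and disordered torsion bars.  ``sum_q_gamma`` is Σ q_t γ_t.
    """

    q: np.ndarray
    q_nat: int
    q_dis: int
    sum_q_gamma: float

    def s_conf_R(self, delta_nat: float, delta_dis: float) -> float:
        """S_conf in units of R for one framework."""
        return self.sum_q_gamma + self.q_nat * delta_nat + self.q_dis * delta_dis


def entropy_counts(framework: BodyBarFramework, state: PebbleGameState) -> EntropyCounts:
    """Counts of independent constraints under preferential ordering.

    The preferential order is required: with any other insertion order the
    per-bar labels no longer give the lowest upper bound on the entropy.
    """
    if not state.used_preferential_order():
        raise ValueError("entropy counts require the preferential insertion order")
    return _entropy_counts_from_flags(framework, state.independent)


def _entropy_counts_from_flags(framework: BodyBarFramework, indep: np.ndarray) -> EntropyCounts:
    hbonds = framework.hbonds or []
    sites = framework.sites or []
    native = (
        framework.native_flags
        if framework.native_flags is not None
        else np.zeros(len(sites), bool)
    )
    q = np.zeros(len(hbonds), np.int64)
    hb_bars = framework.kinds == 1
    for bar_idx in np.nonzero(hb_bars)[0]:
        if indep[bar_idx]:
            q[framework.owners[bar_idx]] += 1
    sum_q_gamma = float(sum(q[t] * hbonds[t].gamma for t in range(len(hbonds))))
    q_nat = 0
    q_dis = 0
    tors = framework.kinds == 2
    for bar_idx in np.nonzero(tors)[0]:
        if indep[bar_idx]:
            if native[framework.owners[bar_idx]]:
                q_nat += 1
            else:
                q_dis += 1
    return EntropyCounts(q=q, q_nat=q_nat, q_dis=q_dis, sum_q_gamma=sum_q_gamma)


# --------------------------------------------------------------------------
# independent oracle: generic rigidity-matrix rank
# --------------------------------------------------------------------------


def oracle_rank(framework: BodyBarFramework, seed: int = 0, n_draws: int = 3) -> int:
    """Rank of the generic body-bar rigidity matrix (numerical, majority vote).

    Each body gets 6 columns (translation, rotation); a bar attached at
    generic points a_u, a_v with direction e contributes the row
    [e, a_u x e, -e, -(a_v x e)].  The rank is evaluated at ``n_draws``
    random generic placements and the majority value returned; it equals
    the pebble game's independent-bar count for every framework.
    """
    n = framework.n_vertices
    m = framework.n_bars
    if m == 0:
        return 0
    ranks = []
    rng = np.random.default_rng(seed)
    for _ in range(n_draws):
        pos = rng.normal(size=(n, 3))
        rows = np.zeros((m, 6 * n))
        for k in range(m):
            u, v = int(framework.us[k]), int(framework.vs[k])
            a_u = pos[u] + 0.1 * rng.normal(size=3)
            a_v = pos[v] + 0.1 * rng.normal(size=3)
            e = a_u - a_v
            rows[k, 6 * u : 6 * u + 3] = e
            rows[k, 6 * u + 3 : 6 * u + 6] = np.cross(a_u, e)
            rows[k, 6 * v : 6 * v + 3] -= e
            rows[k, 6 * v + 3 : 6 * v + 6] -= np.cross(a_v, e)
        ranks.append(int(np.linalg.matrix_rank(rows)))
    vals, counts = np.unique(ranks, return_counts=True)
    return int(vals[np.argmax(counts)])
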