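"""TCtriCluster: time-constrained triclustering of three-way data.

Mines maximal, arbitrarily positioned and possibly overlapping triclusters
``(I, J, K)`` — object set, feature set, context set — whose context set is a
run of CONSECUTIVE time points.  Coherence inside each time slice follows the
ratio-graph model: a block is coherent when, for every pair of features in
``J``, the per-object value ratios span a range of at most ``epsilon``.  A
ratio range of zero therefore admits exact constant and exact scaling
patterns; small ``epsilon`` admits noisy versions of both.

The search has three phases:

1. per slice, build a coherence multigraph whose nodes are features and whose
   edges are the maximal object subsets with ratio range <= epsilon for a
   feature pair (several edges per pair are possible);
2. per slice, enumerate all maximal biclusters from the multigraph;
3. stack biclusters across consecutive contexts (the temporal constraint),
   keeping maximal triclusters only, then optionally delete or merge heavily
   overlapping triclusters (``eta`` / ``gamma`` thresholds).

The enumeration is exhaustive for the ratio-coherence model when the optional
per-dimension range caps (``delta_x/y/z``) are disabled; the caps act as
post-filters on maximal blocks.  All tie-breaks are lexicographic on sorted
index tuples; the miner contains no randomness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np

from .data_model import ThreeWayDataset

__all__ = [
    "MiningParams",
    "BiclusterSlice",
    "Tricluster",
    "CoherenceMultigraph",
    "ratio_range",
    "build_multigraph",
    "mine_slice_biclusters",
    "merge_time_contiguous",
    "prune_overlaps",
    "check_coherence",
    "tc_tricluster",
    "write_triclusters",
    "read_triclusters",
]


@dataclass(frozen=True)
class MiningParams:
    """The nine TCtriCluster hyperparameters plus value-transform options.

    epsilon : maximum ratio range (unitless) for slice coherence.
    mx, my, mz : minimum number of objects, features, contexts.
    delta_x : cap on the value spread of each feature across the block's
        objects (data units); ``None`` disables.
    delta_y : cap on the value spread of each object across the block's
        features; ``None`` disables.
    delta_z : cap on the temporal spread of each (object, feature) cell series
        across the block's contexts; ``None`` disables.
    eta : overlap-deletion threshold in [0, 1] (1 = never delete).
    gamma : merge threshold in [0, 1] (1 = never merge).
    shift : constant added to all values before mining, to make ordinal
        scores that include 0 strictly positive for the ratio model.
    transform : ``None``, ``"log"`` or ``"exp"``; ``exp`` maps additive
        (shifting) patterns onto constant-ratio ones, ``log`` the inverse.
    """

    epsilon: float
    mx: int = 2
    my: int = 2
    mz: int = 2
    delta_x: float | None = None
    delta_y: float | None = None
    delta_z: float | None = None
    eta: float = 1.0
    gamma: float = 1.0
    shift: float = 0.0
    transform: str | None = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if min(self.mx, self.my, self.mz) < 1:
            raise ValueError("minimum sizes must be >= 1")
        for name in ("delta_x", "delta_y", "delta_z"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 or None")
        if not (0 <= self.eta <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("eta and gamma must lie in [0, 1]")
        if self.transform not in (None, "log", "exp"):
            raise ValueError("transform must be None, 'log' or 'exp'")


@dataclass(frozen=True)
class BiclusterSlice:
    """A bicluster ``(I, J)`` inside one time slice ``z_k``."""

    object_ids: frozenset
    feature_ids: frozenset
    context_id: int

    def key(self):
        return (tuple(sorted(self.object_ids)), tuple(sorted(self.feature_ids)))


@dataclass(frozen=True)
class Tricluster:
    """A tricluster ``(I, J, K)`` with ``K`` a run of consecutive contexts."""

    object_ids: tuple
    feature_ids: tuple
    context_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "object_ids", tuple(sorted(self.object_ids)))
        object.__setattr__(self, "feature_ids", tuple(sorted(self.feature_ids)))
        object.__setattr__(self, "context_ids", tuple(sorted(self.context_ids)))

    @property
    def slices(self) -> list[BiclusterSlice]:
        I, J = frozenset(self.object_ids), frozenset(self.feature_ids)
        return [BiclusterSlice(I, J, k) for k in self.context_ids]

    def n_cells(self) -> int:
        return len(self.object_ids) * len(self.feature_ids) * len(self.context_ids)

    def cells(self) -> set:
        return {
            (i, j, k)
            for i in self.object_ids
            for j in self.feature_ids
            for k in self.context_ids
        }

    def contains(self, other: "Tricluster") -> bool:
        return (
            set(other.object_ids) <= set(self.object_ids)
            and set(other.feature_ids) <= set(self.feature_ids)
            and set(other.context_ids) <= set(self.context_ids)
        )

    def sort_key(self):
        return (self.object_ids, self.feature_ids, self.context_ids)


@dataclass
class CoherenceMultigraph:
    """Feature-pair coherence graph of one time slice.

    ``edges[(a, b)]`` (with a < b) holds the maximal object subsets on which
    the value ratios of features a and b span a range <= epsilon; a pair may
    carry several such edges.
    """

    nodes: tuple
    edges: dict


def _transform_values(values: np.ndarray, missing: np.ndarray, params: MiningParams):
    v = values + params.shift
    if params.transform == "log":
        if np.any(v[~missing] <= 0):
            bad = tuple(np.argwhere((v <= 0) & ~missing)[0])
            raise ValueError(f"non-positive value at cell {bad} under log transform")
        v = np.log(v)
    elif params.transform == "exp":
        v = np.exp(v)
    return v


def _check_positive(values: np.ndarray, missing: np.ndarray):
    bad = (values <= 0) & ~missing
    if bad.any():
        cell = tuple(int(x) for x in np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive value at cell {cell}: the ratio model needs strictly "
            "positive values (set MiningParams.shift or a transform)"
        )


def ratio_range(values_a, values_b, epsilon: float, mx: int, object_ids=None):
    """Maximal object subsets on which v_b / v_a spans a range <= epsilon.

    Subsets are intervals of the objects sorted by ratio; each returned subset
    is maximal (not contained in another valid subset) and has >= ``mx``
    members.  Values must be strictly positive.

    Returns a list of frozensets of object ids, in order of the smallest
    ratio they cover.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if object_ids is None:
        object_ids = np.arange(len(va))
    object_ids = np.asarray(object_ids)
    if np.any(va <= 0) or np.any(vb <= 0):
        i = int(np.argmax((va <= 0) | (vb <= 0)))
        raise ValueError(
            f"non-positive value for object {object_ids[i]}: ratios undefined"
        )
    ratios = vb / va
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    ids = object_ids[order]
    n = len(r)
    out = []
    right = 0
    prev_right = -1
    for left in range(n):
        if right < left:
            right = left
        while right + 1 < n and r[right + 1] - r[left] <= epsilon:
            right += 1
        if right > prev_right:  # not nested in the previous window
            if right - left + 1 >= mx:
                out.append(frozenset(ids[left : right + 1].tolist()))
            prev_right = right
    return out


def build_multigraph(slice_values, slice_missing, params: MiningParams) -> CoherenceMultigraph:
    """Phase 1: coherence multigraph of one time slice.

    Nodes are the features with at least ``mx`` non-missing objects; for each
    feature pair the edges are the maximal ratio-coherent object subsets over
    the objects where BOTH features are observed.  Node order follows the
    input feature order.
    """
    slice_values = np.asarray(slice_values, dtype=float)
    slice_missing = np.asarray(slice_missing, dtype=bool)
    _check_positive(slice_values, slice_missing)
    n, m = slice_values.shape
    eligible = [j for j in range(m) if (~slice_missing[:, j]).sum() >= params.mx]
    edges: dict = {}
    for a, b in combinations(eligible, 2):
        present = ~(slice_missing[:, a] | slice_missing[:, b])
        if present.sum() < params.mx:
            continue
        objs = np.nonzero(present)[0]
        subsets = ratio_range(
            slice_values[objs, a], slice_values[objs, b], params.epsilon, params.mx, objs
        )
        if subsets:
            edges[(a, b)] = subsets
    return CoherenceMultigraph(nodes=tuple(eligible), edges=edges)


def _mask_of(ids) -> int:
    m = 0
    for i in ids:
        m |= 1 << int(i)
    return m


def _ids_of(mask: int) -> tuple:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


def _maximal_sets(sets):
    """Keep only the inclusion-maximal frozensets of an iterable."""
    uniq = sorted(set(sets), key=len, reverse=True)
    out = []
    for s in uniq:
        if not any(s < t for t in out):
            out.append(s)
    return out


def _maximal_masks(masks):
    """Keep only the inclusion-maximal bitmasks of an iterable."""
    uniq = sorted(set(masks), key=lambda m: -m.bit_count())
    out: list[int] = []
    for s in uniq:
        if not any(s | t == t for t in out):
            out.append(s)
    return out


def _slice_caps_ok(I, J, slice_values, params: MiningParams) -> bool:
    sub = slice_values[np.ix_(sorted(I), sorted(J))]
    if params.delta_x is not None:
        if np.any(sub.max(axis=0) - sub.min(axis=0) > params.delta_x + 1e-12):
            return False
    if params.delta_y is not None:
        if np.any(sub.max(axis=1) - sub.min(axis=1) > params.delta_y + 1e-12):
            return False
    return True


def mine_slice_biclusters(
    graph: CoherenceMultigraph,
    slice_values,
    params: MiningParams,
    context_id: int = 0,
    slice_missing=None,
) -> list[BiclusterSlice]:
    """Phase 2: all maximal biclusters of one slice from its multigraph.

    A bicluster ``(I, J)`` is valid when every feature pair in ``J`` has an
    edge whose object set contains ``I``; the search is a depth-first walk
    over feature sets in canonical order, carrying the family of maximal
    valid object sets, followed by a containment filter.  Optional
    ``delta_x``/``delta_y`` caps are applied to the maximal blocks.
    """
    slice_values = np.asarray(slice_values, dtype=float)
    n = slice_values.shape[0]
    if slice_missing is None:
        slice_missing = np.zeros_like(slice_values, dtype=bool)
    slice_missing = np.asarray(slice_missing, dtype=bool)
    edge_masks = {
        pair: [_mask_of(E) for E in sets] for pair, sets in graph.edges.items()
    }
    candidates: set = set()

    def valid_sets_after_adding(family, J, f):
        for j in J:
            pair = (min(j, f), max(j, f))
            edges = edge_masks.get(pair, [])
            if not edges:
                return []
            nxt = []
            for S in family:
                for E in edges:
                    inter = S & E
                    if inter.bit_count() >= params.mx:
                        nxt.append(inter)
            family = _maximal_masks(nxt)
            if not family:
                return []
        return family

    def dfs(J, family):
        if len(J) >= params.my:
            Jmask = _mask_of(J)
            for S in family:
                candidates.add((S, Jmask))
        for f in graph.nodes:
            if f <= J[-1]:
                continue
            new_family = valid_sets_after_adding(family, J, f)
            if new_family:
                dfs(J + (f,), new_family)

    for f in graph.nodes:
        seed = _mask_of(np.nonzero(~slice_missing[:, f])[0].tolist())
        dfs((f,), [seed])

    # containment filter -> maximal biclusters only
    cand = sorted(
        candidates,
        key=lambda c: c[0].bit_count() * c[1].bit_count(),
        reverse=True,
    )
    maximal = []
    for S, J in cand:
        if not any(S | S2 == S2 and J | J2 == J2 for S2, J2 in maximal):
            maximal.append((S, J))
    out = [
        BiclusterSlice(frozenset(_ids_of(S)), frozenset(_ids_of(J)), context_id)
        for S, J in maximal
        if S.bit_count() >= params.mx
        and J.bit_count() >= params.my
        and _slice_caps_ok(_ids_of(S), _ids_of(J), slice_values, params)
    ]
    out.sort(key=lambda b: b.key())
    return out


def merge_time_contiguous(
    per_context_biclusters: list[list[BiclusterSlice]],
    params: MiningParams,
    values: np.ndarray | None = None,
) -> list[Tricluster]:
    """Phase 3: stack slice biclusters over consecutive contexts.

    For every run ``K`` of >= ``mz`` consecutive contexts, a candidate
    tricluster is the intersection of one bicluster per slice; candidates are
    grown incrementally (runs ending at k extend runs ending at k-1), then
    filtered for the per-cell temporal spread cap ``delta_z`` (needs
    ``values``) and for maximality (no candidate strictly contained in
    another).  Non-contiguous context sets are never formed.
    """
    p = len(per_context_biclusters)
    if params.delta_z is not None and values is None:
        raise ValueError("delta_z requires the data values")

    def prune_state(blocks):
        # a state contained in another state of the same run can never reach
        # a maximal tricluster its container's line does not also reach, so
        # drop it; grouping by feature mask keeps this near-linear (cross-J
        # containments are left to the final exact maximality filter)
        by_j: dict = {}
        for I, J in set(blocks):
            by_j.setdefault(J, []).append(I)
        kept: list = []
        for J, imasks in by_j.items():
            for I in _maximal_masks(imasks):
                kept.append((I, J))
        return kept

    # state[start] = antichain of (I, J) masks valid over the run start..k
    candidates: set = set()
    prev: dict = {}
    for k in range(p):
        cur: dict = {}
        slice_sets = prune_state(
            [
                (_mask_of(b.object_ids), _mask_of(b.feature_ids))
                for b in per_context_biclusters[k]
            ]
        )
        cur[k] = slice_sets
        for start, blocks in prev.items():
            extended = set()
            for I1, J1 in blocks:
                for I2, J2 in slice_sets:
                    I, J = I1 & I2, J1 & J2
                    if I.bit_count() >= params.mx and J.bit_count() >= params.my:
                        extended.add((I, J))
            if extended:
                cur[start] = prune_state(extended)
        for start, blocks in cur.items():
            if k - start + 1 >= params.mz:
                for I, J in blocks:
                    candidates.add((I, J, tuple(range(start, k + 1))))
        prev = cur

    tris = [Tricluster(_ids_of(I), _ids_of(J), K) for I, J, K in candidates]
    if params.delta_z is not None:
        kept = []
        for t in tris:
            sub = values[np.ix_(t.object_ids, t.feature_ids, t.context_ids)]
            spread = sub.max(axis=2) - sub.min(axis=2)
            if np.all(spread <= params.delta_z + 1e-12):
                kept.append(t)
        tris = kept
    # maximality: drop triclusters strictly contained in another
    masked = sorted(
        (
            (_mask_of(t.object_ids), _mask_of(t.feature_ids), _mask_of(t.context_ids), t)
            for t in tris
        ),
        key=lambda x: -x[3].n_cells(),
    )
    kept: list = []
    maximal: list[Tricluster] = []
    for I, J, K, t in masked:
        if not any(
            I | I2 == I2 and J | J2 == J2 and K | K2 == K2 for I2, J2, K2 in kept
        ):
            kept.append((I, J, K))
            maximal.append(t)
    maximal.sort(key=Tricluster.sort_key)
    return maximal


def _overlap_cells(t1: Tricluster, t2: Tricluster) -> int:
    oi = len(set(t1.object_ids) & set(t2.object_ids))
    oj = len(set(t1.feature_ids) & set(t2.feature_ids))
    ok = len(set(t1.context_ids) & set(t2.context_ids))
    return oi * oj * ok


def _bounding(t1: Tricluster, t2: Tricluster) -> Tricluster:
    ks = sorted(set(t1.context_ids) | set(t2.context_ids))
    K = tuple(range(ks[0], ks[-1] + 1))  # contiguous bounding run
    return Tricluster(
        tuple(set(t1.object_ids) | set(t2.object_ids)),
        tuple(set(t1.feature_ids) | set(t2.feature_ids)),
        K,
    )


def prune_overlaps(
    triclusters: list[Tricluster],
    params: MiningParams,
    data: ThreeWayDataset | None = None,
    values: np.ndarray | None = None,
) -> list[Tricluster]:
    """Delete or merge heavily overlapping triclusters.

    Deletion: a tricluster whose cell overlap with a strictly larger one
    exceeds ``eta`` of its OWN cell count is removed.  Merge: two triclusters
    whose union-normalised overlap exceeds ``gamma`` are replaced by the
    bounding tricluster of their union if that block passes the coherence
    check (needs ``data``), else both are kept.  The process iterates to a
    fixed point, visiting triclusters largest-first with lexicographic ties.
    """
    tris = sorted(set(triclusters), key=lambda t: (-t.n_cells(), t.sort_key()))
    changed = True
    while changed:
        changed = False
        # deletion pass
        kept = []
        for t in tris:
            doomed = False
            for big in tris:
                if big is t or big.n_cells() <= t.n_cells():
                    continue
                if _overlap_cells(t, big) > params.eta * t.n_cells():
                    doomed = True
                    break
            if not doomed:
                kept.append(t)
        if len(kept) != len(tris):
            tris = kept
            changed = True
            continue
        # merge pass
        if params.gamma < 1.0 and data is not None:
            merged = None
            for a, b in combinations(tris, 2):
                inter = _overlap_cells(a, b)
                union = a.n_cells() + b.n_cells() - inter
                if union and inter / union > params.gamma:
                    bb = _bounding(a, b)
                    ok, _ = check_coherence(bb, data, params, _values=values)
                    if ok:
                        merged = (a, b, bb)
                        break
            if merged:
                a, b, bb = merged
                tris = [t for t in tris if t not in (a, b)] + [bb]
                tris = sorted(set(tris), key=lambda t: (-t.n_cells(), t.sort_key()))
                changed = True
    tris.sort(key=Tricluster.sort_key)
    return tris


def check_coherence(
    candidate: Tricluster,
    data: ThreeWayDataset,
    params: MiningParams,
    _values: np.ndarray | None = None,
) -> tuple[bool, str]:
    """Independent coherence oracle for a candidate tricluster.

    Returns ``(ok, report)`` where the report names the first violated
    condition: sizes, contiguity, missing cells, the pairwise ratio-range
    condition on any slice, or a delta cap.
    """
    I = sorted(candidate.object_ids)
    J = sorted(candidate.feature_ids)
    K = sorted(candidate.context_ids)
    if len(I) < params.mx or len(J) < params.my or len(K) < params.mz:
        return False, f"size: |I|={len(I)}, |J|={len(J)}, |K|={len(K)} below minimums"
    if list(K) != list(range(K[0], K[-1] + 1)):
        return False, f"contiguity: context set {tuple(K)} is not a consecutive run"
    if _values is None:
        _values = _transform_values(data.values, data.missing_mask, params)
    if data.missing_mask[np.ix_(I, J, K)].any():
        cell = np.argwhere(data.missing_mask[np.ix_(I, J, K)])[0]
        loc = (I[cell[0]], J[cell[1]], K[cell[2]])
        return False, f"missing cell at {loc}"
    sub = _values[np.ix_(I, J, K)]
    if np.any(sub <= 0):
        loc = tuple(np.argwhere(sub <= 0)[0])
        return False, f"non-positive value at local cell {loc}"
    for kk, k in enumerate(K):
        sl = sub[:, :, kk]
        for a in range(len(J)):
            for b in range(a + 1, len(J)):
                r = sl[:, b] / sl[:, a]
                if r.max() - r.min() > params.epsilon + 1e-12:
                    return False, (
                        f"ratio range {r.max() - r.min():.6g} > epsilon for features "
                        f"({J[a]}, {J[b]}) at context {k}"
                    )
        if params.delta_x is not None and np.any(
            sl.max(axis=0) - sl.min(axis=0) > params.delta_x + 1e-12
        ):
            return False, f"delta_x cap violated at context {k}"
        if params.delta_y is not None and np.any(
            sl.max(axis=1) - sl.min(axis=1) > params.delta_y + 1e-12
        ):
            return False, f"delta_y cap violated at context {k}"
    if params.delta_z is not None:
        spread = sub.max(axis=2) - sub.min(axis=2)
        if np.any(spread > params.delta_z + 1e-12):
            ij = np.argwhere(spread > params.delta_z + 1e-12)[0]
            return False, f"delta_z cap violated for cell series ({I[ij[0]]}, {J[ij[1]]})"
    return True, "ok"


def tc_tricluster(data: ThreeWayDataset, params: MiningParams) -> list[Tricluster]:
    """Run the full three-phase TCtriCluster search on a dataset.

    Deterministic for fixed input and parameters; every returned tricluster
    passes :func:`check_coherence`.
    """
    values = _transform_values(data.values, data.missing_mask, params)
    _check_positive(values, data.missing_mask)
    per_context = []
    for k in range(len(data.contexts)):
        sv, sm = values[:, :, k], data.missing_mask[:, :, k]
        graph = build_multigraph(sv, sm, params)
        per_context.append(mine_slice_biclusters(graph, sv, params, context_id=k))
    tris = merge_time_contiguous(per_context, params, values=values)
    # missing cells inside a stacked block disqualify it
    tris = [
        t
        for t in tris
        if not data.missing_mask[
            np.ix_(t.object_ids, t.feature_ids, t.context_ids)
        ].any()
    ]
    tris = prune_overlaps(tris, params, data=data, values=values)
    return tris


def write_triclusters(triclusters, path, params: MiningParams | None = None) -> None:
    """Write triclusters as JSON-lines (0-based indices) with provenance."""
    prov = asdict(params) if params is not None else {}
    with open(path, "w") as fh:
        for tid, t in enumerate(triclusters):
            fh.write(
                json.dumps(
                    {
                        "id": tid,
                        "objects": list(t.object_ids),
                        "features": list(t.feature_ids),
                        "contexts": list(t.context_ids),
                        "provenance": prov,
                    }
                )
                + "\n"
            )


def read_triclusters(path) -> list[Tricluster]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(
                    Tricluster(tuple(d["objects"]), tuple(d["features"]), tuple(d["contexts"]))
                )
    return out
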