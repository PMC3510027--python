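"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain loops, enumeration or
closed-form arithmetic, independent of the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- kinetics ---------------------------------------------------------------

def ols_slope_normal_equations(t, y) -> float:
    """OLS slope via the raw normal equations (sums, not centered)."""
    t = list(map(float, t))
    y = list(map(float, y))
    n = len(t)
    st, sy = sum(t), sum(y)
    stt = sum(x * x for x in t)
    sty = sum(a * b for a, b in zip(t, y))
    return (n * sty - st * sy) / (n * stt - st * st)


# --- normalization ----------------------------------------------------------

def position_normalize_loop(plates: dict[str, dict[str, float]],) -> dict[str, dict[str, float]]:
    """Naive per-position batch normalization over plate dicts."""
    wells = sorted(next(iter(plates.values())))
    out = {p: {} for p in plates}
    for w in wells:
        vals = [plates[p][w] for p in plates]
        mean = sum(vals) / len(vals)
        for p in plates:
            out[p][w] = plates[p][w] / mean
    return out


def control_normalize_loop(values: dict[str, float], neg_wells) -> dict[str, float]:
    ref = sum(values[w] for w in neg_wells) / len(neg_wells)
    return {w: v / ref for w, v in values.items()}


def mean_sem_closed_form(values) -> tuple[float, float]:
    v = list(map(float, values))
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


# --- ontology / enrichment --------------------------------------------------

def ancestors_by_relaxation(edges: list[tuple[str, str]], term: str) -> set[str]:
    """Inclusive ancestor set by repeated edge relaxation (no graph library)."""
    anc = {term}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if child in anc and parent not in anc:
                anc.add(parent)
                changed = True
    return anc


def propagate_by_relaxation(edges, annots: dict[str, set[str]]) -> dict[str, set[str]]:
    out = {}
    for gene, terms in annots.items():
        closed = set()
        for t in terms:
            closed |= ancestors_by_relaxation(edges, t)
        out[gene] = closed
    return out


def bfs_level(edges: list[tuple[str, str]], term: str, root: str) -> int:
    """Shortest child->parent path length from term to root, by plain BFS."""
    frontier = {term}
    level = 0
    seen = set()
    while frontier:
        if root in frontier:
            return level
        seen |= frontier
        frontier = {
            p for c, p in edges if c in frontier and p not in seen
        }
        level += 1
    raise ValueError(f"{term} unreachable from {root}")


def pcu_exhaustive(
    edges: list[tuple[str, str]],
    annots: dict[str, set[str]],
    study: set[str],
    population: set[str],
    term: str,
) -> float:
    """Parent-Child-Union upper-tail p by exhaustive subset enumeration.

    Recomputes the conditioning sets with loop-based propagation, then
    enumerates every subset of the parent-union population of the study
    size and counts the fraction with at least the observed number of
    term-annotated genes.
    """
    prop = propagate_by_relaxation(edges, annots)
    parents = {p for c, p in edges if c == term}
    if parents:
        def in_union(g):
            return any(t in prop.get(g, ()) for t in parents)
    else:
        def in_union(g):
            return True
    pop_union = sorted(g for g in population if in_union(g))
    study_union = [g for g in study if in_union(g)]
    if not study_union:
        return 1.0
    term_genes = {g for g in pop_union if term in prop.get(g, ())}
    k = sum(1 for g in study_union if term in prop.get(g, ()))
    n = len(study_union)
    total = 0
    at_least = 0
    for subset in itertools.combinations(pop_union, n):
        total += 1
        if sum(1 for g in subset if g in term_genes) >= k:
            at_least += 1
    return at_least / total


def bh_sort_cummin(p) -> list[float]:
    """BH adjustment by sort + cumulative minimum (numpy reference)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def two_prop_z_longhand(x1, n1, x2, n2):
    """Pooled two-proportion z and two-tailed normal p, spelled out."""
    p1 = x1 / n1
    p2 = x2 / n2
    pc = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pc * (1 - pc) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * (1 - _phi(abs(z)))
    return z, p


def _phi(x):
    return 0.5 * (1 + math.erf(x / math.sqrt(2)))


# --- networks ---------------------------------------------------------------

def induced_subgraph_double_loop(edges: set[frozenset], seeds: set[str]):
    """Brute-force direct network: seed pairs joined by an edge."""
    members = set()
    kept_edges = set()
    for a in seeds:
        for b in seeds:
            if a < b and frozenset((a, b)) in edges:
                members |= {a, b}
                kept_edges.add(frozenset((a, b)))
    return members, kept_edges


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def shortest_path_members_bfs(
    adj: dict[str, set[str]], seeds: set[str], max_intervening: int
) -> set[str]:
    """All nodes on qualifying canonical shortest paths, by brute force.

    Enumerates every shortest path per seed pair via DFS over BFS
    distance layers; a pair qualifies when some shortest path has at
    most ``max_intervening`` non-seed interior nodes, and the
    lexicographically smallest qualifying interior is kept.
    """
    members = set(s for s in seeds if s in adj)
    for a in sorted(s for s in seeds if s in adj):
        da = bfs_distances(adj, a)
        for b in sorted(s for s in seeds if s in adj):
            if b <= a or b not in da:
                continue
            paths = []
            _enumerate_paths(adj, a, b, da[b], [a], paths)
            best = None
            for p in paths:
                interior = p[1:-1]
                if sum(1 for n in interior if n not in seeds) > max_intervening:
                    continue
                if best is None or tuple(interior) < tuple(best[1:-1]):
                    best = p
            if best:
                members |= set(best)
    return members


def _enumerate_paths(adj, node, target, remaining, prefix, out):
    if node == target:
        out.append(list(prefix))
        return
    if remaining == 0:
        return
    dt = bfs_distances(adj, target)
    for nbr in sorted(adj.get(node, ())):
        if dt.get(nbr, math.inf) == remaining - 1:
            _enumerate_paths(adj, nbr, target, remaining - 1, prefix + [nbr], out)


# --- screen-level Monte-Carlo oracle ---------------------------------------

def mc_screen_stats(
    n_sirna,
    n_spiked,
    effect,
    noise_sd,
    rng,
    pos_sd=0.15,
    scale_sd=0.05,
    replicates=3,
    plates_per_day=10,
    n_test=84,
):
    """One summary-level simulation of the screen under the generator's
    noise model and the two-stage normalization.

    Implements the generative chain directly on normalized-value
    matrices (position factors, plate scales, replicate effect noise,
    per-position batch division, per-plate negative-control division)
    without touching the file-based pipeline.  Kinetic-read and protein
    noise are omitted: with the generator defaults their contribution to
    a normalized value is below 1e-3 relative, negligible against the
    replicate noise.  Returns (hit_fraction, recall, precision).
    """
    n_layout = -(-n_sirna // n_test)
    effects = np.ones(n_sirna)
    spiked_idx = rng.choice(n_sirna, size=n_spiked, replace=False)
    effects[spiked_idx] = effect
    n_wells = 12 + n_test  # 12 control wells first (3 neg, 3 pos, 3+3 tox)
    control_e = np.array([1.0] * 3 + [0.4] * 3 + [0.12] * 3 + [0.10] * 3)
    values = [[] for _ in range(n_sirna)]
    for b0 in range(0, n_layout, plates_per_day):
        lps = range(b0, min(b0 + plates_per_day, n_layout))
        f = np.exp(rng.normal(0, pos_sd, n_wells))
        rows = []
        slices = []
        for lp in lps:
            for _ in range(replicates):
                e = np.ones(n_wells)
                e[:12] = control_e
                sl = np.arange(lp * n_test, min((lp + 1) * n_test, n_sirna))
                e[12 : 12 + sl.size] = effects[sl]
                s = np.exp(rng.normal(0, scale_sd))
                rows.append(s * f * (e + rng.normal(0, noise_sd, n_wells)))
                slices.append(sl)
        m = np.array(rows)
        m = m / m.mean(axis=0)  # position normalization
        m = m / m[:, 0:3].mean(axis=1)[:, None]  # neg-control normalization
        for row, sl in zip(m, slices):
            for j, si in enumerate(sl):
                values[si].append(row[12 + j])
    means = np.array([np.mean(v) for v in values])
    sems = np.array(
        [np.std(v, ddof=1) / math.sqrt(len(v)) for v in values]
    )
    cutoff = 1.0 - means.std(ddof=1)
    hit = (means + sems) < cutoff
    spiked_mask = np.zeros(n_sirna, bool)
    spiked_mask[spiked_idx] = True
    recall = float(hit[spiked_mask].mean()) if n_spiked else float("nan")
    precision = (
        float(spiked_mask[hit].mean()) if hit.any() else float("nan")
    )
    return float(hit.mean()), recall, precision


def mc_predict(n_reps, seed, **kwargs):
    """Average hit fraction / recall / precision over n_reps simulations."""
    import warnings

    rng = np.random.default_rng(seed)
    stats = [mc_screen_stats(rng=rng, **kwargs) for _ in range(n_reps)]
    arr = np.array(stats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN recall at n_spiked=0
        return tuple(np.nanmean(arr, axis=0))
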