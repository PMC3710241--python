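"""Semantic similarity, Ward agglomeration and KGS cut selection."""

import numpy as np
import pytest

from sepminer.clustering import (
    ClusteringError,
    build_term_clusters,
    kgs_penalties,
    select_k,
    ward_cluster,
)
from sepminer.hierarchy import (
    HierarchyError,
    TermHierarchy,
    semantic_similarity,
    similarity_matrix,
)
from sepminer.synth import SynthConfig, generate_hierarchy


def chain_hierarchy():
    labels = {t: t for t in ("root", "x", "y", "z")}
    edges = [("x", "root", "is_a"), ("y", "x", "is_a"), ("z", "root", "is_a")]
    return TermHierarchy(labels, edges)


def test_similarity_identity_is_one():
    h = chain_hierarchy()
    assert semantic_similarity(h, "y", "y") == 1.0
    assert semantic_similarity(h, "root", "root") == 1.0


def test_similarity_root_children_is_zero():
    # deepest common ancestor of two root children is the root itself (depth 0)
    h = chain_hierarchy()
    assert semantic_similarity(h, "x", "z") == 0.0


def test_similarity_chain_parent_child():
    # x at depth 1, y at depth 2, deepest common ancestor x: 2*1/(1+2)
    h = chain_hierarchy()
    assert semantic_similarity(h, "x", "y") == pytest.approx(2 / 3)


def test_similarity_unknown_term_named_in_error():
    with pytest.raises(HierarchyError, match="nope"):
        semantic_similarity(chain_hierarchy(), "x", "nope")


def _nx_similarity(h, a, b):
    """Independent oracle: ancestors and depths via networkx shortest paths."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(h.labels)
    for child, parent, _ in h.edges:
        g.add_edge(child, parent)  # edges point rootward
    anc = lambda t: {t} | nx.descendants(g, t)
    roots = [t for t in h.labels if g.out_degree(t) == 0]
    rev = g.reverse()
    depth = {}
    for t in h.labels:
        depth[t] = min(
            nx.shortest_path_length(rev, r, t) for r in roots
            if nx.has_path(rev, r, t)
        )
    if a == b:
        return 1.0
    common = anc(a) & anc(b)
    denom = depth[a] + depth[b]
    if not common or denom == 0:
        return 0.0
    return 2 * max(depth[c] for c in common) / denom


@pytest.mark.parametrize("seed", range(3))
def test_similarity_matches_graph_oracle_on_random_dags(seed):
    h = generate_hierarchy(
        SynthConfig(seed=seed, hierarchy_branching=3, hierarchy_depth=3,
                    second_parent_rate=0.3)
    )
    terms = sorted(h.terms)
    rng = np.random.default_rng(seed)
    for _ in range(30):
        a, b = (terms[int(i)] for i in rng.integers(len(terms), size=2))
        assert semantic_similarity(h, a, b) == pytest.approx(_nx_similarity(h, a, b))


# ----------------------------------------------------------------------- ward
def lance_williams_ward(dist):
    """Hand implementation of the Ward update on squared distances."""
    n = dist.shape[0]
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dist[i, j] ** 2
    members = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), val = min(
            ((p, v) for p, v in d2.items()
             if p[0] in active and p[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        height = np.sqrt(val)
        merged = members[i] | members[j]
        merges.append((merged, height))
        si, sj = sizes[i], sizes[j]
        for k in sorted(active - {i, j}):
            sk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            new = ((si + sk) * dik + (sj + sk) * djk - sk * val) / (si + sj + sk)
            d2[(k, next_id) if k < next_id else (next_id, k)] = new
        members[next_id] = merged
        sizes[next_id] = si + sj
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return merges


def _scipy_merges(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append((merged, h))
    return out


def test_ward_two_points_merge_at_their_distance():
    dist = np.array([[0.0, 0.7], [0.7, 0.0]])
    Z = ward_cluster(dist)
    assert Z.shape == (1, 4)
    assert Z[0, 2] == pytest.approx(0.7)


def test_ward_tight_pair_merges_first():
    dist = np.array([
        [0.0, 0.1, 0.9],
        [0.1, 0.0, 0.8],
        [0.9, 0.8, 0.0],
    ])
    Z = ward_cluster(dist)
    assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}


def test_ward_matches_lance_williams_oracle():
    rng = np.random.default_rng(42)
    pts = rng.random((6, 2))
    dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    Z = ward_cluster(dist)
    got = _scipy_merges(Z, 6)
    expected = lance_williams_ward(dist)
    for (gm, gh), (em, eh) in zip(got, expected):
        assert gm == em
        assert gh == pytest.approx(eh)


def test_ward_rejects_asymmetric_input():
    with pytest.raises(ClusteringError):
        ward_cluster(np.array([[0.0, 1.0], [0.5, 0.0]]))


# ------------------------------------------------------------------- select_k
def _block_dist(group_sizes, within, between):
    """Groups of pairwise-equidistant points (simplexes), far apart."""
    n = sum(group_sizes)
    dist = np.full((n, n), between)
    start = 0
    for size in group_sizes:
        block = slice(start, start + size)
        dist[block, block] = within
        start += size
    np.fill_diagonal(dist, 0.0)
    return dist


def test_select_k_two_separated_groups():
    # two tight groups of 5: the penalty scan ties across levels with equal
    # within-cluster spread and resolves toward the coarser cut
    dist = _block_dist([5, 5], within=1.0, between=20.0)
    assert select_k(ward_cluster(dist), dist) == 2


def test_select_k_three_pair_groups():
    # merging any two pairs blows up the spread, so three clusters win
    dist = _block_dist([2, 2, 2], within=0.1, between=10.0)
    assert select_k(ward_cluster(dist), dist) == 3


def test_select_k_attains_exhaustive_minimum():
    rng = np.random.default_rng(5)
    pts = rng.random((12, 2))
    dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    Z = ward_cluster(dist)
    pen = kgs_penalties(Z, dist)
    k = select_k(Z, dist)
    assert pen[k] == min(pen.values())


def test_select_k_needs_three_points():
    dist = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ClusteringError):
        select_k(ward_cluster(dist), dist)


# --------------------------------------------------------------- term clusters
def two_subtree_hierarchy():
    labels = {t: t for t in
              ("root", "u", "v", "u1", "u2", "u3", "v1", "v2", "v3")}
    edges = [("u", "root", "is_a"), ("v", "root", "is_a")]
    edges += [(f"u{i}", "u", "is_a") for i in (1, 2, 3)]
    edges += [(f"v{i}", "v", "is_a") for i in (1, 2, 3)]
    return TermHierarchy(labels, edges)


def test_k_override_all_singletons():
    h = two_subtree_hierarchy()
    terms = ["u1", "u2", "v1"]
    tc = build_term_clusters(terms, h, k=3)
    assert all(c.size == 1 and c.representative in terms for c in tc.clusters)


def test_two_disjoint_subtrees_recovered_at_k2():
    h = two_subtree_hierarchy()
    terms = ["u1", "u2", "u3", "v1", "v2", "v3"]
    tc = build_term_clusters(terms, h, k=2)
    got = {frozenset(c.members) for c in tc.clusters}
    assert got == {frozenset({"u1", "u2", "u3"}), frozenset({"v1", "v2", "v3"})}


def test_cluster_naming_uses_index_and_representative():
    h = two_subtree_hierarchy()
    tc = build_term_clusters(["u1", "u2", "u3"], h, k=1)
    c = tc.clusters[0]
    assert c.index == 1
    assert c.name == f"1_{c.representative_label}"
    assert c.representative in c.members


def test_clustering_is_deterministic():
    h = generate_hierarchy(SynthConfig(seed=9, hierarchy_branching=3,
                                       hierarchy_depth=3))
    terms = sorted(h.leaves())
    a = build_term_clusters(terms, h)
    b = build_term_clusters(terms, h)
    assert [(c.index, c.representative, c.members) for c in a.clusters] == \
           [(c.index, c.representative, c.members) for c in b.clusters]


@pytest.mark.parametrize("seed", range(3))
def test_partition_property_on_random_hierarchies(seed):
    h = generate_hierarchy(SynthConfig(seed=seed, hierarchy_branching=3,
                                       hierarchy_depth=3))
    terms = sorted(h.leaves())
    tc = build_term_clusters(terms, h)
    all_members = [t for c in tc.clusters for t in c.members]
    assert len(all_members) == len(set(all_members)) == len(terms)
    assert set(all_members) == set(terms)


def test_k_larger_than_term_count_rejected():
    h = two_subtree_hierarchy()
    with pytest.raises(ClusteringError):
        build_term_clusters(["u1", "u2"], h, k=5)


def test_representative_is_medoid():
    # u1 and u2 are siblings under u; w is a deeper outlier under u1
    labels = {t: t for t in ("root", "u", "u1", "u2", "w")}
    edges = [("u", "root", "is_a"), ("u1", "u", "is_a"), ("u2", "u", "is_a"),
             ("w", "u1", "is_a")]
    h = TermHierarchy(labels, edges)
    terms = ["u1", "u2", "w"]
    sim = similarity_matrix(h, terms)
    tc = build_term_clusters(terms, h, k=1)
    avg = (sim.sum(axis=1) - 1) / (len(terms) - 1)
    assert tc.clusters[0].representative == terms[int(np.argmax(avg))]
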