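"""Independent brute-force reimplementations used as test oracles.

Everything here is written as plain loops over definitions, deliberately
sharing no code with the package, so that agreement between the two routes
is evidence and not tautology.
"""

from __future__ import annotations

import math


def oracle_variances(values) -> list[float]:
    """Unbiased per-row variance by the textbook two-pass formula."""
    out = []
    for row in values:
        n = len(row)
        mean = sum(row) / n
        out.append(sum((x - mean) ** 2 for x in row) / (n - 1))
    return out


def oracle_top_variance_rows(values, n_keep: int) -> list[int]:
    """Indices of the n_keep highest-variance rows, ties by input order."""
    variances = oracle_variances(values)
    ranked = sorted(range(len(values)), key=lambda i: (-variances[i], i))
    return ranked[: min(n_keep, len(values))]


def oracle_profile(expr_vector, gene_ids, set_names, members):
    """Membership-masked profile: genes x sets nested lists."""
    profile = []
    for p, gene in enumerate(gene_ids):
        row = []
        for name in set_names:
            row.append(expr_vector[p] if gene in members[name] else 0.0)
        profile.append(row)
    return profile


def oracle_distances(profile):
    """Euclidean distances between profile columns, by explicit loops."""
    n_genes = len(profile)
    n_sets = len(profile[0])
    d = [[0.0] * n_sets for _ in range(n_sets)]
    for q in range(n_sets):
        for r in range(n_sets):
            ssq = 0.0
            for p in range(n_genes):
                diff = profile[p][q] - profile[p][r]
                ssq += diff * diff
            d[q][r] = math.sqrt(ssq)
    return d


def oracle_adjacency(distances, fraction, rule="largest_distance"):
    """Keep max(1, floor(fraction*m)) edges ranked by weight, ties by index."""
    q = len(distances)
    candidates = [(i, j) for i in range(q) for j in range(i + 1, q)]
    m = len(candidates)
    k = max(1, math.floor(fraction * m + 1e-9))
    if rule == "largest_distance":
        ranked = sorted(candidates, key=lambda e: (-distances[e[0]][e[1]], e[0], e[1]))
    else:
        ranked = sorted(candidates, key=lambda e: (distances[e[0]][e[1]], e[0], e[1]))
    adjacency = [[0] * q for _ in range(q)]
    for i, j in ranked[:k]:
        adjacency[i][j] = 1
        adjacency[j][i] = 1
    return adjacency


def oracle_degrees(adjacency):
    """Per-node neighbour count by explicit enumeration."""
    q = len(adjacency)
    return [sum(1 for j in range(q) if adjacency[i][j]) for i in range(q)]


def oracle_sing(values, gene_ids, set_names, members, n_top, fraction,
                rule="largest_distance"):
    """Straight-line reimplementation of the whole per-sample transform.

    ``values`` is a genes x samples nested list. Returns (degree rows,
    per-sample distance matrices) with rows ordered like the input samples.
    """
    keep = oracle_top_variance_rows(values, n_top)
    kept_genes = [gene_ids[i] for i in keep]
    n_samples = len(values[0])
    degree_rows, distance_mats = [], []
    for j in range(n_samples):
        expr_vector = [values[i][j] for i in keep]
        profile = oracle_profile(expr_vector, kept_genes, set_names, members)
        distances = oracle_distances(profile)
        adjacency = oracle_adjacency(distances, fraction, rule)
        degree_rows.append(oracle_degrees(adjacency))
        distance_mats.append(distances)
    return degree_rows, distance_mats


def oracle_symmetric_difference_sq(expr_vector, gene_ids, members_a, members_b):
    """Sum of squared expression over the membership symmetric difference."""
    total = 0.0
    for p, gene in enumerate(gene_ids):
        in_a = gene in members_a
        in_b = gene in members_b
        if in_a != in_b:
            total += expr_vector[p] ** 2
    return total


def oracle_ward_merge_order(distances, n_obs):
    """Ward (error-sum-of-squares) agglomeration by the Lance-Williams
    update applied directly to the given dissimilarities (ward.D dialect).

    Returns the merge order as a list of frozensets of observation indices.
    """
    clusters = {i: frozenset([i]) for i in range(n_obs)}
    sizes = {i: 1 for i in range(n_obs)}
    d = {
        (i, j): distances[i][j]
        for i in range(n_obs)
        for j in range(i + 1, n_obs)
    }
    next_id = n_obs
    merges = []
    while len(clusters) > 1:
        (a, b), _ = min(
            d.items(), key=lambda kv: (kv[1], kv[0])
        )
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        del clusters[a], clusters[b]
        new_d = {}
        for (i, j), val in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new_d[(i, j)] = val
        for c in clusters:
            if c == next_id:
                continue
            dca = d.get((min(a, c), max(a, c)))
            dcb = d.get((min(b, c), max(b, c)))
            dab = d.get((min(a, b), max(a, b)))
            ni, nj, nk = sizes[a], sizes[b], sizes[c]
            val = ((ni + nk) * dca + (nj + nk) * dcb - nk * dab) / (ni + nj + nk)
            new_d[(min(c, next_id), max(c, next_id))] = val
        d = new_d
        next_id += 1
    return merges
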