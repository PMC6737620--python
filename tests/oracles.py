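"""Brute-force reference implementations used to check the descriptor and
fragmenter code paths.  Everything here is written as plain double loops,
independent of the package's vectorized/BFS implementations."""

import math


def bfs_distances(record, center):
    """Breadth-first distances via repeated edge relaxation (no queue)."""
    n = record.num_atoms()
    dist = {center: 0}
    changed = True
    while changed:
        changed = False
        for (i, j), _ in record.bonds:
            for a, b in ((i, j), (j, i)):
                if a in dist and dist[a] + 1 < dist.get(b, math.inf):
                    dist[b] = dist[a] + 1
                    changed = True
    return [dist.get(i, -1) for i in range(n)]


def shell_members(record, center, k):
    d = bfs_distances(record, center)
    return [i for i in range(record.num_atoms()) if d[i] == k]


def charge_shell_oracle(record, center, K):
    out = []
    for k in range(1, K + 1):
        members = shell_members(record, center, k)
        if not members:
            return None  # inapplicable
        out.append(sum(record.atom_charges[i] for i in members) / len(members))
    return out


def mass_shell_oracle(record, center, K, weights):
    return [
        sum(weights[record.atoms[i][0]] for i in shell_members(record, center, k))
        for k in range(1, K + 1)
    ]


def gacf_oracle(record, center, K):
    qc = record.atom_charges[center]
    return [
        sum(qc * record.atom_charges[i] for i in shell_members(record, center, k))
        for k in range(1, K + 1)
    ]


def euclid(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def crdf_oracle(record, center, grid, beta):
    out = []
    for r in grid:
        total = 0.0
        for j in range(record.num_atoms()):
            if j == center:
                continue
            d = euclid(record.coords3d[center], record.coords3d[j])
            total += record.atom_charges[j] * math.exp(-beta * (r - d) ** 2)
        out.append(total)
    return out


def cacf_oracle(record, center, grid, beta):
    qc = record.atom_charges[center]
    pos, neg = [], []
    for r in grid:
        p_total = n_total = 0.0
        for j in range(record.num_atoms()):
            if j == center:
                continue
            p = qc * record.atom_charges[j]
            d = euclid(record.coords3d[center], record.coords3d[j])
            w = math.exp(-beta * (r - d) ** 2)
            if p > 0:
                p_total += p * w
            elif p < 0:
                n_total += p * w
        pos.append(p_total)
        neg.append(n_total)
    return pos + neg
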