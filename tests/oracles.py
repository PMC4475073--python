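"""Independent brute-force oracles for the test suite.

Deliberately naive implementations that share no code with the package:
flood-fill labeling, exhaustive simple-path enumeration for maximum
product-path probabilities, breadth-first pair enumeration for IIC, and
all-pairs pixel distances. They are only usable at toy sizes.
"""

from collections import deque

import numpy as np


def flood_fill_labels(grid: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labels by explicit BFS flood fill."""
    h, w = grid.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if grid[r0, c0] and not labels[r0, c0]:
                nxt += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = nxt
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and grid[rr, cc] \
                                and not labels[rr, cc]:
                            labels[rr, cc] = nxt
                            queue.append((rr, cc))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label rasters induce the same pixel partition."""
    if a.shape != b.shape:
        return False
    if not np.array_equal(a > 0, b > 0):
        return False
    mapping = {}
    reverse = {}
    for x, y in zip(a.ravel(), b.ravel()):
        if x == 0:
            continue
        if mapping.setdefault(x, y) != y or reverse.setdefault(y, x) != x:
            return False
    return True


def enumerate_pstar(n: int, prob: np.ndarray) -> np.ndarray:
    """Max product-path probability over all simple paths (exhaustive)."""
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i] = 1.0
    for start in range(n):
        stack = [(start, 1.0, 1 << start)]
        while stack:
            node, p, visited = stack.pop()
            for nb in range(n):
                if visited & (1 << nb) or prob[node, nb] <= 0:
                    continue
                q = p * prob[node, nb]
                if q > out[start, nb]:
                    out[start, nb] = q
                stack.append((nb, q, visited | (1 << nb)))
    return out


def bfs_link_counts(n: int, adjacent: np.ndarray) -> np.ndarray:
    """Number of links on the shortest topological path; -1 if none."""
    out = np.full((n, n), -1, dtype=int)
    for start in range(n):
        out[start, start] = 0
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nb in range(n):
                if adjacent[node, nb] and out[start, nb] < 0:
                    out[start, nb] = out[start, node] + 1
                    queue.append(nb)
    return out


def pc_numerator_oracle(attrs: np.ndarray, prob: np.ndarray) -> float:
    pstar = enumerate_pstar(len(attrs), prob)
    return sum(
        attrs[i] * attrs[j] * pstar[i, j]
        for i in range(len(attrs)) for j in range(len(attrs))
    )


def iic_numerator_oracle(attrs: np.ndarray, adjacent: np.ndarray) -> float:
    n = len(attrs)
    nl = bfs_link_counts(n, adjacent)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if nl[i, j] >= 0:
                total += attrs[i] * attrs[j] / (1.0 + nl[i, j])
    return total


def min_pixel_distance(labels: np.ndarray, id_a: int, id_b: int,
                       resolution: float) -> float:
    """Minimum center-to-center distance between two patches' pixels,
    brute-forced over every pixel pair."""
    pa = np.argwhere(labels == id_a)
    pb = np.argwhere(labels == id_b)
    best = np.inf
    for r1, c1 in pa:
        for r2, c2 in pb:
            d = np.hypot(r1 - r2, c1 - c2) * resolution
            if d < best:
                best = d
    return best


def random_graph(rng: np.random.Generator, max_nodes: int = 8):
    """A random symmetric probability matrix + attributes for oracle tests."""
    n = int(rng.integers(1, max_nodes + 1))
    attrs = rng.uniform(0.0, 5.0, size=n)
    prob = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.55:
                prob[i, j] = prob[j, i] = rng.uniform(0.0, 1.0)
    return attrs, prob
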