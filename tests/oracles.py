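"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, double loops) and never call the code paths they check.
"""

from __future__ import annotations

import numpy as np

OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
             (0, 1), (1, -1), (1, 0), (1, 1))


def enumerate_shortest_path(weight_fn, shape):
    """Exhaustive DFS over all simple left-to-right paths on the 8-connected
    grid; returns (best_cost, rows-per-column with the last-visited rule)."""
    n_rows, n_cols = shape
    best = {"cost": np.inf, "path": None}

    def dfs(r, c, cost, path, visited):
        if cost >= best["cost"]:
            return
        if c == n_cols - 1:
            best["cost"] = cost
            best["path"] = list(path)
            return
        for dr, dc in OFFSETS_8:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols and (r2, c2) not in visited:
                w = max(float(weight_fn((r, c), (r2, c2))), 1e-6)
                visited.add((r2, c2))
                path.append((r2, c2))
                dfs(r2, c2, cost + w, path, visited)
                path.pop()
                visited.remove((r2, c2))

    for r0 in range(n_rows):
        dfs(r0, 0, 0.0, [(r0, 0)], {(r0, 0)})

    rows = np.full(n_cols, -1, dtype=int)
    for r, c in best["path"]:
        rows[c] = r
    return best["cost"], rows


def naive_energy(labels, T, I, mu_O, mu_B, lambda1, lambda2, sigma, sigma_b,
                 neighborhood=8, damping_floor=True):
    """Double-loop evaluation of the segmentation energy."""
    n_rows, n_cols = T.shape
    regional = 0.0
    for r in range(n_rows):
        for c in range(n_cols):
            r1_o = 2.0 - 2.0 * np.exp(-((mu_O - T[r, c]) ** 2) / (2 * sigma ** 2))
            r1_b = 2.0 - 2.0 * np.exp(-((mu_B - T[r, c]) ** 2) / (2 * sigma ** 2))
            d = 1.0 - I[r, c]
            if r1_o > r1_b:
                r_o = max(d * r1_o, r1_b) if damping_floor else d * r1_o
                r_b = r1_b
            elif r1_b > r1_o:
                r_o = r1_o
                r_b = max(d * r1_b, r1_o) if damping_floor else d * r1_b
            else:
                r_o, r_b = r1_o, r1_b
            regional += r_o if labels[r, c] else r_b
    boundary = 0.0
    offs = ((0, 1), (1, 0)) if neighborhood == 4 else ((0, 1), (1, 0), (1, 1), (1, -1))
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in offs:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                    if labels[r, c] != labels[r2, c2]:
                        dist = float(np.hypot(dr, dc))
                        boundary += np.exp(-((T[r, c] - T[r2, c2]) ** 2)
                                           / (2 * sigma_b ** 2)) / dist
    return lambda1 * regional + lambda2 * boundary


def brute_force_min_energy(T, I, fluid_seeds, tissue_seeds, mu_O, mu_B,
                           lambda1, lambda2, sigma, sigma_b,
                           neighborhood=8, damping_floor=True):
    """Minimum energy over every labeling consistent with the seeds."""
    n_rows, n_cols = T.shape
    seeded = {tuple(p): 1 for p in fluid_seeds}
    seeded.update({tuple(p): 0 for p in tissue_seeds})
    free = [(r, c) for r in range(n_rows) for c in range(n_cols)
            if (r, c) not in seeded]
    best = np.inf
    labels = np.zeros((n_rows, n_cols), dtype=bool)
    for (r, c), v in seeded.items():
        labels[r, c] = bool(v)
    for bits in range(2 ** len(free)):
        for i, (r, c) in enumerate(free):
            labels[r, c] = bool((bits >> i) & 1)
        e = naive_energy(labels, T, I, mu_O, mu_B, lambda1, lambda2,
                         sigma, sigma_b, neighborhood, damping_floor)
        best = min(best, e)
    return best


def naive_confusion(pred, truth):
    """Double-loop confusion counts for metric checks."""
    tp = fp = fn = tn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, t = bool(pred[r, c]), bool(truth[r, c])
            tp += p and t
            fp += p and not t
            fn += (not p) and t
            tn += (not p) and (not t)
    return tp, fp, fn, tn
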