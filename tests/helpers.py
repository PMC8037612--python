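"""Independent brute-force oracles used to pin the fast implementations."""

from collections import deque

import numpy as np

NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def oracle_find_maxima(image, tolerance, plateau_policy="centroid"):
    """Prominence-filtered maxima by exhaustive flood fill.

    Plain-Python reference: enumerate equal-value plateaus with no strictly
    higher neighbor, then for each one walk every 8-connected path that
    never drops to ``value - tolerance`` or below; the maximum dies if such
    a path reaches strictly higher ground, and equal-valued maxima that
    reach each other collapse onto the plateau holding the smallest
    (row, col) pixel. Returns a sorted list of (row, col).
    """
    im = np.asarray(image, dtype=float)
    nr, nc = im.shape

    def neighbors(r, c):
        for dr, dc in NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                yield rr, cc

    # plateaus: BFS over equal values
    seen = np.zeros(im.shape, dtype=bool)
    plateaus = []
    for r0 in range(nr):
        for c0 in range(nc):
            if seen[r0, c0]:
                continue
            v = im[r0, c0]
            comp, is_max = [], True
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.append((r, c))
                for rr, cc in neighbors(r, c):
                    if im[rr, cc] > v:
                        is_max = False
                    elif im[rr, cc] == v and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            if is_max and len(comp) < im.size:  # a constant image has no maxima
                plateaus.append((v, sorted(comp)))

    # flood each maximum without dropping to value - tolerance
    survivors = []
    reaches = {}
    for v, comp in plateaus:
        reached = set(comp)
        queue = deque(comp)
        dies = False
        while queue:
            r, c = queue.popleft()
            for rr, cc in neighbors(r, c):
                if (rr, cc) in reached or im[rr, cc] <= v - tolerance:
                    continue
                if im[rr, cc] > v:
                    dies = True
                reached.add((rr, cc))
                queue.append((rr, cc))
        if not dies:
            survivors.append((v, comp))
            reaches[comp[0]] = reached

    # equal-valued survivors whose floods touch collapse to the lexicographic first
    out = []
    for v, comp in survivors:
        better_peer = any(
            ov == v and ocomp[0] < comp[0] and set(ocomp) & reaches[comp[0]]
            for ov, ocomp in survivors
        )
        if better_peer:
            continue
        if plateau_policy == "centroid":
            rs = [p[0] for p in comp]
            cs = [p[1] for p in comp]
            out.append((int(round(sum(rs) / len(rs))), int(round(sum(cs) / len(cs)))))
        else:
            out.append(comp[0])
    return sorted(out)


def brute_force_density(xyz, radius):
    """All-pairs strict-inequality neighbor counts, O(n^2)."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = xyz[i] - xyz[j]
            if float(d @ d) < radius * radius:
                counts[i] += 1
                counts[j] += 1
    return counts


def peaks_to_set(peaks):
    """Detector DataFrame -> sorted list of (row, col)."""
    return sorted(zip(peaks["y_px"].tolist(), peaks["x_px"].tolist()))


def well_separated_grid(n_side, spacing_um, origin=200.0, jitter_um=5.0, seed=0):
    """n_side² spot positions on a jittered grid, min distance >> psf."""
    rng = np.random.default_rng(seed)
    g = origin + spacing_um * np.arange(n_side)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return pts + rng.uniform(-jitter_um, jitter_um, size=pts.shape)
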