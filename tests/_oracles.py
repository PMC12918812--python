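"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive (double loops, per-pixel scans) and
independent of the code paths it verifies.
"""

import numpy as np


def max_project_loop(stack):
    out = np.full(stack.shape[1:], -np.inf)
    for plane in stack:
        for i in range(plane.shape[0]):
            for j in range(plane.shape[1]):
                out[i, j] = max(out[i, j], plane[i, j])
    return out


def msd_double_loop(xy, max_lag=None):
    n = len(xy)
    lags = range(1, n if max_lag is None else max_lag + 1)
    out = []
    for k in lags:
        acc = 0.0
        cnt = 0
        for i in range(n - k):
            dx = xy[i + k, 0] - xy[i, 0]
            dy = xy[i + k, 1] - xy[i, 1]
            acc += dx * dx + dy * dy
            cnt += 1
        out.append(acc / cnt)
    return np.array(out)


def coverage_loop(starts, ends, size):
    cov = np.zeros(size)
    for s, e in zip(starts, ends):
        for b in range(max(s, 0), min(e, size)):
            cov[b] += 1
    return cov


def regional_max_count(image, threshold):
    """Count regional maxima (8-connected plateaus with no greater neighbour)
    whose value exceeds ``threshold``."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    # flood plateaus of equal value; a plateau is a regional max if no
    # neighbour of any member is greater
    visited = np.zeros((h, w), dtype=bool)
    count = 0
    for r in range(h):
        for c in range(w):
            if visited[r, c]:
                continue
            v = img[r, c]
            stack = [(r, c)]
            visited[r, c] = True
            members = []
            is_max = True
            while stack:
                y, x = stack.pop()
                members.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and (dy or dx):
                            if img[yy, xx] > v:
                                is_max = False
                            elif img[yy, xx] == v and not visited[yy, xx]:
                                visited[yy, xx] = True
                                stack.append((yy, xx))
            if is_max and v > threshold:
                count += 1
    return count


def metaprofile_loop(values, centers, flank, minus=None):
    rows = []
    minus = minus or [False] * len(centers)
    for center, rev in zip(centers, minus):
        row = np.zeros(2 * flank + 1)
        for k, pos in enumerate(range(center - flank, center + flank + 1)):
            if 0 <= pos < len(values):
                row[k] = values[pos]
        rows.append(row[::-1] if rev else row)
    return np.mean(rows, axis=0)
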