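"""Independent brute-force oracles used to check the fast implementations.

Everything here is written from definitions (explicit loops, densified
sampling, closed forms) and deliberately shares no code with the package
beyond basic containers.
"""

from __future__ import annotations

import numpy as np
import shapely


def point_segment_distance(p, a, b) -> float:
    """Euclidean distance from point p to segment ab, from the projection formula."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = float((p - a) @ ab) / denom
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + t * ab)))


def brute_force_nearest(point, geometries) -> float:
    """Minimum distance from a point to any vertex/segment of the geometries."""
    p = np.asarray(point, dtype=float)
    best = np.inf
    for geom in geometries:
        if geom.geom_type == "Point":
            best = min(best, float(np.linalg.norm(p - np.asarray(geom.coords[0]))))
            continue
        if geom.geom_type == "LineString":
            paths = [np.asarray(geom.coords)]
        elif geom.geom_type == "MultiLineString":
            paths = [np.asarray(g.coords) for g in geom.geoms]
        elif geom.geom_type == "Polygon":
            paths = [np.asarray(geom.exterior.coords)]
            paths += [np.asarray(r.coords) for r in geom.interiors]
        else:
            raise NotImplementedError(geom.geom_type)
        for coords in paths:
            for k in range(len(coords) - 1):
                best = min(best, point_segment_distance(p, coords[k], coords[k + 1]))
    return best


def densified_clipped_length(line, center, radius, step=0.1) -> float:
    """Clipped-length oracle: sample points every ``step`` metres along the
    line and count those inside the closed disc, times ``step``."""
    total = line.length
    if total == 0:
        return 0.0
    distances = np.arange(step / 2, total, step)
    pts = shapely.line_interpolate_point(line, distances)
    xy = shapely.get_coordinates(pts)
    c = np.asarray(center, dtype=float)
    inside = ((xy - c) ** 2).sum(axis=1) <= radius**2
    return float(inside.sum() * step)


def raster_scan_mean(values, xll, yll, cell_size, center, radius) -> float:
    """Explicit double loop over cell centres inside the closed disc."""
    nrows, ncols = values.shape
    cx, cy = center
    acc, n = 0.0, 0
    for row in range(nrows):
        y = yll + (nrows - row - 0.5) * cell_size
        for col in range(ncols):
            x = xll + (col + 0.5) * cell_size
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2:
                acc += values[row, col]
                n += 1
    return acc / n


def best_single_predictor(y, X, signs, names) -> str | None:
    """Enumeration oracle for the first forward-selection step.

    Fits every single-predictor OLS, discards wrong-signed slopes, and
    returns the name with the largest R-squared (ties by name)."""
    y = np.asarray(y, dtype=float)
    best = None
    for j, name in enumerate(sorted(names)):
        col = X[:, list(names).index(name)]
        A = np.column_stack([np.ones(len(y)), col])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        if coef[1] * (1 if signs[list(names).index(name)] == "+" else -1) <= 0:
            continue
        resid = y - A @ coef
        r2 = 1 - resid @ resid / ((y - y.mean()) ** 2).sum()
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, name)
    if best is None or best[0] < 0.01:
        return None
    return best[1]


def hat_matrix_loocv(y, X) -> np.ndarray:
    """Closed-form leave-one-out predictions: pred_i = y_i - e_i / (1 - h_ii)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    H = A @ np.linalg.inv(A.T @ A) @ A.T
    e = y - H @ y
    h = np.diag(H)
    return y - e / (1 - h)


def loo_cooks_distance(y, X) -> np.ndarray:
    """Definitional Cook's D via explicit leave-one-out coefficient shifts."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    n, p = A.shape
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    resid = y - A @ beta
    s2 = resid @ resid / (n - p)
    xtx = A.T @ A
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta_i = np.linalg.lstsq(A[mask], y[mask], rcond=None)[0]
        diff = beta - beta_i
        out[i] = diff @ xtx @ diff / (p * s2)
    return out


def morans_i_direct(z, coords, floor=1.0) -> float:
    """Moran's I from the definition with explicit loops."""
    z = np.asarray(z, dtype=float)
    n = len(z)
    zc = z - z.mean()
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = max(np.hypot(*(np.asarray(coords[i]) - np.asarray(coords[j]))), floor)
            w[i, j] = 1.0 / d
    w = w / w.sum(axis=1, keepdims=True)
    num = sum(w[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / (zc @ zc)
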