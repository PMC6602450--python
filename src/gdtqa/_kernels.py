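"""Numba inner loops for superposition search.

The rotation solver follows the quaternion formulation of the rigid
superposition problem: the optimal proper rotation is the dominant
eigenvector of a symmetric 4x4 key matrix built from the cross-covariance of
the two centered point sets.  The dominant eigenvalue is found by Newton
iteration on the characteristic polynomial starting from an upper bound
(the QCP approach used by fast-RMSD codes) and the eigenvector is recovered
from the adjugate, with a shifted power iteration as a fallback for
degenerate spectra.  This is algebraically equivalent to SVD-based Kabsch
with the reflection correction, but runs without LAPACK calls inside tight
loops.  All routines are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _det3(m, r0, r1, r2, c0, c1, c2):
    return (m[r0, c0] * (m[r1, c1] * m[r2, c2] - m[r1, c2] * m[r2, c1])
            - m[r0, c1] * (m[r1, c0] * m[r2, c2] - m[r1, c2] * m[r2, c0])
            + m[r0, c2] * (m[r1, c0] * m[r2, c1] - m[r1, c1] * m[r2, c0]))


@njit(cache=False)
def _quat_power_iteration(key):
    """Fallback dominant eigenvector via shifted power iteration."""
    shift = 0.0
    for i in range(4):
        row = 0.0
        for j in range(4):
            row += abs(key[i, j])
        if row > shift:
            shift = row
    m = key.copy()
    for i in range(4):
        m[i, i] += shift
    v = np.array([1.0, 0.02, 0.03, 0.04])
    v /= np.sqrt((v * v).sum())
    prev = 0.0
    for _ in range(500):
        w = m @ v
        lam = np.sqrt((w * w).sum())
        if lam == 0.0:
            return v
        v = w / lam
        if abs(lam - prev) <= 1e-13 * lam:
            break
        prev = lam
    return v


@njit(cache=False)
def _dominant_quat(key, lam0):
    """Dominant eigenvector of the 4x4 key matrix.

    ``lam0`` is an upper bound on the dominant eigenvalue (half the sum of
    the two sets' centered squared norms); Newton descends monotonically to
    the largest root of the characteristic polynomial.
    """
    # characteristic polynomial x^4 + c2 x^2 + c1 x + c0 (trace is zero)
    tr2 = 0.0
    for i in range(4):
        for j in range(4):
            tr2 += key[i, j] * key[i, j]
    c2 = -0.5 * tr2
    k2 = key @ key
    tr3 = 0.0
    for i in range(4):
        for j in range(4):
            tr3 += k2[i, j] * key[j, i]
    c1 = -tr3 / 3.0
    c0 = (key[0, 0] * _det3(key, 1, 2, 3, 1, 2, 3)
          - key[0, 1] * _det3(key, 1, 2, 3, 0, 2, 3)
          + key[0, 2] * _det3(key, 1, 2, 3, 0, 1, 3)
          - key[0, 3] * _det3(key, 1, 2, 3, 0, 1, 2))

    lam = lam0 if lam0 > 0.0 else 1.0
    for _ in range(60):
        p = ((lam * lam + c2) * lam + c1) * lam + c0
        dp = (4.0 * lam * lam + 2.0 * c2) * lam + c1
        if dp == 0.0:
            break
        step = p / dp
        lam -= step
        if abs(step) <= 1e-13 * (abs(lam) + 1.0):
            break

    # eigenvector from the adjugate of (key - lam I): any non-null column
    m = key.copy()
    for i in range(4):
        m[i, i] -= lam
    q = np.empty(4)
    best = -1.0
    bestq = np.empty(4)
    sign = 1.0
    for col in range(4):
        # cofactor column: use the three columns other than `col`
        cols = np.empty(3, dtype=np.int64)
        k = 0
        for c in range(4):
            if c != col:
                cols[k] = c
                k += 1
        s = 1.0 if col % 2 == 0 else -1.0
        q[0] = s * _det3(m, 1, 2, 3, cols[0], cols[1], cols[2])
        q[1] = -s * _det3(m, 0, 2, 3, cols[0], cols[1], cols[2])
        q[2] = s * _det3(m, 0, 1, 3, cols[0], cols[1], cols[2])
        q[3] = -s * _det3(m, 0, 1, 2, cols[0], cols[1], cols[2])
        nrm = q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3]
        if nrm > best:
            best = nrm
            bestq[:] = q
    scale = tr2 + 1.0
    if best <= 1e-22 * scale * scale * scale:
        return _quat_power_iteration(key)
    return bestq / np.sqrt(best)


@njit(cache=False)
def _rotation_from_quat(q):
    w, x, y, z = q[0], q[1], q[2], q[3]
    r = np.empty((3, 3))
    r[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    r[0, 1] = 2.0 * (x * y - w * z)
    r[0, 2] = 2.0 * (x * z + w * y)
    r[1, 0] = 2.0 * (x * y + w * z)
    r[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    r[1, 2] = 2.0 * (y * z - w * x)
    r[2, 0] = 2.0 * (x * z - w * y)
    r[2, 1] = 2.0 * (y * z + w * x)
    r[2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return r


@njit(cache=False)
def _fit_masked(a, b, mask):
    """Proper rotation + centroids mapping a[mask] onto b[mask].

    Returns (R, mu_a, mu_b) such that R @ (x - mu_a) + mu_b is the
    least-squares rigid map of the selected points of ``a`` onto ``b``.
    """
    n = a.shape[0]
    mu_a = np.zeros(3)
    mu_b = np.zeros(3)
    cnt = 0.0
    for i in range(n):
        if mask[i]:
            cnt += 1.0
            for d in range(3):
                mu_a[d] += a[i, d]
                mu_b[d] += b[i, d]
    for d in range(3):
        mu_a[d] /= cnt
        mu_b[d] /= cnt
    # cross-covariance S[p, q] = sum (a - mu_a)_p (b - mu_b)_q
    s = np.zeros((3, 3))
    ga = 0.0
    gb = 0.0
    for i in range(n):
        if mask[i]:
            ax = a[i, 0] - mu_a[0]
            ay = a[i, 1] - mu_a[1]
            az = a[i, 2] - mu_a[2]
            bx = b[i, 0] - mu_b[0]
            by = b[i, 1] - mu_b[1]
            bz = b[i, 2] - mu_b[2]
            ga += ax * ax + ay * ay + az * az
            gb += bx * bx + by * by + bz * bz
            s[0, 0] += ax * bx
            s[0, 1] += ax * by
            s[0, 2] += ax * bz
            s[1, 0] += ay * bx
            s[1, 1] += ay * by
            s[1, 2] += ay * bz
            s[2, 0] += az * bx
            s[2, 1] += az * by
            s[2, 2] += az * bz
    key = np.empty((4, 4))
    key[0, 0] = s[0, 0] + s[1, 1] + s[2, 2]
    key[0, 1] = s[1, 2] - s[2, 1]
    key[0, 2] = s[2, 0] - s[0, 2]
    key[0, 3] = s[0, 1] - s[1, 0]
    key[1, 1] = s[0, 0] - s[1, 1] - s[2, 2]
    key[1, 2] = s[0, 1] + s[1, 0]
    key[1, 3] = s[2, 0] + s[0, 2]
    key[2, 2] = -s[0, 0] + s[1, 1] - s[2, 2]
    key[2, 3] = s[1, 2] + s[2, 1]
    key[3, 3] = -s[0, 0] - s[1, 1] + s[2, 2]
    key[1, 0] = key[0, 1]
    key[2, 0] = key[0, 2]
    key[3, 0] = key[0, 3]
    key[2, 1] = key[1, 2]
    key[3, 1] = key[1, 3]
    key[3, 2] = key[2, 3]
    q = _dominant_quat(key, 0.5 * (ga + gb))
    return _rotation_from_quat(q), mu_a, mu_b


@njit(cache=False)
def _sq_dists(a, b, rot, mu_a, mu_b, out):
    n = a.shape[0]
    for i in range(n):
        d2 = 0.0
        for p in range(3):
            x = (rot[p, 0] * (a[i, 0] - mu_a[0])
                 + rot[p, 1] * (a[i, 1] - mu_a[1])
                 + rot[p, 2] * (a[i, 2] - mu_a[2]) + mu_b[p])
            dx = x - b[i, p]
            d2 += dx * dx
        out[i] = d2


@njit(cache=False)
def _score_all_cutoffs(d2, cutoffs, best_counts, best_masks):
    """Credit one evaluated superposition to every cutoff's running maximum."""
    n = d2.shape[0]
    for ci in range(cutoffs.shape[0]):
        c2 = cutoffs[ci] * cutoffs[ci]
        cnt = 0
        for i in range(n):
            if d2[i] <= c2:
                cnt += 1
        if cnt > best_counts[ci]:
            best_counts[ci] = cnt
            for i in range(n):
                best_masks[ci, i] = d2[i] <= c2


@njit(cache=False)
def _extend(a, b, cutoff, mask0, d2, mask, within, cutoffs, best_counts,
            best_masks, max_iter):
    """Iteratively refit on the included pairs and re-include within ``cutoff``.

    Starts from ``mask0`` (assumed already fitted/scored by the caller once,
    or not at all - every fit here is scored against all cutoffs anyway).
    """
    n = a.shape[0]
    c2 = cutoff * cutoff
    for i in range(n):
        mask[i] = mask0[i]
    for _ in range(max_iter):
        cnt0 = 0
        for i in range(n):
            if mask[i]:
                cnt0 += 1
        if cnt0 < 3:
            break
        rot, mu_a, mu_b = _fit_masked(a, b, mask)
        _sq_dists(a, b, rot, mu_a, mu_b, d2)
        _score_all_cutoffs(d2, cutoffs, best_counts, best_masks)
        same = True
        for i in range(n):
            within[i] = d2[i] <= c2
            if within[i] != mask[i]:
                same = False
        if same:
            break
        for i in range(n):
            mask[i] = within[i]


@njit(cache=False)
def _window_collinear(a, s, w, tol):
    """True if points a[s:s+w] lie (numerically) on a line."""
    best = 0.0
    for i in range(s, s + w - 2):
        ux = a[i + 1, 0] - a[i, 0]
        uy = a[i + 1, 1] - a[i, 1]
        uz = a[i + 1, 2] - a[i, 2]
        vx = a[i + 2, 0] - a[i, 0]
        vy = a[i + 2, 1] - a[i, 1]
        vz = a[i + 2, 2] - a[i, 2]
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        c2 = cx * cx + cy * cy + cz * cz
        if c2 > best:
            best = c2
    return best <= tol * tol


@njit(cache=False)
def gdt_search(a, b, cutoffs, window_sizes, max_iter):
    """Seed-and-extend GDT search.

    Seeds are every contiguous correspondence window of each requested size.
    Each seed is superposed once and credited to every cutoff; each cutoff
    then extends the seed by alternating refit-on-included with re-inclusion
    of all pairs within the cutoff until stable.  A final cross-seeding round
    re-extends each cutoff from the best inclusion set found at every other
    cutoff.  Every reported count is measured under a superposition fitted on
    >= 3 pairs, so the result never exceeds the exhaustive-subset optimum.

    Returns (best_counts, best_masks): per-cutoff maximal pair counts and
    the inclusion masks achieving them.
    """
    n = a.shape[0]
    nc = cutoffs.shape[0]
    best_counts = np.zeros(nc, dtype=np.int64)
    best_masks = np.zeros((nc, n), dtype=np.bool_)
    d2 = np.empty(n)
    mask = np.empty(n, dtype=np.bool_)
    within = np.empty(n, dtype=np.bool_)
    seed = np.empty(n, dtype=np.bool_)
    for wi in range(window_sizes.shape[0]):
        w = window_sizes[wi]
        if w < 3 or w > n:
            continue
        for s in range(n - w + 1):
            if _window_collinear(a, s, w, 1e-9):
                continue
            for i in range(n):
                seed[i] = (i >= s) and (i < s + w)
            # one shared window fit, credited to all cutoffs
            rot, mu_a, mu_b = _fit_masked(a, b, seed)
            _sq_dists(a, b, rot, mu_a, mu_b, d2)
            _score_all_cutoffs(d2, cutoffs, best_counts, best_masks)
            for ci in range(nc):
                c2 = cutoffs[ci] * cutoffs[ci]
                cnt = 0
                same = True
                for i in range(n):
                    within[i] = d2[i] <= c2
                    if within[i]:
                        cnt += 1
                    if within[i] != seed[i]:
                        same = False
                if same or cnt < 3:
                    continue
                _extend(a, b, cutoffs[ci], within, d2, mask, within,
                        cutoffs, best_counts, best_masks, max_iter)
    # dense seeding for tiny instances: every 3-subset (non-contiguous too),
    # optionally widened by a fourth member; contiguous windows alone cannot
    # reach isolated triples, and at this size the extra seeds are cheap
    if n <= 14:
        for i0 in range(n - 2):
            for i1 in range(i0 + 1, n - 1):
                for i2 in range(i1 + 1, n):
                    ux = a[i1, 0] - a[i0, 0]
                    uy = a[i1, 1] - a[i0, 1]
                    uz = a[i1, 2] - a[i0, 2]
                    vx = a[i2, 0] - a[i0, 0]
                    vy = a[i2, 1] - a[i0, 1]
                    vz = a[i2, 2] - a[i0, 2]
                    cx = uy * vz - uz * vy
                    cy = uz * vx - ux * vz
                    cz = ux * vy - uy * vx
                    if cx * cx + cy * cy + cz * cz <= 1e-18:
                        continue
                    for i3 in range(i2, n):
                        for i4 in range(i3, n):
                            # i4 == i3 == i2 keeps the bare triple; larger
                            # indices widen it to a quadruple or quintuple
                            for i in range(n):
                                seed[i] = (i == i0) or (i == i1) or (i == i2) \
                                    or (i == i3) or (i == i4)
                            rot, mu_a, mu_b = _fit_masked(a, b, seed)
                            _sq_dists(a, b, rot, mu_a, mu_b, d2)
                            _score_all_cutoffs(d2, cutoffs, best_counts, best_masks)
                            for ci in range(nc):
                                c2 = cutoffs[ci] * cutoffs[ci]
                                cnt = 0
                                for i in range(n):
                                    within[i] = d2[i] <= c2
                                    if within[i]:
                                        cnt += 1
                                if cnt >= 3:
                                    _extend(a, b, cutoffs[ci], within, d2, mask,
                                            within, cutoffs, best_counts,
                                            best_masks, max_iter)
    # cross-seeding: re-extend each cutoff from the other cutoffs' best sets
    for src in range(nc):
        for ci in range(nc):
            if src == ci:
                continue
            for i in range(n):
                seed[i] = best_masks[src, i]
            _extend(a, b, cutoffs[ci], seed, d2, mask, within,
                    cutoffs, best_counts, best_masks, max_iter)
    return best_counts, best_masks


@njit(cache=False)
def oracle_search(a, b, cutoffs):
    """Exhaustive-subset GDT reference: superpose on every subset of size >= 3.

    Intended for n <= 12 (2^n subsets); the caller guards the size.
    """
    n = a.shape[0]
    nc = cutoffs.shape[0]
    best_counts = np.zeros(nc, dtype=np.int64)
    best_masks = np.zeros((nc, n), dtype=np.bool_)
    d2 = np.empty(n)
    mask = np.empty(n, dtype=np.bool_)
    for bits in range(1, 1 << n):
        k = 0
        for i in range(n):
            mask[i] = (bits >> i) & 1 == 1
            if mask[i]:
                k += 1
        if k < 3:
            continue
        rot, mu_a, mu_b = _fit_masked(a, b, mask)
        _sq_dists(a, b, rot, mu_a, mu_b, d2)
        _score_all_cutoffs(d2, cutoffs, best_counts, best_masks)
    return best_counts, best_masks
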