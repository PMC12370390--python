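"""Independent reference implementations used to cross-check the package.

These deliberately use naive double loops and literal formula transcriptions
so that they share no code path with the implementation under test.
"""

import math

import numpy as np


def brute_force_glcm(levels, mask, ng, offset, symmetric):
    """Exhaustive pair-counting co-occurrence matrix.

    Walks every pixel, looks up its neighbour at ``offset``, and counts the
    ordered grey-tone pair when both pixels are inside the image and the
    mask.  Returns the normalized matrix, or None if no pair contributes.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    dr, dc = offset
    counts = np.zeros((ng, ng), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1.0
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def literal_haralick(p, log_base=2):
    """Term-by-term evaluation of the five co-occurrence statistics."""
    p = np.asarray(p, dtype=float)
    ng = p.shape[0]
    energy = 0.0
    entropy = 0.0
    contrast = 0.0
    homogeneity = 0.0
    for i in range(ng):
        for j in range(ng):
            pij = p[i, j]
            energy += pij * pij
            if pij > 0:
                entropy -= pij * (
                    math.log2(pij) if log_base == 2 else math.log(pij)
                )
            contrast += (i - j) ** 2 * pij
            homogeneity += pij / (1.0 + (i - j) ** 2)
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sigma_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sigma_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))
    if sigma_x * sigma_y > 0:
        num = sum(i * j * p[i, j] for i in range(ng) for j in range(ng))
        correlation = (num - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = None
    return {
        "energy": energy,
        "entropy": entropy,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": correlation,
    }


def central_difference_gradients(net, x, y, loss_fn, eps=1e-6):
    """Finite-difference gradient of the batch MSE for every parameter."""
    grads = {}
    for name in ("W1", "b1", "W2", "b2"):
        param = getattr(net, name)
        g = np.zeros_like(param)
        it = np.nditer(param, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = param[idx]
            param[idx] = orig + eps
            up = loss_fn(net, x, y)
            param[idx] = orig - eps
            down = loss_fn(net, x, y)
            param[idx] = orig
            g[idx] = (up - down) / (2 * eps)
            it.iternext()
        grads[name] = g
    return grads
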