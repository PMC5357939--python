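"""Independent brute-force oracles used to validate the fast implementations.

Every function here recomputes a quantity by direct enumeration (explicit
loops over thresholds, pixel pairs, sample pairs or pooled breakpoints)
and stays deliberately independent of the package code paths it checks.
"""

from __future__ import annotations

import numpy as np


def otsu_bruteforce(values: np.ndarray) -> int:
    """Exhaustive search over all 256 thresholds maximizing between-class
    variance; returns the lowest maximizer."""
    hist = np.bincount(np.asarray(values, dtype=np.uint8).ravel(), minlength=256)
    p = hist / hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * p[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * p[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def glcm_bruteforce(
    quantized: np.ndarray, offsets: list[tuple[int, int]], levels: int
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrices by explicit pair counting.

    Returns an array (levels, levels, n_offsets).
    """
    q = np.asarray(quantized, dtype=int)
    h, w = q.shape
    mats = np.zeros((levels, levels, len(offsets)))
    for k, (dr, dc) in enumerate(offsets):
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    mats[q[r, c], q[r2, c2], k] += 1
                    mats[q[r2, c2], q[r, c], k] += 1  # symmetric
        s = mats[:, :, k].sum()
        if s > 0:
            mats[:, :, k] /= s
    return mats


def glcm_props_bruteforce(P: np.ndarray) -> dict[str, float]:
    """Haralick statistics of one normalized co-occurrence matrix."""
    L = P.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    contrast = float((P * (i - j) ** 2).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    sd_i = float(np.sqrt((P * (i - mu_i) ** 2).sum()))
    sd_j = float(np.sqrt((P * (j - mu_j) ** 2).sum()))
    if sd_i * sd_j == 0:
        corr = 1.0
    else:
        corr = float((P * (i - mu_i) * (j - mu_j)).sum() / (sd_i * sd_j))
    return dict(Contrast=contrast, Energy=energy, Homogeneity=homogeneity, Correlation=corr)


def lbp_code_bruteforce(image: np.ndarray, r: int, c: int, P: int = 8, R: float = 1.0) -> int:
    """Rotation-invariant uniform LBP code of one pixel by direct sampling.

    Neighbors are sampled counterclockwise at angles 2 pi p / P with
    bilinear interpolation, matching the circular sampling convention of
    the standard implementation.
    """
    img = np.asarray(image, dtype=float)
    center = img[r, c]
    bits = []
    for p in range(P):
        rr = r - R * np.sin(2 * np.pi * p / P)
        cc = c + R * np.cos(2 * np.pi * p / P)
        r0, c0 = int(np.floor(rr)), int(np.floor(cc))
        fr, fc = rr - r0, cc - c0
        val = 0.0
        for dr, wr in ((0, 1 - fr), (1, fr)):
            for dc, wc in ((0, 1 - fc), (1, fc)):
                if 0 <= r0 + dr < img.shape[0] and 0 <= c0 + dc < img.shape[1]:
                    val += wr * wc * img[r0 + dr, c0 + dc]
        # tiny tolerance against interpolation round-off, as in skimage
        bits.append(1 if val >= center - 1e-7 * abs(center) - 1e-12 else 0)
    transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
    if transitions <= 2:
        return sum(bits)
    return P + 1


def auc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean over all positive-negative pairs of [s+ > s-] + 1/2 [s+ = s-]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def ks_d_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| by scanning every pooled breakpoint."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def distance_features_bruteforce(
    centroids: np.ndarray, areas: np.ndarray, half: float = 50.0, nb_half: float = 17.5
) -> dict[str, float]:
    """All-pairs recomputation of the inter-nucleus distance features."""
    n = len(centroids)
    means, maxs, stds, skews, nb_means, nb_counts = [], [], [], [], [], []
    for i in range(n):
        d100, d35 = [], []
        for j in range(n):
            if i == j:
                continue
            dr = centroids[j, 0] - centroids[i, 0]
            dc = centroids[j, 1] - centroids[i, 1]
            dist = np.hypot(dr, dc)
            if abs(dr) <= half and abs(dc) <= half:
                d100.append(dist)
            if abs(dr) <= nb_half and abs(dc) <= nb_half:
                d35.append(dist)
        if d100:
            d100 = np.asarray(d100)
            means.append(d100.mean())
            maxs.append(d100.max())
            stds.append(d100.std())
            if len(d100) >= 3 and d100.std() > 0:
                m = d100.mean()
                skews.append(
                    np.mean((d100 - m) ** 3) / (np.mean((d100 - m) ** 2) ** 1.5)
                )
        nb_counts.append(len(d35))
        if d35:
            nb_means.append(np.mean(d35))
    return dict(
        NhoodMeanDist=np.mean(means),
        NhoodMaxDist=np.mean(maxs),
        NhoodStdDist=np.mean(stds),
        NhoodSkewness=np.mean(skews) if skews else np.nan,
        meanNucDistInNucNB=np.mean(nb_means),
        numberOfNucInNucNB=np.mean(nb_counts),
        meanNucSize=float(np.mean(areas)),
    )


def centroid_match_f1(
    detected: np.ndarray, truth: np.ndarray, tol: float = 10.0
) -> float:
    """F1 of optimal one-to-one centroid matching at a distance tolerance."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    if len(detected) == 0 or len(truth) == 0:
        return 0.0
    D = cdist(detected, truth)
    rows, cols = linear_sum_assignment(D)
    tp = int((D[rows, cols] <= tol).sum())
    precision = tp / len(detected)
    recall = tp / len(truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
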