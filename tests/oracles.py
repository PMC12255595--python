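"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops over pixels, bins or
chart windows, deliberately avoiding the vectorised code paths of the
package, so agreement is a genuine cross-check.
"""

import math


def mse_loop(I, ref):
    m, n = I.shape
    acc = 0.0
    for i in range(m):
        for j in range(n):
            acc += (I[i, j] - ref[i, j]) ** 2
    return acc / (m * n)


def psnr_loop(I, ref):
    peak = max(ref[i, j] for i in range(ref.shape[0]) for j in range(ref.shape[1]))
    err = mse_loop(I, ref)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def sam_loop(I, ref):
    dot = norm1 = norm2 = 0.0
    m, n = I.shape
    for i in range(m):
        for j in range(n):
            dot += I[i, j] * ref[i, j]
            norm1 += I[i, j] ** 2
            norm2 += ref[i, j] ** 2
    c = dot / math.sqrt(norm1 * norm2)
    return math.acos(min(1.0, max(-1.0, c)))


def frobenius_loop(I, ref):
    m, n = I.shape
    acc = 0.0
    for i in range(m):
        for j in range(n):
            acc += (I[i, j] - ref[i, j]) ** 2
    return math.sqrt(acc)


def wjs_loop(I, ref):
    num = den = 0.0
    m, n = I.shape
    for i in range(m):
        for j in range(n):
            num += min(I[i, j], ref[i, j])
            den += max(I[i, j], ref[i, j])
    return num / den


def bcd_loop(I, ref):
    num = den = 0.0
    m, n = I.shape
    for i in range(m):
        for j in range(n):
            num += abs(I[i, j] - ref[i, j])
            den += I[i, j] + ref[i, j]
    return num / den


def histogram_loop(I, n_bins, hi):
    """Counts over n_bins equal-width bins on [0, hi], upper edge closed."""
    counts = [0] * n_bins
    m, n = I.shape
    for i in range(m):
        for j in range(n):
            v = I[i, j]
            if v < 0 or v > hi:
                continue
            k = int(v / hi * n_bins)
            if k == n_bins:  # v == hi
                k -= 1
            counts[k] += 1
    total = sum(counts)
    return [c / total for c in counts]


def bhattacharyya_loop(I, ref, n_bins):
    hi = max(
        max(I[i, j] for i in range(I.shape[0]) for j in range(I.shape[1])),
        max(ref[i, j] for i in range(ref.shape[0]) for j in range(ref.shape[1])),
    )
    p = histogram_loop(I, n_bins, hi)
    q = histogram_loop(ref, n_bins, hi)
    bc = sum(math.sqrt(a * b) for a, b in zip(p, q))
    bd = math.inf if bc == 0.0 else -math.log(bc)
    return bc, bd


def chi2d_loop(I, ref, n_bins):
    hi = max(
        max(I[i, j] for i in range(I.shape[0]) for j in range(I.shape[1])),
        max(ref[i, j] for i in range(ref.shape[0]) for j in range(ref.shape[1])),
    )
    p = histogram_loop(I, n_bins, hi)
    q = histogram_loop(ref, n_bins, hi)
    return 0.5 * sum(
        (a - b) ** 2 / (a + b) for a, b in zip(p, q) if a + b > 0
    )


def entropy_loop(I, n_bins):
    hi = max(I[i, j] for i in range(I.shape[0]) for j in range(I.shape[1]))
    if hi <= 0:
        return 0.0
    p = histogram_loop(I, n_bins, hi)
    return -sum(a * math.log2(a) for a in p if a > 0)


def ssim_global_loop(I, ref, k1, k2, D):
    """Direct evaluation of the single-window SSIM closed form."""
    m, n = I.shape
    N = m * n
    mu1 = sum(I[i, j] for i in range(m) for j in range(n)) / N
    mu2 = sum(ref[i, j] for i in range(m) for j in range(n)) / N
    v1 = sum((I[i, j] - mu1) ** 2 for i in range(m) for j in range(n)) / N
    v2 = sum((ref[i, j] - mu2) ** 2 for i in range(m) for j in range(n)) / N
    cov = (
        sum((I[i, j] - mu1) * (ref[i, j] - mu2) for i in range(m) for j in range(n))
        / N
    )
    c1, c2 = (k1 * D) ** 2, (k2 * D) ** 2
    return ((2 * mu1 * mu2 + c1) * (2 * cov + c2)) / (
        (mu1**2 + mu2**2 + c1) * (v1 + v2 + c2)
    )


def tenengrad_central_loop(I):
    """Central-difference squared-gradient mean over interior pixels."""
    m, n = I.shape
    acc = 0.0
    cnt = 0
    for i in range(1, m - 1):
        for j in range(1, n - 1):
            gx = (I[i, j + 1] - I[i, j - 1]) / 2.0
            gy = (I[i + 1, j] - I[i - 1, j]) / 2.0
            acc += gx**2 + gy**2
            cnt += 1
    return acc / cnt


def sobel_loop(I):
    """Sobel-gradient squared magnitude mean over interior pixels."""
    m, n = I.shape
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    acc = 0.0
    cnt = 0
    for i in range(1, m - 1):
        for j in range(1, n - 1):
            gx = gy = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    gx += kx[di + 1][dj + 1] * I[i + di, j + dj]
                    gy += kx[dj + 1][di + 1] * I[i + di, j + dj]
            acc += gx**2 + gy**2
            cnt += 1
    return acc / cnt


def vif_single_scale_loop(I, ref, sigma_nsq=2.0, eps=1e-10):
    """Pixel-domain VIF at one scale with an explicit 3x3 Gaussian window."""
    import math as _m

    n = 3
    sigma = n / 5.0
    w = [
        [
            _m.exp(-((i - 1) ** 2 + (j - 1) ** 2) / (2 * sigma**2))
            for j in range(n)
        ]
        for i in range(n)
    ]
    s = sum(sum(row) for row in w)
    w = [[v / s for v in row] for row in w]

    def conv(img):
        m_, n_ = img.shape
        out = []
        for i in range(m_ - 2):
            row = []
            for j in range(n_ - 2):
                acc = 0.0
                for a in range(3):
                    for b in range(3):
                        acc += w[a][b] * img[i + a, j + b]
                row.append(acc)
            out.append(row)
        return out

    mu1 = conv(ref)
    mu2 = conv(I)
    m11 = conv(ref * ref)
    m22 = conv(I * I)
    m12 = conv(ref * I)
    num = den = 0.0
    for i in range(len(mu1)):
        for j in range(len(mu1[0])):
            s1 = max(m11[i][j] - mu1[i][j] ** 2, 0.0)
            s2 = max(m22[i][j] - mu2[i][j] ** 2, 0.0)
            s12 = m12[i][j] - mu1[i][j] * mu2[i][j]
            g = s12 / (s1 + eps)
            sv = s2 - g * s12
            if s1 < eps:
                g, sv, s1 = 0.0, s2, 0.0
            if s2 < eps:
                g, sv = 0.0, 0.0
            if g < 0:
                sv, g = s2, 0.0
            sv = max(sv, eps)
            num += _m.log10(1.0 + g * g * s1 / (sv + sigma_nsq))
            den += _m.log10(1.0 + s1 / sigma_nsq)
    return num / den


def scan_rules(z, always_on=False):
    """Window-scanning oracle for the four chart rules.

    ``z`` are standardised exam values in chronological order.  Returns a
    set of (rule_id, index_tuple, side) triples; indices are positions in
    ``z`` of the exams involved.
    """
    out = set()
    for i, zi in enumerate(z):
        fired1 = zi > 2.0 or zi < -2.0
        side = "high" if zi > 0 else "low"
        if fired1:
            out.add((1, (i,), side))
        if not (fired1 or always_on):
            continue
        if zi > 3.0 or zi < -3.0:
            out.add((2, (i,), side))
        if i >= 1:
            if all(z[j] > 2.0 for j in (i - 1, i)) or all(
                z[j] < -2.0 for j in (i - 1, i)
            ):
                out.add((3, (i - 1, i), side))
        if i >= 3:
            w = range(i - 3, i + 1)
            if all(z[j] > 1.0 for j in w) or all(z[j] < -1.0 for j in w):
                out.add((4, tuple(w), side))
    return out
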