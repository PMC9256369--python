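"""Independent brute-force oracles, written with plain Python loops so
they share no code path with the implementations they check."""

import numpy as np


def quantize_half_up(v: float, n_levels: int = 256) -> int:
    level = int(np.floor(v * (n_levels - 1) + 0.5))
    return min(max(level, 0), n_levels - 1)


def gcadw_map_oracle(levels_2d, a: float, n_levels: int = 256):
    """Scalar evaluation of the adaptive-gamma mapping on integer levels."""
    flat = [int(v) for row in levels_2d for v in row]
    n = len(flat)
    hist = [0] * n_levels
    for v in flat:
        hist[v] += 1
    pdf = [h / n for h in hist]
    pmax, pmin = max(pdf), min(pdf)
    if pmax > pmin:
        pdf_w = [pmax * ((p - pmin) / (pmax - pmin)) ** a for p in pdf]
    else:
        pdf_w = pdf[:]
    total_w = sum(pdf_w)
    cdf_w, acc = [], 0.0
    for p in pdf_w:
        acc += p
        cdf_w.append(acc / total_w)
    l_max = max(flat)
    out = []
    for row in levels_2d:
        out_row = []
        for v in row:
            gamma = 1.0 - cdf_w[int(v)]
            if v == 0 and gamma == 0.0:
                out_row.append(float(l_max))
            else:
                out_row.append(l_max * (v / l_max) ** gamma)
        out.append(out_row)
    return np.array(out)


def jeh_oracle(img, window_z: int = 3, n_levels: int = 256):
    """Joint histogram equalization by full pair enumeration."""
    h, w = img.shape
    f = [[quantize_half_up(img[r][c], n_levels) for c in range(w)] for r in range(h)]
    half = window_z // 2
    g = []
    for r in range(h):
        g_row = []
        for c in range(w):
            total = 0.0
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr = min(max(r + dr, 0), h - 1)  # replicate padding
                    cc = min(max(c + dc, 0), w - 1)
                    total += img[rr][cc]
            g_row.append(quantize_half_up(total / (window_z**2), n_levels))
        g.append(g_row)

    hist = {}
    for r in range(h):
        for c in range(w):
            hist[(f[r][c], g[r][c])] = hist.get((f[r][c], g[r][c]), 0) + 1

    def cdf(a, b):
        return sum(n for (p, q), n in hist.items() if p <= a and q <= b)

    cdf_min = min(cdf(a, b) for (a, b) in hist)
    mn = h * w
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            value = cdf(f[r][c], g[r][c])
            out[r, c] = int((n_levels - 1) * (value - cdf_min) / (mn - 1))
    return out / (n_levels - 1)


def hysteresis_oracle(response, low, high, connectivity: int = 8):
    """Breadth-first flood fill from every strong pixel through weak pixels."""
    h, w = response.shape
    weak = response >= low
    strong = response >= high
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    out = np.zeros((h, w), dtype=bool)
    queue = [(r, c) for r in range(h) for c in range(w) if strong[r, c]]
    for r, c in queue:
        out[r, c] = True
    while queue:
        r, c = queue.pop()
        for dr, dc in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and weak[rr, cc] and not out[rr, cc]:
                out[rr, cc] = True
                queue.append((rr, cc))
    return out


def label_components_oracle(mask, connectivity: int = 8):
    """Two-pass-free flood-fill labelling; returns list of pixel sets."""
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                components.append(comp)
    return components


def clean_oracle(mask, min_area: int, connectivity: int = 8):
    """Small-component removal via the labelling oracle."""
    out = np.zeros_like(mask, dtype=bool)
    for comp in label_components_oracle(mask, connectivity):
        if len(comp) >= min_area:
            for r, c in comp:
                out[r, c] = True
    return out


def confusion_oracle(pred, truth, fov=None):
    """Per-pixel loop confusion counting."""
    tp = tn = fp = fn = 0
    h, w = pred.shape
    for r in range(h):
        for c in range(w):
            if fov is not None and not fov[r, c]:
                continue
            if pred[r, c] and truth[r, c]:
                tp += 1
            elif pred[r, c]:
                fp += 1
            elif truth[r, c]:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def sharpness_oracle(img):
    """Direct double loop over forward differences."""
    h, w = img.shape
    total = 0.0
    for p in range(h):
        for q in range(w):
            dx = img[p, q] - img[p + 1, q] if p + 1 < h else 0.0
            dy = img[p, q] - img[p, q + 1] if q + 1 < w else 0.0
            total += (dx * dx + dy * dy) ** 0.5
    return total / (h * w)
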