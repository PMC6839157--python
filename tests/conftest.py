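import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask_pair(rng, side=16, p=0.35):
    """A random prediction/gold mask pair for metric oracle checks."""
    pred = (rng.random((side, side)) < p).astype(np.uint8)
    gold = (rng.random((side, side)) < p).astype(np.uint8)
    return pred, gold


# ---------------------------------------------------------------------------
# independent brute-force oracles (per-pixel loops; never reuse the package's
# vectorized paths)

def confusion_loop(pred, gold):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = pred[i, j], gold[i, j]
            if p == 1 and g == 1:
                tp += 1
            elif p == 1 and g == 0:
                fp += 1
            elif p == 0 and g == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def boundary_loop(mask):
    """4-connectivity lesion boundary, image border counts as background."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if mask[i, j] != 1:
                continue
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or mask[ni, nj] == 0:
                    out[i, j] = True
                    break
    return out


def bf_score_loop(pred, gold, tol):
    """Brute-force boundary F1: all-pairs Euclidean distance matching."""
    bp = np.argwhere(boundary_loop(pred))
    bg = np.argwhere(boundary_loop(gold))
    if len(bp) == 0 and len(bg) == 0:
        return float("nan")
    if len(bp) == 0 or len(bg) == 0:
        return 0.0

    def frac_matched(src, dst):
        hits = 0
        for a in src:
            dmin = min(np.hypot(a[0] - b[0], a[1] - b[1]) for b in dst)
            if dmin <= tol:
                hits += 1
        return hits / len(src)

    precision = frac_matched(bp, bg)
    recall = frac_matched(bg, bp)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
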