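"""Independent brute-force reference implementations used only by tests.

Everything here is written deliberately naively (explicit loops, polyfit,
sklearn) so it shares no code path with the package implementations it
checks.
"""

import numpy as np
from sklearn.cross_decomposition import PLSRegression


def naive_msc(X, ref):
    """Row-by-row MSC via polyfit: fit s = a + b*ref, return (s - a)/b."""
    out = np.empty_like(X, dtype=float)
    for i, row in enumerate(np.atleast_2d(X)):
        b, a = np.polyfit(ref, row, 1)
        out[i] = (row - a) / b
    return out


def naive_gap_segment_derivative(x, wavenumbers, segment, gap):
    """Smooth-then-gap-difference first derivative with explicit loops."""
    x = np.asarray(x, float)
    n = x.size
    half = segment // 2
    delta = float(np.median(np.diff(wavenumbers)))
    smoothed = {}
    for i in range(half, n - half):
        smoothed[i] = x[i - half : i + half + 1].mean()
    out, keep = [], []
    for i in range(half + gap, n - half - gap):
        out.append((smoothed[i + gap] - smoothed[i - gap]) / (2 * gap * delta))
        keep.append(wavenumbers[i])
    return np.array(out), np.array(keep)


def naive_window_mask(wavenumbers, windows):
    keep = []
    for i, v in enumerate(wavenumbers):
        if any(lo <= v <= hi for lo, hi in windows):
            keep.append(i)
    return np.array(keep, dtype=int)


def sklearn_pls_predict(X_train, y_train, X_test, k):
    m = PLSRegression(n_components=k, scale=False)
    m.fit(X_train, np.asarray(y_train, float).reshape(-1, 1))
    return m.predict(np.atleast_2d(X_test)).ravel()


def brute_force_press(raw, wavenumbers, y, max_factors, segment, gap, windows):
    """Leave-one-out PRESS refitting MSC/derivative/windows and a sklearn PLS
    from scratch for every fold and factor count."""
    raw = np.asarray(raw, float)
    y = np.asarray(y, float)
    n = raw.shape[0]
    press = np.zeros(max_factors)
    for k in range(1, max_factors + 1):
        for i in range(n):
            train = np.delete(raw, i, axis=0)
            ref = train.mean(axis=0)
            tr = naive_msc(train, ref)
            te = naive_msc(raw[i][None, :], ref)
            tr_d = np.array(
                [naive_gap_segment_derivative(r, wavenumbers, segment, gap)[0] for r in tr]
            )
            te_d, kept_wn = naive_gap_segment_derivative(te[0], wavenumbers, segment, gap)
            if windows is not None:
                idx = naive_window_mask(kept_wn, windows)
                tr_d, te_d = tr_d[:, idx], te_d[idx]
            pred = sklearn_pls_predict(tr_d, np.delete(y, i), te_d, k)[0]
            press[k - 1] += (y[i] - pred) ** 2
    return press


def single_marker_lod(y, x):
    """Closed-form LOD for a single marker: -(n/2) log10(1 - r^2)."""
    r = np.corrcoef(y, x)[0, 1]
    return -(len(y) / 2.0) * np.log10(1.0 - r**2)
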