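"""Naive loop-based reimplementation of the 22 trace descriptors.

Deliberately written with plain Python loops and no shared code with the
package, so it can serve as an independent oracle in equivalence tests.
"""

from __future__ import annotations

import math


def naive_features(times, currents, injection_time, i0, sigma0,
                   smooth_window=5, kappa=3.0, up_window_s=60.0):
    t_rel, y = [], []
    for t, c in zip(times, currents):
        if t >= injection_time:
            t_rel.append(t - injection_time)
            y.append(c)
    n = len(y)
    assert n >= 3

    imax_idx = 0
    imin_idx = 0
    for i in range(n):
        if y[i] > y[imax_idx]:
            imax_idx = i
        if y[i] < y[imin_idx]:
            imin_idx = i
    i_max, i_min = y[imax_idx], y[imin_idx]
    t_imax, t_imin = t_rel[imax_idx], t_rel[imin_idx]
    delta_i = i_max - i_min
    delta_t = t_imax - t_imin
    k_secant = delta_i / delta_t if delta_t != 0 else 0.0
    i_rise = i_max - i0
    i_drop = i0 - i_min
    k_max0 = i_rise / t_imax if t_imax > 0 else 0.0
    k_min0 = (i_min - i0) / t_imin if t_imin > 0 else 0.0
    i_end = y[-1]
    duration = times[-1] - injection_time
    k_all = (i_end - i0) / duration if duration > 0 else 0.0

    integral = 0.0
    for i in range(n - 1):
        integral += 0.5 * (y[i] + y[i + 1]) * (t_rel[i + 1] - t_rel[i])

    h = smooth_window // 2
    smoothed = []
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        smoothed.append(sum(y[lo:hi]) / (hi - lo))

    deriv = []
    for i in range(n):
        if i == 0:
            d = (smoothed[1] - smoothed[0]) / (t_rel[1] - t_rel[0])
        elif i == n - 1:
            d = (smoothed[-1] - smoothed[-2]) / (t_rel[-1] - t_rel[-2])
        else:
            d = (smoothed[i + 1] - smoothed[i - 1]) / (t_rel[i + 1] - t_rel[i - 1])
        deriv.append(d)
    dmax_idx = 0
    dmin_idx = 0
    for i in range(n):
        if deriv[i] > deriv[dmax_idx]:
            dmax_idx = i
        if deriv[i] < deriv[dmin_idx]:
            dmin_idx = i

    early_max = -math.inf
    for i in range(n):
        if t_rel[i] <= up_window_s and y[i] > early_max:
            early_max = y[i]
    up = 1 if early_max > i0 + kappa * sigma0 else 0

    back = 0
    if t_imin < duration:
        for i in range(n):
            if t_rel[i] > t_imin and smoothed[i] >= i_min + kappa * sigma0:
                back = 1
                break

    return {
        "i_max": i_max, "i_min": i_min, "delta_i": delta_i,
        "delta_i_rel": delta_i / i0,
        "t_imax": t_imax, "t_imin": t_imin, "delta_t": delta_t,
        "k_secant": k_secant, "i_rise": i_rise, "i_drop": i_drop,
        "k_max0": k_max0, "k_min0": k_min0, "i_end": i_end,
        "duration": duration, "k_all": k_all, "up": up, "back": back,
        "integral": integral, "d_max": deriv[dmax_idx],
        "d_min": deriv[dmin_idx], "t_dmax": t_rel[dmax_idx],
        "t_dmin": t_rel[dmin_idx],
    }
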