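"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain Python loops / closed
forms, sharing no code with the package, so agreement is evidence and not
tautology.
"""

from __future__ import annotations

import math


def _project(frames):
    """Pixel-wise max over frames by exhaustive looping."""
    n = len(frames)
    h, w = len(frames[0]), len(frames[0][0])
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            m = frames[0][i][j]
            for k in range(1, n):
                if frames[k][i][j] > m:
                    m = frames[k][i][j]
            out[i][j] = float(m)
    return out


def fb_oracle(f_frames, b_frames, noise_f, noise_b, threshold=40.0,
              cal_f=1.0, cal_b=1.0, background="per_pixel"):
    """Naive per-pixel re-implementation of the F/B measurement chain:
    project, subtract closed-shutter background, clamp at zero, dual
    threshold (strict >), ratio, calibrate, average.

    Returns (mean ratio, n retained pixels); (None, 0) if nothing passes.
    """
    pf, pb = _project(f_frames), _project(b_frames)
    bgf, bgb = _project(noise_f), _project(noise_b)
    h, w = len(pf), len(pf[0])
    if background == "scalar":
        sf = sum(sum(r) for r in bgf) / (h * w)
        sb = sum(sum(r) for r in bgb) / (h * w)
        bgf = [[sf] * w for _ in range(h)]
        bgb = [[sb] * w for _ in range(h)]
    ratios = []
    for i in range(h):
        for j in range(w):
            fv = max(pf[i][j] - bgf[i][j], 0.0)
            bv = max(pb[i][j] - bgb[i][j], 0.0)
            if fv > threshold and bv > threshold:
                ratios.append(fv / bv * (cal_f / cal_b))
    if not ratios:
        return None, 0
    return sum(ratios) / len(ratios), len(ratios)


def naive_dft_magnitude(image):
    """|DFT| by the double sum definition (O(N^4); tiny images only)."""
    h, w = len(image), len(image[0])
    out = [[0.0] * w for _ in range(h)]
    for u in range(h):
        for v in range(w):
            re = im = 0.0
            for y in range(h):
                for x in range(w):
                    phase = -2.0 * math.pi * (u * y / h + v * x / w)
                    re += image[y][x] * math.cos(phase)
                    im += image[y][x] * math.sin(phase)
            out[u][v] = math.hypot(re, im)
    return out


def r2_closed_form(xs, ys):
    """Coefficient of determination 1 - SS_res/SS_tot of OLS y on x."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    syy = sum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    ss_res = sum((y - my - slope * (x - mx)) ** 2 for x, y in zip(xs, ys))
    return 1.0 - ss_res / syy if syy > 0 else 1.0


def cox_score_test_oracle(times, events, covariate):
    """Cox partial-likelihood score test at beta=0 with Breslow ties for a
    single numeric covariate; equals the score-weighted log-rank trend
    statistic when event times are untied."""
    n = len(times)
    stat_u = 0.0
    info = 0.0
    for t in sorted({times[i] for i in range(n) if events[i] == 1}):
        risk = [i for i in range(n) if times[i] >= t]
        dead = [i for i in range(n) if times[i] == t and events[i] == 1]
        d = len(dead)
        s_risk = [covariate[i] for i in risk]
        mean_s = sum(s_risk) / len(s_risk)
        mean_s2 = sum(s * s for s in s_risk) / len(s_risk)
        stat_u += sum(covariate[i] for i in dead) - d * mean_s
        info += d * (mean_s2 - mean_s**2)
    return stat_u * stat_u / info


def cox_partial_loglik(beta, times, events, x):
    """Breslow log partial likelihood for one covariate (loops)."""
    n = len(times)
    ll = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        denom = sum(math.exp(beta * x[j]) for j in range(n) if times[j] >= times[i])
        ll += beta * x[i] - math.log(denom)
    return ll


def km_survival_oracle(times, events):
    """Product-limit estimate by direct multiplication; returns
    (sorted distinct event times, S after each)."""
    out_t, out_s = [], []
    s = 1.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s
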