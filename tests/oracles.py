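"""Brute-force metric oracles, coded independently of the package.

Plain-Python loop implementations used to cross-check the vectorized metric
implementations; they deliberately share no code with tkqsar.metrics.
"""

import math


def o_rmse(y, p):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(y, p)) / len(y))


def o_mae(y, p):
    return sum(abs(a - b) for a, b in zip(y, p)) / len(y)


def o_medae(y, p):
    d = sorted(abs(a - b) for a, b in zip(y, p))
    n = len(d)
    return d[n // 2] if n % 2 else (d[n // 2 - 1] + d[n // 2]) / 2


def o_r2(y, p):
    ybar = sum(y) / len(y)
    return 1 - sum((a - b) ** 2 for a, b in zip(y, p)) / sum(
        (a - ybar) ** 2 for a in y)


def o_q2f3(y_out, p, y_tr):
    tbar = sum(y_tr) / len(y_tr)
    num = sum((a - b) ** 2 for a, b in zip(y_out, p)) / len(y_out)
    den = sum((a - tbar) ** 2 for a in y_tr) / len(y_tr)
    return 1 - num / den


def o_gmfe(y, p):
    s = sum(abs(math.log10(b / a)) for a, b in zip(y, p))
    return 10 ** (s / len(y))


def o_confusion(yt, yp, positive):
    tp = sum(1 for a, b in zip(yt, yp) if a == positive and b == positive)
    tn = sum(1 for a, b in zip(yt, yp) if a != positive and b != positive)
    fp = sum(1 for a, b in zip(yt, yp) if a != positive and b == positive)
    fn = sum(1 for a, b in zip(yt, yp) if a == positive and b != positive)
    return tp, tn, fp, fn


def o_se_sp_ba(tp, tn, fp, fn):
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return se, sp, (se + sp) / 2


def o_multiclass(yt, yp, classes):
    per = {}
    tot = [0, 0, 0, 0]
    for c in classes:
        counts = o_confusion(yt, yp, c)
        per[c] = o_se_sp_ba(*counts)
        tot = [t + x for t, x in zip(tot, counts)]
    macro = tuple(sum(per[c][i] for c in classes) / len(classes)
                  for i in range(3))
    micro = o_se_sp_ba(*tot)
    return per, macro, micro
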