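"""Independent scalar reference implementations of the four statistics.

Plain ``math``-module arithmetic, written separately from the package's
vectorised numpy path, used to cross-check it on random tables.
"""

import math

Z = 1.96
LN2 = math.log(2.0)


def ror(a, b, c, d):
    point = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, point * math.exp(-Z * se), point * math.exp(Z * se)


def prr(a, b, c, d):
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return point, point * math.exp(-Z * se), point * math.exp(Z * se)


def ebgm(a, b, c, d):
    n = a + b + c + d
    point = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, point * math.exp(-Z * se)


def information_component(a, b, c, d):
    n = a + b + c + d
    point = math.log2(a * n / ((a + b) * (a + c)))
    v = (1 / a - 1 / (a + b) - 1 / (a + c) + 1 / n) / LN2 ** 2
    return point, point - 2 * math.sqrt(max(v, 0.0))


def chi_square(a, b, c, d, yates):
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
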