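"""Independent brute-force oracles used to check the library's statistics.

These deliberately avoid numpy/scipy summary routines: explicit sorting
for order statistics and explicit moment loops, so they form a second,
independent route to every HistogramSummary field and to the ICC mean
squares.
"""

import math


def oracle_mean(xs):
    total = 0.0
    for v in xs:
        total += v
    return total / len(xs)


def oracle_sd(xs):
    """Sample standard deviation, n-1 denominator (0 for a single value)."""
    n = len(xs)
    if n == 1:
        return 0.0
    m = oracle_mean(xs)
    acc = 0.0
    for v in xs:
        acc += (v - m) ** 2
    return math.sqrt(acc / (n - 1))


def oracle_percentile(xs, q):
    """Linear interpolation between order statistics (numpy 'linear')."""
    s = sorted(xs)
    n = len(s)
    if n == 1:
        return s[0]
    pos = (q / 100.0) * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return s[lo] * (1.0 - frac) + s[hi] * frac


def oracle_median(xs):
    return oracle_percentile(xs, 50.0)


def oracle_skewness(xs):
    """Biased Fisher-Pearson g1: m3 / m2^(3/2)."""
    n = len(xs)
    m = oracle_mean(xs)
    m2 = 0.0
    m3 = 0.0
    for v in xs:
        d = v - m
        m2 += d * d
        m3 += d * d * d
    m2 /= n
    m3 /= n
    return m3 / m2**1.5


def oracle_kurtosis(xs):
    """Biased excess kurtosis g2: m4 / m2^2 - 3 (normal -> 0)."""
    n = len(xs)
    m = oracle_mean(xs)
    m2 = 0.0
    m4 = 0.0
    for v in xs:
        d = v - m
        d2 = d * d
        m2 += d2
        m4 += d2 * d2
    m2 /= n
    m4 /= n
    return m4 / (m2 * m2) - 3.0


def oracle_icc21(table):
    """ICC(2,1) from explicit two-way mean squares on a list-of-rows table."""
    n = len(table)
    k = len(table[0])
    grand = oracle_mean([v for row in table for v in row])
    row_means = [oracle_mean(row) for row in table]
    col_means = [oracle_mean([table[i][j] for i in range(n)]) for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((v - grand) ** 2 for row in table for v in row)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def oracle_icc31(table):
    """Consistency ICC(3,1) (two-way mixed), for offset comparisons."""
    n = len(table)
    k = len(table[0])
    grand = oracle_mean([v for row in table for v in row])
    row_means = [oracle_mean(row) for row in table]
    col_means = [oracle_mean([table[i][j] for i in range(n)]) for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((v - grand) ** 2 for row in table for v in row)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def oracle_pearson(xs, ys):
    """Pearson r from the direct covariance/variance formula."""
    n = len(xs)
    mx = oracle_mean(xs)
    my = oracle_mean(ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)
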