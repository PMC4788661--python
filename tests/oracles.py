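"""Independent brute-force / high-precision oracles used only by the tests.

Each oracle recomputes a statistic by a different algorithm than the
implementation: the hypergeometric tail by a pmf recurrence in exact
rationals, the g-test in 50-digit decimal arithmetic, and local matching by
explicit enumeration of every strand, diagonal and window.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from fractions import Fraction

from phasekit.annotate import MatchParams
from phasekit.seq import revcomp


def hypergeom_tail_recurrence(N: int, K: int, n: int, k: int) -> Fraction:
    """Upper tail P(X >= k) via the pmf ratio recurrence, exact rationals.

    Starts from the lowest attainable value of X and steps the pmf with
    p(i+1)/p(i) = (K-i)(n-i) / ((i+1)(N-K-n+i+1)).
    """
    lo = max(0, n + K - N)
    hi = min(n, K)
    if k <= lo:
        return Fraction(1)
    if k > hi:
        return Fraction(0)
    pmf = Fraction(math.comb(N - K, n - lo) * math.comb(K, lo), math.comb(N, n))
    total = Fraction(0)
    for i in range(lo, hi + 1):
        if i >= k:
            total += pmf
        if i < hi:
            pmf = pmf * (K - i) * (n - i) / ((i + 1) * (N - K - n + i + 1))
    return total


def gtest_decimal(observed, expected) -> Decimal:
    """G statistic in 50-digit decimal arithmetic (log-domain oracle)."""
    getcontext().prec = 50
    obs = [Decimal(o) for o in observed]
    exp = [Decimal(e) for e in expected]
    total_o = sum(obs)
    total_e = sum(exp)
    g = Decimal(0)
    for o, e in zip(obs, exp):
        if o > 0:
            scaled = e * total_o / total_e
            g += o * (o / scaled).ln()
    return 2 * g


def brute_local_match(query: str, subject: str, params: MatchParams):
    """Enumerate every strand/diagonal/window; keep the per-diagonal best.

    Returns tuples ``(strand, subject_start, aligned_len, identities,
    query_start)`` sorted, mirroring the contract of
    :func:`phasekit.annotate.local_match` (best window per diagonal by
    identities, then length, then leftmost start).
    """
    out = []
    Lq, Ls = len(query), len(subject)
    wmin = max(params.min_match_len, math.ceil(params.min_coverage_frac * Lq))
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        for d in range(-(Lq - 1), Ls):
            best = None
            for qs in range(Lq):
                ss = qs + d
                if ss < 0 or ss >= Ls:
                    continue
                ident = 0
                for w in range(1, min(Lq - qs, Ls - ss) + 1):
                    if q[qs + w - 1] == subject[ss + w - 1]:
                        ident += 1
                    if w < wmin:
                        continue
                    if ident / w + 1e-9 >= params.min_identity_frac:
                        key = (ident, w, -qs)
                        if best is None or key > best[0]:
                            best = (key, (qs, ss, w, ident))
            if best is not None:
                qs, ss, w, ident = best[1]
                q_start = qs if strand == "+" else Lq - (qs + w)
                out.append((strand, ss, w, ident, q_start))
    return sorted(out)
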