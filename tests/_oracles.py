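"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or direct arithmetic,
sharing no code path with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from isc.phmm import SKIP_MASS, encode


def enumerate_glocal_best(model, seq: str) -> float:
    """Maximum log2-odds over *all* legal glocal paths, by recursion.

    A legal path enters at any match state (paying the entry probability),
    moves through match/insert/delete states following the model's
    transition table, and leaves from any match state (paying the exit
    probability); read positions outside the path are free.  Tractable for
    K <= ~5 and sequences up to ~7 nt.
    """
    K = model.K
    x = encode(seq)
    L = len(x)
    bg = model.background

    def q_entry(k):
        return 1.0 if K == 1 else (1 - SKIP_MASS if k == 1
                                   else SKIP_MASS / (K - 1))

    def q_exit(k):
        return 1.0 if K == 1 else (1 - SKIP_MASS if k == K
                                   else SKIP_MASS / (K - 1))

    def em(k, c):
        return 0.0 if c > 3 else math.log2(model.match_emission[k - 1][c]
                                           / bg[c])

    def iem(k, c):
        return 0.0 if c > 3 else math.log2(model.insert_emission[k][c]
                                           / bg[c])

    best = -math.inf

    def go(stype, k, pos, score):
        nonlocal best
        if stype == "M":
            total = score + math.log2(q_exit(k))
            if total > best:
                best = total
        if k >= K:
            return
        tr = {"M": model.tr_m[k - 1], "I": model.tr_i[k],
              "D": model.tr_d[k - 1]}[stype]
        if pos < L:
            go("M", k + 1, pos + 1,
               score + math.log2(tr[0]) + em(k + 1, x[pos]))
            go("I", k, pos + 1, score + math.log2(tr[1]) + iem(k, x[pos]))
        go("D", k + 1, pos, score + math.log2(tr[2]))

    for start in range(L):
        for k in range(1, K + 1):
            go("M", k, start + 1, math.log2(q_entry(k)) + em(k, x[start]))
    return best


def brute_force_medoid(points: np.ndarray) -> int:
    """Argmin over summed Euclidean distances by direct double loop."""
    pts = np.asarray(points, float)
    n = pts.shape[0]
    sums = []
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += math.dist(pts[i], pts[j])
        sums.append(s)
    return int(np.argmin(sums))


def random_profile(rng, max_k: int = 4, max_rows: int = 6):
    """A random small profile HMM via a random gappy alignment."""
    from isc.formats import Msa
    from isc.phmm import ModelBuildError, build_profile

    while True:
        n_rows = int(rng.integers(2, max_rows + 1))
        n_cols = int(rng.integers(2, max_k + 2))
        rows = []
        for r in range(n_rows):
            chars = [
                "-" if rng.random() < 0.25 else "ACGT"[rng.integers(4)]
                for _ in range(n_cols)
            ]
            rows.append((f"r{r}", "".join(chars)))
        try:
            model = build_profile(Msa(rows))
        except ModelBuildError:
            continue
        if model.K <= max_k:
            return model
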