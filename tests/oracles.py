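"""Independent brute-force reference implementations of every encoder.

Written with plain dict/list arithmetic and naive nested loops, so they can
serve as oracles for the vectorized package encoders.  They share only the
physicochemical lookup tables with the package (the tables are data, not
computation).
"""

import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def oracle_aac(seq: str) -> list[float]:
    return [sum(1 for r in seq if r == a) / len(seq) for a in ALPHABET]


def oracle_ctd(seq: str, classes: dict[str, int]) -> list[float]:
    """21 composition/transition/distribution values for one partition."""
    L = len(seq)
    cls = [classes[r] for r in seq]
    out = []
    for c in (1, 2, 3):
        out.append(sum(1 for x in cls if x == c) / L)
    for a, b in ((1, 2), (1, 3), (2, 3)):
        n = 0
        for i in range(L - 1):
            pair = (cls[i], cls[i + 1])
            if pair == (a, b) or pair == (b, a):
                n += 1
        out.append(n / (L - 1) if L > 1 else 0.0)
    for c in (1, 2, 3):
        pos = [i + 1 for i in range(L) if cls[i] == c]
        if not pos:
            out.extend([0.0] * 5)
            continue
        n = len(pos)
        for q in (None, 0.25, 0.5, 0.75, 1.0):
            if q is None:
                idx = 1
            else:
                idx = max(1, math.ceil(q * n))
            out.append(pos[idx - 1] / L * 100.0)
    return out


def oracle_188d(seq: str, tables) -> list[float]:
    out = oracle_aac(seq)
    for prop in tables.ctd_partitions:
        out.extend(oracle_ctd(seq, tables.ctd_partitions[prop]))
    return out


def oracle_apaac(seq: str, lam: int, w: float, tables) -> list[float]:
    h1 = tables.scales["hydrophobicity"]
    h2 = tables.scales["hydrophilicity"]
    L = len(seq)
    taus = []
    for j in range(1, lam + 1):
        t1 = sum(h1[seq[i]] * h1[seq[i + j]] for i in range(L - j)) / (L - j)
        t2 = sum(h2[seq[i]] * h2[seq[i + j]] for i in range(L - j)) / (L - j)
        taus.extend([t1, t2])
    freqs = oracle_aac(seq)
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def oracle_paac(seq: str, lam: int, w: float, tables) -> list[float]:
    h1 = tables.scales["hydrophobicity"]
    h2 = tables.scales["hydrophilicity"]
    m = tables.scales["sidechain_mass"]
    L = len(seq)

    def theta_pair(a, b):
        return ((h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2) / 3.0

    thetas = []
    for j in range(1, lam + 1):
        thetas.append(
            sum(theta_pair(seq[i], seq[i + j]) for i in range(L - j)) / (L - j)
        )
    freqs = oracle_aac(seq)
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def oracle_ksctriad(seq: str, kmax: int, tables) -> list[float]:
    cls = [tables.triad_classes[r] for r in seq]
    L = len(cls)
    out = []
    for k in range(kmax + 1):
        counts = {}
        for a in range(1, 8):
            for b in range(1, 8):
                for c in range(1, 8):
                    counts[(a, b, c)] = 0
        for i in range(L - 2 * (k + 1)):
            key = (cls[i], cls[i + k + 1], cls[i + 2 * (k + 1)])
            counts[key] += 1
        vals = [counts[(a, b, c)]
                for a in range(1, 8) for b in range(1, 8) for c in range(1, 8)]
        mx = max(vals)
        if mx > 0:
            mn = min(vals)
            vals = [(v - mn) / mx for v in vals]
        out.extend(vals)
    return out


def oracle_cksaagp(seq: str, kmax: int, tables) -> list[float]:
    names = list(tables.sidechain_groups)
    group_of = {r: g for g, rs in tables.sidechain_groups.items() for r in rs}
    L = len(seq)
    out = []
    for k in range(kmax + 1):
        windows = L - k - 1
        for ga in names:
            for gb in names:
                n = sum(
                    1
                    for i in range(windows)
                    if group_of[seq[i]] == ga and group_of[seq[i + k + 1]] == gb
                )
                out.append(n / windows)
    return out


def oracle_cksaap(seq: str, kmax: int) -> list[float]:
    L = len(seq)
    out = []
    for k in range(kmax + 1):
        windows = L - k - 1
        for a in ALPHABET:
            for b in ALPHABET:
                n = sum(
                    1
                    for i in range(windows)
                    if seq[i] == a and seq[i + k + 1] == b
                )
                out.append(n / windows)
    return out
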