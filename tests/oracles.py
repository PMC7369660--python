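"""Independent brute-force oracles for the texture features.

Pure nested-loop evaluations of the printed formulas, deliberately sharing
no code with the package's vectorized implementations.
"""

import math


def glcm_counts(levels, n_levels, dr, dc):
    h, w = len(levels), len(levels[0])
    P = [[0.0] * n_levels for _ in range(n_levels)]
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[levels[r][c] - 1][levels[r2][c2] - 1] += 1
                total += 1
    return [[x / total for x in row] for row in P]


def glcm_features(P):
    n = len(P)
    hom = enr = ent = sym = con = 0.0
    mom = [0.0, 0.0, 0.0, 0.0]
    mux = muy = 0.0
    for a in range(n):
        for b in range(n):
            p = P[a][b]
            i, j = a + 1, b + 1
            hom += p / (1 + (i - j) ** 2)
            enr += p * p
            if p > 0:
                ent -= p * math.log(p)
            sym += abs(P[a][b] - P[b][a])
            con += (i - j) ** 2 * p
            for k in range(4):
                mom[k] += (i - j) ** (k + 1) * p
            mux += i * p
            muy += j * p
    sx = sy = 0.0
    for a in range(n):
        px = sum(P[a])
        py = sum(P[b][a] for b in range(n))
        sx += (a + 1 - mux) ** 2 * px
        sy += (a + 1 - muy) ** 2 * py
    sx, sy = math.sqrt(sx), math.sqrt(sy)
    if sx == 0 or sy == 0:
        cor = 0.0
    else:
        sij = 0.0
        for a in range(n):
            for b in range(n):
                sij += (a + 1) * (b + 1) * P[a][b]
        cor = (sij - mux * muy) / (sx * sy)
    return {"hom": hom, "enr": enr, "ent": ent, "sym": sym, "con": con, "cor": cor,
            "mom1": mom[0], "mom2": mom[1], "mom3": mom[2], "mom4": mom[3]}


def _runs_of_line(line):
    runs = []
    k = 0
    while k < len(line):
        j = k
        while j + 1 < len(line) and line[j + 1] == line[k]:
            j += 1
        runs.append((line[k], j - k + 1))
        k = j + 1
    return runs


def glrlm_runs(levels, direction):
    h, w = len(levels), len(levels[0])
    lines = []
    if direction == 0:
        lines = [list(row) for row in levels]
    elif direction == 90:
        lines = [[levels[r][c] for r in range(h)] for c in range(w)]
    elif direction == 45:
        for s in range(h + w - 1):
            line = [levels[r][c] for r in range(h - 1, -1, -1)
                    for c in range(w) if r + c == s]
            lines.append(line)
    elif direction == 135:
        for d in range(-(h - 1), w):
            line = [levels[r][r + d] for r in range(h) if 0 <= r + d < w]
            lines.append(line)
    runs = []
    for line in lines:
        if line:
            runs.extend(_runs_of_line(line))
    return runs


def glrlm_features(runs, n_pixels):
    nr = len(runs)
    sre = lre = lgre = hgre = 0.0
    by_level, by_length = {}, {}
    for level, length in runs:
        sre += 1.0 / length**2
        lre += float(length**2)
        lgre += 1.0 / level**2
        hgre += float(level**2)
        by_level[level] = by_level.get(level, 0) + 1
        by_length[length] = by_length.get(length, 0) + 1
    gln = sum(v * v for v in by_level.values()) / nr
    rln = sum(v * v for v in by_length.values()) / nr
    return {"sre": sre / nr, "lre": lre / nr, "gln": gln, "rp": nr / n_pixels,
            "rln": rln, "lgre": lgre / nr, "hgre": hgre / nr}


def glds_histogram(levels, n_levels, dx, dy):
    h, w = len(levels), len(levels[0])
    counts = [0.0] * n_levels
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dx, c + dy
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[abs(levels[r][c] - levels[r2][c2])] += 1
                total += 1
    return [x / total for x in counts]


def glds_features(P):
    asm = con = men = ent = 0.0
    for g, p in enumerate(P):
        asm += p * p
        con += g * g * p
        men += g * p
        if p > 0:
            ent -= p * math.log(p)
    return {"asm": asm, "con": con, "men": men, "ent": ent}
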