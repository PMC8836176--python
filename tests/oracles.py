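"""Independent brute-force oracles for the two duplex dynamic programs.

Both oracles enumerate explicit solution objects (alignments as monotone
chains of aligned columns; duplex structures as monotone chains of base
pairs) by depth-first search and score each one with their own scoring
code, sharing nothing with the package implementations but the parameter
values.  They are exponential and only usable on tiny instances.
"""

from __future__ import annotations

from spongescan.duplex import AlignmentParams, EnergyParams

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
PAIR_INDEX = {"CG": 0, "GC": 1, "GU": 2, "UG": 3, "AU": 4, "UA": 5}
MIRROR = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}
AU_LIKE = {2, 3, 4, 5}


def oracle_best_alignment(mirna: str, target: str, params: AlignmentParams) -> float:
    """Best local alignment score by exhaustive enumeration of all chains.

    A local alignment is a chain of aligned columns (i1<i2<..., j1<j2<...)
    over (reversed miRNA, target); its score is the sum of weighted column
    scores plus, between consecutive columns, one affine gap run per
    sequence (open + (len-1) * extend).  Ends are free.  Returns 0.0 when
    no positive-scoring alignment exists.
    """
    q = mirna[::-1]
    L, M = len(q), len(target)

    def colscore(i: int, j: int) -> float:
        a, b = q[i], target[j]
        if (a, b) in WC:
            s = params.match_score
        elif (a, b) in WOBBLE:
            s = params.gu_wobble_score
        else:
            s = params.mismatch_score
        pos = L - i  # 1-based miRNA position
        if params.seed_window[0] <= pos <= params.seed_window[1]:
            s *= params.seed_scale
        return s

    def gap(n: int) -> float:
        return 0.0 if n == 0 else params.gap_open + (n - 1) * params.gap_extend

    best = 0.0

    def extend(i0: int, j0: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        for i in range(i0 + 1, L):
            for j in range(j0 + 1, M):
                extend(i, j, score + gap(i - i0 - 1) + gap(j - j0 - 1) + colscore(i, j))

    for i in range(L):
        for j in range(M):
            extend(i, j, colscore(i, j))
    return best


def oracle_structure_energy(
    mirna: str, target: str, pairs: list[tuple[int, int]], params: EnergyParams
) -> float:
    """Free energy of one explicit duplex structure (own implementation).

    ``pairs`` are 0-based (miRNA index, target index), miRNA ascending and
    target descending.  Returns +inf outside the model.
    """
    INF = float("inf")
    if len(pairs) < 2:
        return INF
    types = []
    for i, j in pairs:
        t = PAIR_INDEX.get(mirna[i] + target[j], -1)
        if t < 0:
            return INF
        types.append(t)
    e = params.duplex_init
    for t in (types[0], types[-1]):
        if t in AU_LIKE:
            e += params.terminal_au
    for k in range(len(pairs) - 1):
        (i1, j1), (i2, j2) = pairs[k], pairs[k + 1]
        if not (i2 > i1 and j2 < j1):
            return INF
        b1, b2 = i2 - i1 - 1, j1 - j2 - 1
        stack = params.stack[types[k]][MIRROR[types[k + 1]]]
        if b1 == 0 and b2 == 0:
            e += stack
        elif b1 == 0 or b2 == 0:
            b = max(b1, b2)
            if b > params.max_bulge or b > len(params.bulge):
                return INF
            e += params.bulge[b - 1] + (stack if b == 1 else 0.0)
        else:
            n = b1 + b2
            if b1 > params.max_bulge or b2 > params.max_bulge:
                return INF
            if n > params.max_internal or n - 2 >= len(params.internal):
                return INF
            e += params.internal[n - 2] + min(params.ninio_max, params.ninio_m * abs(b1 - b2))
    return e


def oracle_min_energy(mirna: str, target: str, params: EnergyParams) -> float:
    """Minimum duplex free energy by exhaustive enumeration of structures.

    Enumerates every monotone chain of canonical pairs (miRNA ascending,
    target descending) and evaluates each with
    :func:`oracle_structure_energy`.  Returns +inf when no structure with
    at least two pairs exists.
    """
    L, M = len(mirna), len(target)
    cells = [
        (i, j)
        for i in range(L)
        for j in range(M)
        if (mirna[i] + target[j]) in PAIR_INDEX
    ]
    INF = float("inf")
    best = INF

    def extend(chain: list[tuple[int, int]]) -> None:
        nonlocal best
        e = oracle_structure_energy(mirna, target, chain, params)
        if e < best:
            best = e
        i0, j0 = chain[-1]
        for (i, j) in cells:
            if i > i0 and j < j0:
                chain.append((i, j))
                extend(chain)
                chain.pop()

    for c in cells:
        extend([c])
    return best
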