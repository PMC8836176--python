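"""miRNA:target duplex prediction by two independent dynamic programs.

Two complementary views of the same binding event are computed:

1. A *weighted local alignment* score (miRanda style): Smith-Waterman over
   the reversed miRNA versus the target in complement sense, with G:U
   wobbles allowed and substitution scores in the miRNA seed window scaled
   up.  The score is dimensionless.

2. A *hybridization minimum free energy* (RNAhybrid style): the most stable
   intermolecular secondary structure under a nearest-neighbor model
   (stacking + bulge/internal-loop penalties + duplex initiation + terminal
   A:U penalties), with no intramolecular pairs and no pseudoknots.
   Energies are kcal/mol; more negative is more stable.

Both programs are exact within their models and deterministic; co-optimal
solutions are resolved toward the smaller target start coordinate.  A pair
of thresholds on the two quantities (score > 150, mfe < -30 by default)
defines the final set of miRNA:lncRNA pairs.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .seqcore import Transcript

INF = float("inf")

_PAIR_TYPES = {"CG": 0, "GC": 1, "GU": 2, "UG": 3, "AU": 4, "UA": 5}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_AU_LIKE = {0: False, 1: False, 2: True, 3: True, 4: True, 5: True}


class DuplexError(ValueError):
    """Raised on degenerate duplex-prediction input or parameters."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("spongescan").joinpath("data", name)))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentParams:
    """Weights for the miRanda-style weighted Smith-Waterman."""

    match_score: float = 5.0
    mismatch_score: float = -3.0
    gu_wobble_score: float = 2.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_window: tuple[int, int] = (2, 8)
    score_threshold: float = 140.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise DuplexError("gap penalties must be <= 0")
        if self.seed_scale < 1:
            raise DuplexError("seed_scale must be >= 1")
        if self.match_score <= 0:
            raise DuplexError("degenerate parameters: match_score must be positive")

    @classmethod
    def reference(cls) -> "AlignmentParams":
        """Load the shipped reference parameter file."""
        return cls.from_yaml(_data_path("miranda_params.yaml"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlignmentParams":
        raw = yaml.safe_load(Path(path).read_text())
        raw["seed_window"] = tuple(raw["seed_window"])
        return cls(**raw)


@dataclass(frozen=True)
class EnergyParams:
    """Nearest-neighbor free-energy tables for intermolecular duplexes."""

    stack: tuple = ()               # 6x6, kcal/mol, indexed by pair types
    bulge: tuple = ()               # bulge[n-1] = cost of n-nt bulge
    internal: tuple = ()            # internal[n-2] = cost of n-nt internal loop
    ninio_m: float = 0.5
    ninio_max: float = 3.0
    duplex_init: float = 4.10
    terminal_au: float = 0.50
    max_bulge: int = 15
    max_internal: int = 15

    @classmethod
    def reference(cls) -> "EnergyParams":
        """Load the shipped Turner/Mathews 1999 rule set."""
        return cls.from_yaml(_data_path("turner1999_energies.yaml"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyParams":
        raw = yaml.safe_load(Path(path).read_text())
        raw.pop("pair_order", None)
        raw["stack"] = tuple(tuple(row) for row in raw["stack"])
        raw["bulge"] = tuple(raw["bulge"])
        raw["internal"] = tuple(raw["internal"])
        return cls(**raw)

    def bulge_cost(self, n: int) -> float:
        if n < 1 or n > min(self.max_bulge, len(self.bulge)):
            return INF
        return self.bulge[n - 1]

    def internal_cost(self, n1: int, n2: int) -> float:
        n = n1 + n2
        if n < 2 or n > min(self.max_internal, len(self.internal) + 1):
            return INF
        if n - 2 >= len(self.internal):
            return INF
        return self.internal[n - 2] + min(self.ninio_max, self.ninio_m * abs(n1 - n2))


@dataclass
class DuplexHit:
    """One predicted miRNA:target binding site.

    ``align_score`` and ``mfe`` are each filled by their own program and
    joined at filtering time.  ``target_start``/``target_end`` are 1-based
    inclusive coordinates on the target, 5'->3'.  ``pairing_trace`` renders
    the site as three lines: miRNA 3'->5', pair symbols (``|`` Watson-Crick,
    ``:`` G:U wobble), target 5'->3'.
    """

    mirna_id: str
    target_id: str
    align_score: float | None = None
    mfe: float | None = None
    target_start: int = 0
    target_end: int = 0
    pairing_trace: str = field(default="", repr=False)


def pair_type(a: str, b: str) -> int:
    """Energy pair-type index of bases (a, b), or -1 if not pairable."""
    return _PAIR_TYPES.get(a + b, -1)


def _column_score(a: str, b: str, params: AlignmentParams) -> float:
    """Substitution score of aligning miRNA base a against target base b.

    The target is read in *complement sense*: a column scores as a match
    when the two bases can form a Watson-Crick pair, as a wobble when they
    form G:U.
    """
    if (a, b) in _WC:
        return params.match_score
    if (a, b) in _WOBBLE:
        return params.gu_wobble_score
    return params.mismatch_score


# ---------------------------------------------------------------------------
# weighted local alignment (miRanda style)
# ---------------------------------------------------------------------------

def _gotoh_best(
    mirna_seq: str,
    target_seq: str,
    params: AlignmentParams,
    masked: set[int] | None = None,
) -> tuple[float, int, int, list[tuple[int, int, str]]] | None:
    """Best local alignment of the reversed miRNA against the target.

    Returns (score, target_start, target_end, columns) where columns are
    (miRNA 1-based position | 0 for gap, target 1-based position | 0 for
    gap, symbol) in target 5'->3' order, or None when no positive-score
    alignment exists.  ``masked`` holds 0-based target indices excluded
    from any alignment.
    """
    L = len(mirna_seq)
    M = len(target_seq)
    q = mirna_seq[::-1]  # q[k] is miRNA position L-k (0-based k)
    weights = np.ones(L)
    lo, hi = params.seed_window
    for k in range(L):
        pos = L - k  # 1-based miRNA position of q[k]
        if lo <= pos <= hi:
            weights[k] = params.seed_scale

    NEG = -1e12
    H = np.zeros((L + 1, M + 1))
    E = np.full((L + 1, M + 1), NEG)
    F = np.full((L + 1, M + 1), NEG)
    # pointers: 0 stop, 1 diag, 2 E (gap in miRNA), 3 F (gap in target)
    ptr = np.zeros((L + 1, M + 1), dtype=np.int8)
    eptr = np.zeros((L + 1, M + 1), dtype=np.int8)  # 1: from H, 0: extend
    fptr = np.zeros((L + 1, M + 1), dtype=np.int8)

    for i in range(1, L + 1):
        for j in range(1, M + 1):
            if masked and (j - 1) in masked:
                continue  # H stays 0; no alignment may cross this column
            e_open = H[i, j - 1] + params.gap_open
            e_ext = E[i, j - 1] + params.gap_extend
            E[i, j] = max(e_open, e_ext)
            eptr[i, j] = 1 if e_open >= e_ext else 0
            f_open = H[i - 1, j] + params.gap_open
            f_ext = F[i - 1, j] + params.gap_extend
            F[i, j] = max(f_open, f_ext)
            fptr[i, j] = 1 if f_open >= f_ext else 0
            diag = H[i - 1, j - 1] + _column_score(q[i - 1], target_seq[j - 1], params) * weights[i - 1]
            best = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = best
            if best == 0.0:
                ptr[i, j] = 0
            elif best == diag:
                ptr[i, j] = 1
            elif best == E[i, j]:
                ptr[i, j] = 2
            else:
                ptr[i, j] = 3

    best = H.max()
    if best <= 0:
        return None
    # co-optimal cells: traceback each, prefer the smallest target_start
    cells = np.argwhere(H >= best - 1e-9)
    results = []
    for i_end, j_end in cells:
        cols: list[tuple[int, int, str]] = []
        i, j = int(i_end), int(j_end)
        while i > 0 and j > 0 and ptr[i, j] != 0:
            p = ptr[i, j]
            if p == 1:
                a, b = q[i - 1], target_seq[j - 1]
                sym = "|" if (a, b) in _WC else (":" if (a, b) in _WOBBLE else " ")
                cols.append((L - i + 1, j, sym))
                i, j = i - 1, j - 1
            elif p == 2:
                # gap in miRNA, consume target; walk the affine run
                while True:
                    from_h = eptr[i, j] == 1
                    cols.append((0, j, " "))
                    j -= 1
                    if from_h:
                        break
            else:
                while True:
                    from_h = fptr[i, j] == 1
                    cols.append((L - i + 1, 0, " "))
                    i -= 1
                    if from_h:
                        break
        cols.reverse()
        tpos = [c[1] for c in cols if c[1] > 0]
        results.append((min(tpos), max(tpos), cols))
    results.sort(key=lambda r: r[0])
    start, end, cols = results[0]
    return float(best), start, end, cols


def _render_trace(mirna_seq: str, target_seq: str, cols: Sequence[tuple[int, int, str]]) -> str:
    top = "".join(mirna_seq[c[0] - 1] if c[0] else "-" for c in cols)
    mid = "".join(c[2] for c in cols)
    bot = "".join(target_seq[c[1] - 1] if c[1] else "-" for c in cols)
    return f"miRNA  3' {top} 5'\n          {mid}\ntarget 5' {bot} 3'"


def miranda_align(
    mirna: Transcript,
    target: Transcript,
    params: AlignmentParams | None = None,
) -> list[DuplexHit]:
    """All non-overlapping local binding sites scoring >= the threshold.

    Sites are found greedily: the globally best local alignment is reported,
    its target interval is masked, and the search repeats until the best
    remaining score falls below ``params.score_threshold``.  Hits are
    returned best-first; co-optimal hits resolve to the smaller target
    start.
    """
    params = params or AlignmentParams.reference()
    if not target.sequence:
        raise DuplexError("empty target")
    if len(mirna) < 6 or len(mirna) > 30:
        raise DuplexError(
            f"miRNA {mirna.id!r} has length {len(mirna)}; expected a mature miRNA (6-30 nt)"
        )
    masked: set[int] = set()
    hits: list[DuplexHit] = []
    while True:
        res = _gotoh_best(mirna.sequence, target.sequence, params, masked)
        if res is None or res[0] < params.score_threshold:
            break
        score, start, end, cols = res
        hits.append(
            DuplexHit(
                mirna_id=mirna.id,
                target_id=target.id,
                align_score=round(score, 6),
                target_start=start,
                target_end=end,
                pairing_trace=_render_trace(mirna.sequence, target.sequence, cols),
            )
        )
        masked.update(range(start - 1, end))
    return hits


# ---------------------------------------------------------------------------
# hybridization minimum free energy (RNAhybrid style)
# ---------------------------------------------------------------------------

def duplex_energy(
    mirna_seq: str,
    target_seq: str,
    pairs: Sequence[tuple[int, int]],
    params: EnergyParams,
) -> float:
    """Free energy of one explicit intermolecular structure (certificate).

    ``pairs`` are (miRNA position, target position), 1-based, such that
    miRNA positions strictly increase while target positions strictly
    decrease (antiparallel, no pseudoknots).  Returns +inf for structures
    outside the model (non-canonical pairs, oversized loops, < 2 pairs).
    """
    if len(pairs) < 2:
        return INF
    types = []
    for i, j in pairs:
        t = pair_type(mirna_seq[i - 1], target_seq[j - 1])
        if t < 0:
            return INF
        types.append(t)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i2 > i1 and j2 < j1):
            return INF
    e = params.duplex_init
    for p in (0, -1):
        if _AU_LIKE[types[p]]:
            e += params.terminal_au
    for k in range(len(pairs) - 1):
        i1, j1 = pairs[k]
        i2, j2 = pairs[k + 1]
        b1, b2 = i2 - i1 - 1, j1 - j2 - 1
        stack = params.stack[types[k]][_mirror(types[k + 1])]
        if b1 == 0 and b2 == 0:
            e += stack
        elif b1 == 0 or b2 == 0:
            b = max(b1, b2)
            cost = params.bulge_cost(b)
            if cost == INF:
                return INF
            e += cost + (stack if b == 1 else 0.0)
        else:
            cost = params.internal_cost(b1, b2)
            if cost == INF:
                return INF
            e += cost
    return e


def _mirror(t: int) -> int:
    """Pair type of the same pair read from the opposite strand (X:Y -> Y:X)."""
    return {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}[t]


def hybrid_mfe(
    mirna: Transcript,
    target: Transcript,
    params: EnergyParams | None = None,
) -> DuplexHit | None:
    """Energy-optimal intermolecular duplex, or None if no duplex forms.

    Dynamic program over (miRNA position, target position) pairs; the
    model allows stacks, bulges and internal loops up to the configured
    sizes, no intramolecular structure and no pseudoknots.  Returns the
    optimal site with its free energy (kcal/mol); co-optimal structures
    resolve to the smaller target start.
    """
    params = params or EnergyParams.reference()
    ms, ts = mirna.sequence, target.sequence
    L, M = len(ms), len(ts)

    # ptab[i, j] = pair type of (miRNA i, target j), 0-based; -1 unpairable
    base_idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    pt_lookup = np.full((4, 4), -1, dtype=np.int8)
    for (a, b), name in {
        ("C", "G"): "CG", ("G", "C"): "GC", ("G", "U"): "GU",
        ("U", "G"): "UG", ("A", "U"): "AU", ("U", "A"): "UA",
    }.items():
        pt_lookup[base_idx[a], base_idx[b]] = _PAIR_TYPES[name]
    m_idx = np.array([base_idx[c] for c in ms])
    t_idx = np.array([base_idx[c] for c in ts])
    ptab = pt_lookup[m_idx[:, None], t_idx[None, :]]

    stack = np.array(params.stack)
    mirror = np.array([1, 0, 3, 2, 5, 4])
    au_pen = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0]) * params.terminal_au
    pairable = ptab >= 0

    # S[i, j]: duplex consisting of the single opening pair (i, j)
    # B[i, j]: best duplex ending at pair (i, j) with >= 2 pairs
    S = np.where(pairable, params.duplex_init + au_pen[np.clip(ptab, 0, 5)], INF)
    B = np.full((L, M), INF)
    # parent pointers: (di, dj) of the predecessor pair, 0 if none
    pdi = np.zeros((L, M), dtype=np.int16)
    pdj = np.zeros((L, M), dtype=np.int16)

    maxb = int(params.max_bulge)
    for i in range(1, L):
        prev_best = np.minimum(B[:i], S[:i])  # candidates for the predecessor
        row_pt = ptab[i]
        valid = pairable[i]
        best = np.full(M, INF)
        bdi = np.zeros(M, dtype=np.int16)
        bdj = np.zeros(M, dtype=np.int16)
        for di in range(1, min(i, maxb + 1) + 1):
            src = prev_best[i - di]
            for dj in range(1, maxb + 2):
                b1, b2 = di - 1, dj - 1
                if b1 > 0 and b2 > 0:
                    loop = params.internal_cost(b1, b2)
                    if loop == INF:
                        continue
                elif b1 > maxb or b2 > maxb:
                    continue
                # cand[j] = src[j + dj] + transition cost into pair (i, j)
                cand = np.full(M, INF)
                upper = M - dj
                if upper <= 0:
                    continue
                seg = src[dj:]
                if b1 == 0 and b2 == 0:
                    tr = stack[ptab[i - di, dj:], mirror[np.clip(row_pt[:upper], 0, 5)]]
                    cand[:upper] = seg + tr
                elif (b1 == 0) != (b2 == 0):
                    b = max(b1, b2)
                    cost = params.bulge_cost(b)
                    if cost == INF:
                        continue
                    if b == 1:
                        tr = cost + stack[ptab[i - di, dj:], mirror[np.clip(row_pt[:upper], 0, 5)]]
                    else:
                        tr = cost
                    cand[:upper] = seg + tr
                else:
                    cand[:upper] = seg + loop
                cand[~valid] = INF
                upd = cand < best
                if upd.any():
                    best[upd] = cand[upd]
                    bdi[upd] = di
                    bdj[upd] = dj
        B[i] = best
        pdi[i] = bdi
        pdj[i] = bdj

    closing = B + np.where(pairable, au_pen[np.clip(ptab, 0, 5)], 0.0)
    mfe = closing.min()
    if not np.isfinite(mfe):
        return None
    # co-optimal: smallest target start = smallest j of the last pair
    cells = np.argwhere(closing <= mfe + 1e-9)
    i_end, j_end = min(cells.tolist(), key=lambda c: (c[1], c[0]))
    # traceback
    pairs = [(i_end + 1, j_end + 1)]
    i, j = i_end, j_end
    while pdi[i, j] != 0:
        i, j = i - int(pdi[i, j]), j + int(pdj[i, j])
        pairs.append((i + 1, j + 1))
    pairs.reverse()
    trace = _render_duplex_trace(ms, ts, pairs)
    return DuplexHit(
        mirna_id=mirna.id,
        target_id=target.id,
        mfe=round(float(mfe), 6),
        target_start=pairs[-1][1],
        target_end=pairs[0][1],
        pairing_trace=trace,
    )


def _render_duplex_trace(ms: str, ts: str, pairs: Sequence[tuple[int, int]]) -> str:
    """Render a duplex as miRNA 3'->5' over target 5'->3'.

    The target line runs left to right over the site; paired miRNA bases
    sit above their partners, loop regions are padded with gaps.
    """
    cols: list[tuple[str, str, str]] = []
    for k, (i, j) in enumerate(pairs):
        if k > 0:
            pi, pj = pairs[k - 1]
            for b in range(i - 1, pi, -1):  # unpaired miRNA between pairs
                cols.append((ms[b - 1], " ", "-"))
            for b in range(pj - 1, j, -1):  # unpaired target between pairs
                cols.append(("-", " ", ts[b - 1]))
        a, t = ms[i - 1], ts[j - 1]
        sym = "|" if (a, t) in _WC else ":"
        cols.append((a, sym, t))
    cols.reverse()  # present target 5'->3'
    top = "".join(c[0] for c in cols)
    mid = "".join(c[1] for c in cols)
    bot = "".join(c[2] for c in cols)
    return f"miRNA  3' {top} 5'\n          {mid}\ntarget 5' {bot} 3'"


# ---------------------------------------------------------------------------
# joint filter
# ---------------------------------------------------------------------------

def filter_duplex_pairs(
    hits: Iterable[DuplexHit],
    score_min: float = 150.0,
    mfe_max: float = -30.0,
) -> list[DuplexHit]:
    """Keep hits with align_score strictly > score_min AND mfe strictly < mfe_max.

    Every hit must carry both quantities (joined per miRNA:target pair
    upstream); a hit missing one raises :class:`DuplexError` naming the
    pair.  Input order is preserved.
    """
    kept = []
    for h in hits:
        if h.align_score is None or h.mfe is None:
            raise DuplexError(
                f"hit {h.mirna_id}:{h.target_id} is missing "
                f"{'align_score' if h.align_score is None else 'mfe'}"
            )
        if h.align_score > score_min and h.mfe < mfe_max:
            kept.append(h)
    return kept


def best_pair_evidence(
    mirna: Transcript,
    target: Transcript,
    align_params: AlignmentParams | None = None,
    energy_params: EnergyParams | None = None,
) -> DuplexHit | None:
    """Pair-level evidence: best alignment score joined with the global mfe.

    Multiple sites may exist; pair-level filtering uses the best site
    (maximum alignment score, minimum energy).  Returns None when the
    alignment program reports no site above threshold.
    """
    ahits = miranda_align(mirna, target, align_params)
    if not ahits:
        return None
    ehit = hybrid_mfe(mirna, target, energy_params)
    best = ahits[0]
    best.mfe = ehit.mfe if ehit is not None else INF
    return best
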