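"""Canonical miRNA seed-site scanning and the percentile target filter.

A canonical site on a target (read 5'->3') is an exact match to the
reverse complement of the miRNA seed.  With the 6mer core defined as the
complement of miRNA positions 2-7, the four canonical site types are::

    8mer      m8 match + core + 'A' opposite position 1
    7mer-m8   m8 match + core, no A at t1
    7mer-A1   core + 'A' at t1, no m8 match
    6mer      core only

The t1 adenosine is read from the target and is not required to pair
(the recognition comes from Argonaute, not from base pairing).  Each core
occurrence yields exactly one site of the strongest type it supports.

When no externally computed target-score table is available, percentiles
for the (miRNA, gene) edge filter are derived internally by rank-
transforming a simplified site score across every candidate pair scanned
in the run; see :func:`internal_percentiles`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import Transcript, reverse_complement

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: simplified site-strength weights used by the internal percentile fallback
SITE_WEIGHTS = {"8mer": 4.0, "7mer-m8": 3.0, "7mer-A1": 2.0, "6mer": 1.0}


class SeedError(ValueError):
    """Raised on invalid seed-scan or percentile input."""


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match site on a target, 1-based inclusive."""

    mirna_id: str
    target_id: str
    site_type: str
    start: int
    end: int
    site_sequence: str

    def __post_init__(self) -> None:
        width = self.end - self.start + 1
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.site_type]
        if width != expected or len(self.site_sequence) != width:
            raise SeedError(
                f"{self.site_type} site on {self.target_id} has width {width}"
            )


@dataclass(frozen=True)
class TargetScoreRecord:
    """A (miRNA, gene) candidate edge with a context-score percentile."""

    mirna_id: str
    gene_id: str
    percentile: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percentile <= 100.0):
            raise SeedError(
                f"percentile {self.percentile} for {self.mirna_id}:{self.gene_id} "
                "outside [0, 100]"
            )


def scan_seed_sites(mirna: Transcript, target: Transcript) -> list[SeedSite]:
    """All canonical seed sites of ``mirna`` on ``target``, sorted by start.

    Scans for the reverse complement of miRNA positions 2-7 and classifies
    each occurrence by the position-8 match and the t1 adenosine.
    """
    if len(mirna) < 8:
        raise SeedError(f"miRNA {mirna.id!r} is shorter than 8 nt; no seed can be defined")
    seq = target.sequence
    core = reverse_complement(mirna.sequence[1:7])      # complement of positions 2-7
    m8 = reverse_complement(mirna.sequence[7])          # complement of position 8

    sites: list[SeedSite] = []
    i = seq.find(core)
    while i != -1:
        s = i + 1  # 1-based core start
        has_m8 = s >= 2 and seq[s - 2] == m8
        has_a1 = s + 6 <= len(seq) and seq[s + 5] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", s - 1, s + 6
        elif has_m8:
            site_type, start, end = "7mer-m8", s - 1, s + 5
        elif has_a1:
            site_type, start, end = "7mer-A1", s, s + 6
        else:
            site_type, start, end = "6mer", s, s + 5
        sites.append(
            SeedSite(
                mirna_id=mirna.id,
                target_id=target.id,
                site_type=site_type,
                start=start,
                end=end,
                site_sequence=seq[start - 1 : end],
            )
        )
        i = seq.find(core, i + 1)
    return sites


def site_table(sites: Iterable[SeedSite]) -> pd.DataFrame:
    """Sites as the tab-delimited schema (one row per site)."""
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "site_type": s.site_type,
                "start": s.start,
                "end": s.end,
                "site_sequence": s.site_sequence,
            }
            for s in sites
        ],
        columns=["mirna_id", "target_id", "site_type", "start", "end", "site_sequence"],
    )


def simplified_site_score(
    sites: Sequence[SeedSite], target: Transcript | None = None
) -> float:
    """Internal fallback score for one (miRNA, gene) candidate pair.

    Site-type weight (8mer > 7mer-m8 > 7mer-A1 > 6mer), plus a local
    AU-content term (sites in AU-rich context are more accessible) and a
    position term favoring sites near the UTR ends, both in [0, 1] per
    site.  This is a deliberately simple stand-in for a trained context
    model and is labeled as such in output.
    """
    score = 0.0
    for s in sites:
        score += SITE_WEIGHTS[s.site_type]
        if target is not None:
            lo = max(0, s.start - 31)
            hi = min(len(target.sequence), s.end + 30)
            flank = target.sequence[lo : s.start - 1] + target.sequence[s.end : hi]
            if flank:
                au = (flank.count("A") + flank.count("U")) / len(flank)
                score += au
            rel = (s.start - 1) / max(len(target.sequence) - 1, 1)
            score += 2 * abs(rel - 0.5)
    return score


def internal_percentiles(
    scores: pd.Series,
) -> pd.Series:
    """Rank-transform candidate scores to percentiles in (0, 100].

    ``scores`` is indexed by (mirna_id, gene_id) over *all* candidate
    pairs scanned in the run, including pairs with no site (score 0).
    The percentile of a candidate is ``100 * (# candidates with score <=
    its score) / n``, so the best candidate always receives 100.
    """
    n = len(scores)
    if n == 0:
        return scores.astype(float)
    ranks = scores.rank(method="max")  # ties share the highest rank
    return 100.0 * ranks / n


def filter_targets_by_percentile(
    records: Iterable[TargetScoreRecord], threshold: float = 50.0
) -> list[TargetScoreRecord]:
    """Keep records with percentile strictly greater than ``threshold``."""
    out = []
    for r in records:
        if not (0.0 <= r.percentile <= 100.0):
            raise SeedError(f"percentile {r.percentile} outside [0, 100]")
        if r.percentile > threshold:
            out.append(r)
    return out


def read_target_scores(path) -> list[TargetScoreRecord]:
    """Read an externally computed score table (mirna_id, gene_id, percentile)."""
    df = pd.read_csv(path, sep="\t")
    return [
        TargetScoreRecord(str(r.mirna_id), str(r.gene_id), float(r.percentile))
        for r in df.itertuples()
    ]
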