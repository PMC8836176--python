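"""Bundled reference sequences used throughout the package and its tests.

* ``linc02802()`` — the full-length LINC02802 transcript (549 nt), as the
  insert cloned for over-expression and luciferase work; stored in DNA
  notation and normalized to RNA on load.
* ``linc02802_mut()`` — the point-mutant with the miR-486-5p binding site
  GUACAGG at 161-167 replaced by GUCCGGU.
* ``mir486_5p()`` — mature hsa-miR-486-5p (miRBase v22, MIMAT0002177).
* ``maml3_3utr()`` — a *synthetic* stand-in for the MAML3 (NM_018717.5)
  3'UTR: a random background carrying one miR-486-5p 8mer site (605-612)
  and one 7mer-m8 site (1993-1999), with every other seed-core match
  masked.  It reproduces the site architecture reported for the real UTR
  (one 8mer plus one 7mer site) without redistributing the RefSeq sequence.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

from .seqcore import Transcript, read_fasta


def _load(name: str, biotype: str) -> Transcript:
    path = Path(str(resources.files("spongescan").joinpath("data", name)))
    return read_fasta(path, biotype=biotype)[0]


def linc02802() -> Transcript:
    """Wild-type LINC02802 (549 nt, lncRNA)."""
    return _load("linc02802.fa", "lncRNA")


def linc02802_mut() -> Transcript:
    """LINC02802 with the miR-486-5p site at 161-167 point-mutated away."""
    return _load("linc02802_mut.fa", "lncRNA")


def mir486_5p() -> Transcript:
    """Mature hsa-miR-486-5p (22 nt)."""
    return _load("mir486_5p.fa", "miRNA")


def maml3_3utr() -> Transcript:
    """Synthetic MAML3 3'UTR stand-in (2200 nt, one 8mer + one 7mer site)."""
    return _load("maml3_3utr_synthetic.fa", "utr3")
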