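"""Assembly and ranking of lncRNA-miRNA-mRNA sponge circuits.

A circuit is emitted when every edge of the triplet holds simultaneously:

* the lncRNA and the miRNA are both in their differential-expression
  calls, with *opposite* log2 fold-change signs (the sponge and the
  sponged miRNA must move in opposite directions between conditions);
* the (lncRNA, miRNA) pair passed the joint duplex filter (alignment
  score and hybridization energy thresholds);
* the (miRNA, mRNA) pair passed the seed-site / percentile target filter;
* optionally (on by default) the mRNA is differentially expressed with
  sign opposite to the miRNA, i.e. the ceRNA arithmetic is consistent.

With a two-condition design and a handful of replicates per arm, a
per-sample expression correlation is not meaningful; opposite DE sign is
the operational definition of anti-correlation used throughout.  No
multiple-testing correction is applied at the circuit level (multiplicity
is controlled at the DE stage only); the report states this.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .duplex import DuplexHit
from .seeds import SeedSite

REPORT_COLUMNS = [
    "rank", "lncrna_id", "mirna_id", "mrna_id",
    "lnc_base_mean", "lnc_log2fc", "lnc_fdr",
    "mirna_log2fc", "mirna_fdr",
    "mrna_log2fc", "mrna_fdr",
    "duplex_align_score", "duplex_mfe", "duplex_target_start", "duplex_target_end",
    "mrna_site_types", "mrna_percentile",
]


class CircuitError(ValueError):
    """Raised when circuit inputs reference unknown ids or are inconsistent."""


@dataclass
class CeRNACircuit:
    """One lncRNA-miRNA-mRNA triplet with its supporting evidence."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_de: pd.Series
    mirna_de: pd.Series
    duplex: DuplexHit
    mrna_sites: tuple[SeedSite, ...] = ()
    mrna_de: pd.Series | None = None
    mrna_percentile: float | None = None
    rank: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


def assemble_circuits(
    de_lnc: pd.DataFrame,
    de_mirna: pd.DataFrame,
    duplex_hits: Sequence[DuplexHit],
    mrna_edges: Mapping[tuple[str, str], float],
    mrna_sites: Mapping[tuple[str, str], Sequence[SeedSite]] | None = None,
    de_mrna: pd.DataFrame | None = None,
    require_mrna_anticorrelation: bool = True,
    universes: Mapping[str, Iterable[str]] | None = None,
) -> list[CeRNACircuit]:
    """Enumerate every triplet satisfying all circuit constraints.

    Parameters
    ----------
    de_lnc, de_mirna:
        Filtered differential-expression tables (indexed by gene id, with
        ``log2fc`` etc.); membership in the table is membership in the DE
        set.
    duplex_hits:
        (lncRNA, miRNA) pairs that already passed the joint duplex filter.
    mrna_edges:
        Mapping (mirna_id, mrna_id) -> percentile for target edges that
        passed the percentile filter.
    mrna_sites:
        Optional mapping (mirna_id, mrna_id) -> seed sites, attached as
        evidence.
    de_mrna:
        Optional mRNA DE table; when provided and
        ``require_mrna_anticorrelation`` is set, the mRNA must be present
        with log2fc sign opposite to the miRNA's.

    universes:
        Optional id namespaces (keys ``lncrna``, ``mirna``, ``mrna``); when
        given, an edge referencing an id outside its namespace raises
        :class:`CircuitError` naming the id.

    Output is deterministic and independent of input order (sorted by
    triplet ids); ranks are not assigned here (see :func:`rank_circuits`).
    """
    mrna_sites = mrna_sites or {}
    known_lnc = set(de_lnc.index)
    known_mir = set(de_mirna.index)
    if universes is not None:
        lnc_ns = set(universes.get("lncrna", ()))
        mir_ns = set(universes.get("mirna", ()))
        mrna_ns = set(universes.get("mrna", ()))
        for h in duplex_hits:
            if lnc_ns and h.target_id not in lnc_ns:
                raise CircuitError(f"duplex edge references unknown lncRNA id {h.target_id!r}")
            if mir_ns and h.mirna_id not in mir_ns:
                raise CircuitError(f"duplex edge references unknown miRNA id {h.mirna_id!r}")
        for mir_id, mrna_id in mrna_edges:
            if mir_ns and mir_id not in mir_ns:
                raise CircuitError(f"target edge references unknown miRNA id {mir_id!r}")
            if mrna_ns and mrna_id not in mrna_ns:
                raise CircuitError(f"target edge references unknown mRNA id {mrna_id!r}")

    pair_by_ids: dict[tuple[str, str], DuplexHit] = {}
    for h in duplex_hits:
        pair_by_ids.setdefault((h.target_id, h.mirna_id), h)

    circuits: list[CeRNACircuit] = []
    for (lnc_id, mir_id), hit in sorted(pair_by_ids.items()):
        if lnc_id not in known_lnc or mir_id not in known_mir:
            continue  # edge exists but endpoint not differentially expressed
        lnc_de = de_lnc.loc[lnc_id]
        mir_de = de_mirna.loc[mir_id]
        if lnc_de["log2fc"] * mir_de["log2fc"] >= 0:
            continue  # anti-correlation constraint (opposite DE signs)
        for (edge_mir, mrna_id), percentile in sorted(mrna_edges.items()):
            if edge_mir != mir_id:
                continue
            mrna_de_row = None
            if de_mrna is not None:
                if require_mrna_anticorrelation:
                    if mrna_id not in de_mrna.index:
                        continue
                    mrna_de_row = de_mrna.loc[mrna_id]
                    if mrna_de_row["log2fc"] * mir_de["log2fc"] >= 0:
                        continue
                elif mrna_id in de_mrna.index:
                    mrna_de_row = de_mrna.loc[mrna_id]
            sites = tuple(mrna_sites.get((mir_id, mrna_id), ()))
            if not sites and percentile is None:
                continue  # no supporting evidence on the mRNA edge
            circuits.append(
                CeRNACircuit(
                    lncrna_id=lnc_id,
                    mirna_id=mir_id,
                    mrna_id=mrna_id,
                    lnc_de=lnc_de,
                    mirna_de=mir_de,
                    duplex=hit,
                    mrna_sites=sites,
                    mrna_de=mrna_de_row,
                    mrna_percentile=percentile,
                )
            )
    circuits.sort(key=lambda c: c.key)
    return circuits


def rank_circuits(circuits: list[CeRNACircuit]) -> list[CeRNACircuit]:
    """Assign 1-based ranks: lncRNA base mean desc, |log2fc| desc, score desc, ids.

    The primary key mirrors the candidate-selection narrative: among DE
    lncRNAs, the most highly expressed sponge first, then the largest
    fold change.
    """
    ordered = sorted(
        circuits,
        key=lambda c: (
            -float(c.lnc_de["base_mean"]),
            -abs(float(c.lnc_de["log2fc"])),
            -(c.duplex.align_score if c.duplex.align_score is not None else float("-inf")),
            c.key,
        ),
    )
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def circuits_to_table(circuits: Sequence[CeRNACircuit]) -> pd.DataFrame:
    rows = []
    for c in circuits:
        rows.append(
            {
                "rank": c.rank,
                "lncrna_id": c.lncrna_id,
                "mirna_id": c.mirna_id,
                "mrna_id": c.mrna_id,
                "lnc_base_mean": float(c.lnc_de["base_mean"]),
                "lnc_log2fc": float(c.lnc_de["log2fc"]),
                "lnc_fdr": float(c.lnc_de["fdr"]),
                "mirna_log2fc": float(c.mirna_de["log2fc"]),
                "mirna_fdr": float(c.mirna_de["fdr"]),
                "mrna_log2fc": float(c.mrna_de["log2fc"]) if c.mrna_de is not None else float("nan"),
                "mrna_fdr": float(c.mrna_de["fdr"]) if c.mrna_de is not None else float("nan"),
                "duplex_align_score": c.duplex.align_score,
                "duplex_mfe": c.duplex.mfe,
                "duplex_target_start": c.duplex.target_start,
                "duplex_target_end": c.duplex.target_end,
                "mrna_site_types": ",".join(s.site_type for s in c.mrna_sites),
                "mrna_percentile": c.mrna_percentile,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_circuit_report(
    circuits: Sequence[CeRNACircuit],
    path: str | Path,
    thresholds: Mapping[str, float] | None = None,
    stage_counts: Mapping[str, int] | None = None,
    input_files: Iterable[str | Path] = (),
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Write the circuit table (TSV) and a structured-text run summary.

    Returns (table_path, summary_path).  The summary records counts per
    stage, the thresholds used, the package version, input digests and
    the seed, and notes that no circuit-level multiplicity correction is
    applied.
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = circuits_to_table(circuits)
    table.to_csv(path, sep="\t", index=False)

    summary_path = path.with_suffix(".summary.txt")
    lines = [
        "circuit report summary",
        f"version: {__version__}",
        f"circuits: {len(circuits)}",
    ]
    if seed is not None:
        lines.append(f"seed: {seed}")
    for name, value in (thresholds or {}).items():
        lines.append(f"threshold.{name}: {value}")
    for name, value in (stage_counts or {}).items():
        lines.append(f"count.{name}: {value}")
    for f in input_files:
        digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()[:16]
        lines.append(f"input: {Path(f).name} sha256:{digest}")
    lines.append("note: no multiple-testing correction beyond the DE-stage FDR is applied")
    summary_path.write_text("\n".join(lines) + "\n")
    return path, summary_path


def read_circuit_report(path: str | Path) -> pd.DataFrame:
    """Read back a written circuit table."""
    return pd.read_csv(path, sep="\t")
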