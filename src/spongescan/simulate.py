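"""Synthetic benchmark generator with planted sponge circuits.

The generator emulates the statistical structure of a two-condition
(control vs stimulated) spheroid sprouting experiment profiled by total
and small RNA-seq: negative-binomial counts with three replicates per
arm, a handful of planted circuits in which the lncRNA and the mRNA move
up while the miRNA moves down, and transcript sequences carrying planted
canonical seed sites.  Everything is deterministic given ``(design,
seed)`` and carries machine-readable ground truth, so every pipeline
stage and the end-to-end run are testable without any external data.

Counts are NB with variance ``mu + alpha * mu^2`` (default ``alpha`` =
0.05, a typical bulk RNA-seq dispersion).  Planted genes draw their
baselines from a tighter, higher-expression distribution than decoys:
sponge candidates are, by construction of the discovery strategy, found
among well-expressed transcripts, so the benchmark plants its circuits
there.  Sequences are i.i.d. with a target GC content; every planted
circuit writes a perfect-complement (22 nt) miRNA site into its lncRNA
(so the duplex filter is passable, mirroring the extensive pairing a
reported sponge site implies) and one canonical seed site (8mer or
7mer-m8) into its mRNA 3'UTR, while *all* spurious seed-core matches of
every miRNA elsewhere are destroyed by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .seqcore import Transcript, reverse_complement
from .expression import CountMatrix


class SimulationError(ValueError):
    """Raised on invalid simulation designs."""


@dataclass(frozen=True)
class PlantedCircuit:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_log2fc: float = 1.5
    mir_log2fc: float = -1.0
    mrna_log2fc: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lnc_log2fc > 0 and self.mir_log2fc < 0 and self.mrna_log2fc > 0):
            raise SimulationError(
                f"circuit {self.lncrna_id}-{self.mirna_id}-{self.mrna_id}: expected "
                "lncRNA/mRNA up and miRNA down"
            )
        for v in (self.lnc_log2fc, -self.mir_log2fc, self.mrna_log2fc):
            if abs(v) <= 0.5:
                raise SimulationError(
                    "planted |log2fc| must exceed 0.5 (the DE filter's own threshold)"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


@dataclass
class SimulationDesign:
    """Full specification of one synthetic dataset."""

    n_control: int = 3
    n_stimulated: int = 3
    n_lncrna: int = 15
    n_mirna: int = 20
    n_mrna: int = 24          # 15 + 20 + 24 - 3*3 planted = 50 decoy genes
    n_circuits: int = 3
    lnc_log2fc: float = 1.5
    mir_log2fc: float = -1.0
    mrna_log2fc: float = 1.0
    baseline_log_mean: float = float(np.log(300.0))
    baseline_log_sd: float = 1.0
    planted_log_mean: float = float(np.log(600.0))
    planted_log_sd: float = 0.4
    dispersion: float = 0.05
    gc_content: float = 0.45
    lncrna_length: int = 600
    utr_length: int = 800
    mirna_length: int = 22
    seed: int = 1653

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_stimulated <= 0:
            raise SimulationError("replicate counts must be positive")
        if self.n_circuits > min(self.n_lncrna, self.n_mirna, self.n_mrna):
            raise SimulationError("more planted circuits than genes to host them")
        if min(self.lncrna_length, self.utr_length) < 30:
            raise SimulationError("transcripts too short to host a planted site")

    def planted_circuits(self) -> list[PlantedCircuit]:
        return [
            PlantedCircuit(
                f"LNC{i:03d}", f"MIR{i:03d}", f"MRNA{i:03d}",
                self.lnc_log2fc, self.mir_log2fc, self.mrna_log2fc,
            )
            for i in range(self.n_circuits)
        ]

    def gene_ids(self, klass: str) -> list[str]:
        n = {"lncrna": self.n_lncrna, "mirna": self.n_mirna, "mrna": self.n_mrna}[klass]
        prefix = {"lncrna": "LNC", "mirna": "MIR", "mrna": "MRNA"}[klass]
        return [f"{prefix}{i:03d}" for i in range(n)]


@dataclass
class GroundTruth:
    """Machine-readable truth accompanying a simulated dataset."""

    seed: int
    circuits: list[tuple[str, str, str]]
    true_log2fc: dict[str, float]                      # gene id -> planted lfc (0 if decoy)
    site_coords: dict[str, tuple[int, int, str]]       # "mirna|target" -> (start, end, type)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "circuits": [list(c) for c in self.circuits],
            "true_log2fc": self.true_log2fc,
            "site_coords": {k: list(v) for k, v in self.site_coords.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=raw["seed"],
            circuits=[tuple(c) for c in raw["circuits"]],
            true_log2fc=raw["true_log2fc"],
            site_coords={k: tuple(v) for k, v in raw["site_coords"].items()},
        )


@dataclass
class SimulatedCounts:
    lncrna: CountMatrix
    mirna: CountMatrix
    mrna: CountMatrix


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(design: SimulationDesign) -> tuple[SimulatedCounts, GroundTruth]:
    """NB count matrices for the three gene classes, plus ground truth.

    Control means are the gene baselines; stimulated means differ by the
    planted log2 fold change (0 for decoys).  Deterministic given the
    design's seed.
    """
    rng = np.random.default_rng(design.seed)
    circuits = design.planted_circuits()
    planted_lfc: dict[str, float] = {}
    for c in circuits:
        planted_lfc[c.lncrna_id] = c.lnc_log2fc
        planted_lfc[c.mirna_id] = c.mir_log2fc
        planted_lfc[c.mrna_id] = c.mrna_log2fc

    samples = [f"ctrl_{j+1}" for j in range(design.n_control)] + [
        f"stim_{j+1}" for j in range(design.n_stimulated)
    ]
    cond = pd.Series(
        ["control"] * design.n_control + ["stimulated"] * design.n_stimulated,
        index=samples,
    )

    lengths = {"lncrna": design.lncrna_length, "mirna": design.mirna_length, "mrna": design.utr_length}
    matrices: dict[str, CountMatrix] = {}
    true_lfc: dict[str, float] = {}
    for klass in ("lncrna", "mirna", "mrna"):
        ids = design.gene_ids(klass)
        base = np.empty(len(ids))
        for g, gid in enumerate(ids):
            if gid in planted_lfc:
                base[g] = rng.lognormal(design.planted_log_mean, design.planted_log_sd)
            else:
                base[g] = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd)
        lfc = np.array([planted_lfc.get(gid, 0.0) for gid in ids])
        true_lfc.update({gid: float(planted_lfc.get(gid, 0.0)) for gid in ids})
        cols = {}
        for j, s in enumerate(samples):
            mu = base * (2.0 ** lfc if cond[s] == "stimulated" else 1.0)
            cols[s] = _nb_draw(rng, mu, design.dispersion)
        counts = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
        matrices[klass] = CountMatrix(
            counts=counts,
            conditions=cond.copy(),
            gene_lengths=pd.Series(float(lengths[klass]), index=counts.index),
        )

    truth = GroundTruth(
        seed=design.seed,
        circuits=[c.key for c in circuits],
        true_log2fc=true_lfc,
        site_coords={},
    )
    return SimulatedCounts(**matrices), truth


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def simulate_transcriptome(
    design: SimulationDesign,
) -> tuple[dict[str, list[Transcript]], GroundTruth]:
    """Sequences for all genes, with planted sites and masked decoy matches.

    Returns ``({'lncrna': [...], 'mirna': [...], 'mrna': [...]}, truth)``.
    For each planted circuit the lncRNA receives the full reverse
    complement of its miRNA (a perfect extended site) and the mRNA 3'UTR
    one canonical seed site (8mer or 7mer-m8, drawn at random); all other
    occurrences of any miRNA's seed core anywhere are destroyed.
    """
    rng = np.random.default_rng(design.seed + 1)
    circuits = design.planted_circuits()
    planted_mirna_ids = [c.mirna_id for c in circuits]

    # miRNAs with mutually distinct seed cores; additionally no miRNA's
    # core may occur inside a planted miRNA's extended complement, which
    # is protected from masking once written into a lncRNA
    mirnas: dict[str, str] = {}
    cores: dict[str, str] = {}
    for mid in planted_mirna_ids + [m for m in design.gene_ids("mirna")
                                    if m not in planted_mirna_ids]:
        for _ in range(1000):
            seq = _random_seq(rng, design.mirna_length, design.gc_content)
            core = reverse_complement(seq[1:7])
            ext = reverse_complement(seq)
            planted_exts = [reverse_complement(mirnas[p]) for p in planted_mirna_ids
                            if p in mirnas]
            if core in cores.values():
                continue
            if any(core in e for e in planted_exts):
                continue
            if mid in planted_mirna_ids and any(c in ext for c in cores.values()):
                continue
            mirnas[mid] = seq
            cores[mid] = core
            break
        else:
            raise SimulationError(f"could not draw a conflict-free miRNA for {mid}")

    site_coords: dict[str, tuple[int, int, str]] = {}
    protected: dict[str, list[tuple[int, int]]] = {}  # target id -> 0-based [start, end)

    def plant(target_id: str, seq: list[str], insert: str, pos0: int, kind: str, mirna_id: str,
              rec_start: int, rec_end: int) -> None:
        seq[pos0 : pos0 + len(insert)] = list(insert)
        protected.setdefault(target_id, []).append((pos0, pos0 + len(insert)))
        site_coords[f"{mirna_id}|{target_id}"] = (rec_start, rec_end, kind)

    lnc_seqs: dict[str, list[str]] = {
        gid: list(_random_seq(rng, design.lncrna_length, design.gc_content))
        for gid in design.gene_ids("lncrna")
    }
    utr_seqs: dict[str, list[str]] = {
        gid: list(_random_seq(rng, design.utr_length, design.gc_content))
        for gid in design.gene_ids("mrna")
    }

    for c in circuits:
        mseq = mirnas[c.mirna_id]
        # lncRNA: perfect extended complement, recorded at the seed-core interval
        ext = reverse_complement(mseq)
        pos0 = int(rng.integers(10, design.lncrna_length - len(ext) - 10))
        plant(c.lncrna_id, lnc_seqs[c.lncrna_id], ext, pos0, "extended",
              c.mirna_id, pos0 + 1, pos0 + len(ext))
        # mRNA UTR: one canonical site (no foreign seed core may hide inside)
        core = cores[c.mirna_id]
        m8 = reverse_complement(mseq[7])
        foreign = [v for k, v in cores.items() if k != c.mirna_id]
        kind = ("8mer", "7mer-m8")[int(rng.integers(2))]
        insert = None
        for candidate_kind, t1 in ([(kind, "A" if kind == "8mer" else "CGU"[int(rng.integers(3))])]
                                   + [("7mer-m8", b) for b in "CGU"] + [("8mer", "A")]):
            cand = m8 + core + t1
            if not any(f in cand for f in foreign):
                kind, insert = candidate_kind, cand
                break
        if insert is None:
            raise SimulationError(f"no conflict-free seed site for {c.mirna_id}")
        upos0 = int(rng.integers(10, design.utr_length - len(insert) - 10))
        width = 8 if kind == "8mer" else 7
        plant(c.mrna_id, utr_seqs[c.mrna_id], insert, upos0, kind,
              c.mirna_id, upos0 + 1, upos0 + width)

    # destroy spurious seed-core matches of every miRNA everywhere
    all_cores = list(cores.values())

    def masked(target_id: str, seq: list[str]) -> None:
        prot = protected.get(target_id, [])
        for _ in range(100):
            s = "".join(seq)
            dirty = False
            for core in all_cores:
                i = s.find(core)
                while i != -1:
                    if not any(p0 <= i and i + 6 <= p1 for p0, p1 in prot):
                        free = [j for j in range(i, i + 6)
                                if not any(p0 <= j < p1 for p0, p1 in prot)]
                        j = free[len(free) // 2]
                        old = seq[j]
                        seq[j] = "ACGU"[int(rng.integers(4))]
                        if seq[j] == old:
                            seq[j] = {"A": "C", "C": "G", "G": "U", "U": "A"}[old]
                        dirty = True
                    i = s.find(core, i + 1)
            if not dirty:
                return
        raise SimulationError(f"could not mask spurious sites in {target_id}")

    for gid, seq in lnc_seqs.items():
        masked(gid, seq)
    for gid, seq in utr_seqs.items():
        masked(gid, seq)

    transcripts = {
        "lncrna": [Transcript(gid, "lncRNA", "".join(s)) for gid, s in lnc_seqs.items()],
        "mirna": [Transcript(gid, "miRNA", s) for gid, s in mirnas.items()],
        "mrna": [Transcript(gid, "utr3", "".join(s)) for gid, s in utr_seqs.items()],
    }
    truth = GroundTruth(
        seed=design.seed,
        circuits=[c.key for c in circuits],
        true_log2fc={},
        site_coords=site_coords,
    )
    return transcripts, truth


def merge_truth(counts_truth: GroundTruth, seq_truth: GroundTruth) -> GroundTruth:
    return GroundTruth(
        seed=counts_truth.seed,
        circuits=counts_truth.circuits,
        true_log2fc=counts_truth.true_log2fc,
        site_coords=seq_truth.site_coords,
    )


@dataclass(frozen=True)
class RecoveryScore:
    precision: float
    recall: float
    empty_report: bool = False


def score_recovery(report: pd.DataFrame, truth: GroundTruth) -> RecoveryScore:
    """Exact-triplet precision and recall of a circuit report against truth.

    An empty report has no denominator for precision; by convention it
    scores precision 1.0 with ``empty_report`` flagged, and recall 0.0
    (when circuits were planted).
    """
    reported = {
        (str(r.lncrna_id), str(r.mirna_id), str(r.mrna_id)) for r in report.itertuples()
    }
    planted = {tuple(c) for c in truth.circuits}
    tp = len(reported & planted)
    if not reported:
        recall = 1.0 if not planted else 0.0
        return RecoveryScore(precision=1.0, recall=recall, empty_report=True)
    recall = tp / len(planted) if planted else 1.0
    return RecoveryScore(precision=tp / len(reported), recall=recall)
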