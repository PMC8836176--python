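"""Stage orchestration: simulate / DE / duplex / sites / circuits / run-all.

Each stage is a function that reads the previous stage's files and writes
its own under the run directory, so running stages individually composes
to exactly the one-shot :func:`run_pipeline` (byte-identical outputs).
File names under the run directory are fixed:

    counts_genes.tsv, counts_mirna.tsv, conditions.tsv   (inputs / simulate)
    lncrna.fa, mirna.fa, utr3.fa                          (inputs / simulate)
    ground_truth.yaml                                     (simulate only)
    de_genes.tsv, de_lncrna.tsv, de_mirna.tsv, de_mrna.tsv
    duplex_hits.tsv, seed_sites.tsv, target_edges.tsv
    circuits.tsv, circuits.summary.txt, run.log
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .seqcore import read_fasta, write_fasta
from .expression import CountMatrix, read_counts, write_counts, nb_differential_test, filter_and_rank_de
from .duplex import AlignmentParams, EnergyParams, DuplexHit, best_pair_evidence, filter_duplex_pairs
from .seeds import (
    scan_seed_sites, site_table, simplified_site_score, internal_percentiles,
    TargetScoreRecord, filter_targets_by_percentile, read_target_scores,
)
from .circuits import assemble_circuits, rank_circuits, write_circuit_report
from .simulate import SimulationDesign, simulate_counts, simulate_transcriptome, merge_truth

log = logging.getLogger("spongescan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and flags of one pipeline run.

    Thresholds default to the published selection rules: |log2FC| > 0.5,
    FDR < 0.05, TPM > 1 for differential expression; alignment score >
    150 and hybridization mfe < -30 for the lncRNA:miRNA duplex; context
    percentile > 50 for miRNA:mRNA targeting.  Any override is echoed to
    the run log.
    """

    outdir: str = "run"
    lncrna_fasta: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    counts_genes: str | None = None
    counts_mirna: str | None = None
    conditions: str | None = None
    target_scores: str | None = None      # optional external percentile table
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    tpm_threshold: float = 1.0
    miranda_min: float = 150.0
    mfe_max: float = -30.0
    percentile_min: float = 50.0
    alignment_params: str | None = None   # parameter-file overrides
    energy_params: str | None = None
    mrna_anticorrelation: bool = True
    internal_percentiles: bool = True
    seed: int = 1653

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def overrides(self) -> dict:
        default = asdict(PipelineConfig())
        return {k: v for k, v in asdict(self).items() if default.get(k) != v}

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def _setup_log(cfg: PipelineConfig, level: int = logging.INFO) -> None:
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    log.setLevel(level)
    target = str(cfg.path("run.log").resolve())
    for h in list(log.handlers):  # re-point the run-scoped file handler
        if isinstance(h, logging.FileHandler) and h.baseFilename != target:
            log.removeHandler(h)
            h.close()
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(target, mode="a")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    log.info("spongescan %s; thresholds/overrides: %s", __version__, cfg.overrides())


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, design: SimulationDesign | None = None) -> None:
    """Write a full synthetic dataset (counts, sequences, truth) to outdir."""
    _setup_log(cfg)
    design = design or SimulationDesign(seed=cfg.seed)
    counts, truth_counts = simulate_counts(design)
    seqs, truth_seq = simulate_transcriptome(design)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    genes = pd.concat([counts.lncrna.counts, counts.mrna.counts])
    lengths = pd.concat([counts.lncrna.gene_lengths, counts.mrna.gene_lengths])
    gene_cm = CountMatrix(genes, counts.lncrna.conditions, lengths)
    write_counts(gene_cm, out / "counts_genes.tsv", out / "conditions.tsv")
    write_counts(counts.mirna, out / "counts_mirna.tsv", out / "conditions.tsv")
    write_fasta(seqs["lncrna"], out / "lncrna.fa")
    write_fasta(seqs["mirna"], out / "mirna.fa")
    write_fasta(seqs["mrna"], out / "utr3.fa")
    merge_truth(truth_counts, truth_seq).to_yaml(out / "ground_truth.yaml")
    log.info("simulate: %d lncRNA, %d miRNA, %d mRNA, %d planted circuits",
             design.n_lncrna, design.n_mirna, design.n_mrna, design.n_circuits)


def _input(cfg: PipelineConfig, attr: str, default_name: str) -> Path:
    configured = getattr(cfg, attr)
    p = Path(configured) if configured else cfg.path(default_name)
    if not p.exists():
        raise PipelineError(f"stage input missing: {p} ({attr})")
    return p


def stage_de(cfg: PipelineConfig) -> None:
    """Differential expression for genes (lncRNA + mRNA) and miRNAs."""
    _setup_log(cfg)
    try:
        gene_cm = read_counts(_input(cfg, "counts_genes", "counts_genes.tsv"),
                              _input(cfg, "conditions", "conditions.tsv"))
        mir_cm = read_counts(_input(cfg, "counts_mirna", "counts_mirna.tsv"),
                             _input(cfg, "conditions", "conditions.tsv"))
        lnc_ids = {t.id for t in read_fasta(_input(cfg, "lncrna_fasta", "lncrna.fa"))}

        de_genes = nb_differential_test(gene_cm)
        de_mirna_all = nb_differential_test(mir_cm)
        keep = dict(lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.fdr_threshold,
                    tpm_threshold=cfg.tpm_threshold)
        de_lnc = filter_and_rank_de(de_genes[de_genes.index.isin(lnc_ids)], **keep)
        de_mrna = filter_and_rank_de(de_genes[~de_genes.index.isin(lnc_ids)], **keep)
        de_mirna = filter_and_rank_de(de_mirna_all, **keep)

        de_genes.to_csv(cfg.path("de_genes.tsv"), sep="\t")
        de_lnc.to_csv(cfg.path("de_lncrna.tsv"), sep="\t")
        de_mrna.to_csv(cfg.path("de_mrna.tsv"), sep="\t")
        de_mirna.to_csv(cfg.path("de_mirna.tsv"), sep="\t")
        log.info("de: %d DE lncRNA, %d DE miRNA, %d DE mRNA",
                 len(de_lnc), len(de_mirna), len(de_mrna))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"stage 'de' failed: {exc}") from exc


def stage_duplex(cfg: PipelineConfig) -> None:
    """lncRNA:miRNA duplex prediction (DE lncRNAs x all miRNAs) + joint filter."""
    _setup_log(cfg)
    try:
        ap = AlignmentParams.from_yaml(cfg.alignment_params) if cfg.alignment_params else AlignmentParams.reference()
        ep = EnergyParams.from_yaml(cfg.energy_params) if cfg.energy_params else EnergyParams.reference()
        lncs = {t.id: t for t in read_fasta(_input(cfg, "lncrna_fasta", "lncrna.fa"), "lncRNA")}
        mirs = read_fasta(_input(cfg, "mirna_fasta", "mirna.fa"), "miRNA")
        if not mirs:
            raise PipelineError("stage 'duplex': miRNA FASTA contains no records")
        de_lnc = pd.read_csv(cfg.path("de_lncrna.tsv"), sep="\t", index_col=0)

        rows = []
        for lnc_id in de_lnc.index:
            if lnc_id not in lncs:
                raise PipelineError(f"stage 'duplex': DE table names unknown lncRNA {lnc_id!r}")
            for mir in mirs:
                hit = best_pair_evidence(mir, lncs[lnc_id], ap, ep)
                if hit is not None:
                    rows.append({
                        "mirna_id": hit.mirna_id, "target_id": hit.target_id,
                        "align_score": hit.align_score, "mfe": hit.mfe,
                        "target_start": hit.target_start, "target_end": hit.target_end,
                        "pairing_trace": hit.pairing_trace.replace("\n", ";"),
                    })
        hits = pd.DataFrame(rows, columns=["mirna_id", "target_id", "align_score",
                                           "mfe", "target_start", "target_end", "pairing_trace"])
        passing = hits[(hits.align_score > cfg.miranda_min) & (hits.mfe < cfg.mfe_max)]
        hits.to_csv(cfg.path("duplex_hits.tsv"), sep="\t", index=False)
        passing.to_csv(cfg.path("duplex_pairs.tsv"), sep="\t", index=False)
        log.info("duplex: %d candidate hits, %d pairs pass score>%g & mfe<%g",
                 len(hits), len(passing), cfg.miranda_min, cfg.mfe_max)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'duplex' failed: {exc}") from exc


def stage_sites(cfg: PipelineConfig) -> None:
    """Seed-site scan on mRNA 3'UTRs + percentile target filter."""
    _setup_log(cfg)
    try:
        mirs = read_fasta(_input(cfg, "mirna_fasta", "mirna.fa"), "miRNA")
        utrs = read_fasta(_input(cfg, "utr_fasta", "utr3.fa"), "utr3")

        all_sites = []
        scores = {}
        sites_by_pair = {}
        for mir in mirs:
            for utr in utrs:
                sites = scan_seed_sites(mir, utr)
                sites_by_pair[(mir.id, utr.id)] = sites
                scores[(mir.id, utr.id)] = simplified_site_score(sites, utr)
                all_sites.extend(sites)
        site_table(all_sites).to_csv(cfg.path("seed_sites.tsv"), sep="\t", index=False)

        if cfg.target_scores:
            records = read_target_scores(cfg.target_scores)
            source = "external"
        elif cfg.internal_percentiles:
            ser = pd.Series(scores)
            pct = internal_percentiles(ser)
            records = [
                TargetScoreRecord(m, g, float(pct[(m, g)]))
                for (m, g) in ser.index
                if sites_by_pair[(m, g)]
            ]
            source = "internal-fallback"
        else:
            records = []
            source = "none"
        passing = filter_targets_by_percentile(records, cfg.percentile_min)
        edges = pd.DataFrame(
            [{"mirna_id": r.mirna_id, "gene_id": r.gene_id, "percentile": r.percentile,
              "score_source": source} for r in passing],
            columns=["mirna_id", "gene_id", "percentile", "score_source"],
        )
        edges.to_csv(cfg.path("target_edges.tsv"), sep="\t", index=False)
        log.info("sites: %d seed sites, %d target edges pass percentile>%g (%s scores)",
                 len(all_sites), len(edges), cfg.percentile_min, source)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'sites' failed: {exc}") from exc


def stage_circuits(cfg: PipelineConfig) -> None:
    """Assemble, rank and report circuits from the staged tables."""
    _setup_log(cfg)
    try:
        de_lnc = pd.read_csv(cfg.path("de_lncrna.tsv"), sep="\t", index_col=0)
        de_mirna = pd.read_csv(cfg.path("de_mirna.tsv"), sep="\t", index_col=0)
        de_mrna = pd.read_csv(cfg.path("de_mrna.tsv"), sep="\t", index_col=0)
        pairs = pd.read_csv(cfg.path("duplex_pairs.tsv"), sep="\t")
        edges_df = pd.read_csv(cfg.path("target_edges.tsv"), sep="\t")

        duplex_hits = [
            DuplexHit(mirna_id=r.mirna_id, target_id=r.target_id,
                      align_score=r.align_score, mfe=r.mfe,
                      target_start=r.target_start, target_end=r.target_end)
            for r in pairs.itertuples()
        ]
        edges = {(r.mirna_id, r.gene_id): float(r.percentile) for r in edges_df.itertuples()}
        circuits = assemble_circuits(
            de_lnc, de_mirna, duplex_hits, edges,
            de_mrna=de_mrna if cfg.mrna_anticorrelation else None,
            require_mrna_anticorrelation=cfg.mrna_anticorrelation,
        )
        circuits = rank_circuits(circuits)
        thresholds = {
            "lfc": cfg.lfc_threshold, "fdr": cfg.fdr_threshold, "tpm": cfg.tpm_threshold,
            "miranda_min": cfg.miranda_min, "mfe_max": cfg.mfe_max,
            "percentile_min": cfg.percentile_min,
        }
        stage_counts = {
            "de_lncrna": len(de_lnc), "de_mirna": len(de_mirna), "de_mrna": len(de_mrna),
            "duplex_pairs": len(pairs), "target_edges": len(edges_df),
            "circuits": len(circuits),
        }
        inputs = [cfg.path(n) for n in
                  ("de_lncrna.tsv", "de_mirna.tsv", "de_mrna.tsv",
                   "duplex_pairs.tsv", "target_edges.tsv")]
        write_circuit_report(circuits, cfg.path("circuits.tsv"),
                             thresholds=thresholds, stage_counts=stage_counts,
                             input_files=inputs, seed=cfg.seed)
        log.info("circuits: %d reported", len(circuits))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'circuits' failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run DE -> duplex -> sites -> circuits; returns the report path.

    On stage failure a FAILED marker naming the stage is left in the run
    directory and :class:`PipelineError` propagates; completed stages'
    outputs are retained.
    """
    _setup_log(cfg)
    for stage in (stage_de, stage_duplex, stage_sites, stage_circuits):
        try:
            stage(cfg)
        except Exception as exc:
            marker = cfg.path("FAILED")
            marker.write_text(f"{stage.__name__}: {exc}\n")
            log.error("%s failed: %s", stage.__name__, exc)
            raise
    return cfg.path("circuits.tsv")
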