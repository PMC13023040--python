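"""File formats, demultiplexing, run configuration and the pipeline driver.

All tabular interchange uses TSV (tab-separated, header row, UTF-8, '.'
decimal).  Tables written by the pipeline carry a leading comment line
naming the producing stage and the configuration hash, e.g.::

    # repairmap stage=screen config=5f3a9c01

Readers skip ``#`` comment lines, so the tables round-trip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import cluster as _cluster
from . import screen as _screen
from .indel import AlleleCall, OutcomeSpectrum, format_event
from .patterns import (
    DEFAULT_MH_MIN,
    DEFAULT_WINDOW_BP,
    EDITED_PATTERNS,
)

__all__ = [
    "read_fasta",
    "read_reads",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "write_allele_table",
    "write_spectrum",
    "demultiplex_by_barcode",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """All records of a FASTA file as ``{name: sequence}``."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from FASTQ or FASTA (by extension)."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.description, str(rec.seq).upper())
            for rec in SeqIO.parse(str(p), fmt)]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name.split()[0], description=name)
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path: str | Path, stage: str = "",
              config_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if stage:
            fh.write(f"# repairmap stage={stage} config={config_hash or 'none'}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_allele_table(spectrum: OutcomeSpectrum, path: str | Path,
                       stage: str = "classify", config_hash: str = "") -> None:
    """Allele table TSV: sequence, pattern, mh_len, compact events, counts."""
    total = spectrum.total_edited + spectrum.unedited
    rows = []
    for call in spectrum.allele_table:
        rows.append({
            "allele_seq": call.allele_seq,
            "pattern": call.pattern,
            "mh_len": call.mh_len,
            "templated": call.templated,
            "events": ";".join(format_event(e) for e in call.events),
            "read_count": call.read_count,
            "frequency": call.read_count / total if total else 0.0,
        })
    write_tsv(pd.DataFrame(rows), path, stage, config_hash)


def write_spectrum(spectrum: OutcomeSpectrum, path: str | Path,
                   stage: str = "classify", config_hash: str = "") -> None:
    rows = [
        {"pattern": p, "count": spectrum.counts.get(p, 0),
         "proportion": spectrum.proportions.get(p, float("nan"))}
        for p in EDITED_PATTERNS
    ]
    rows.append({"pattern": "Unedited", "count": spectrum.unedited,
                 "proportion": float("nan")})
    df = pd.DataFrame(rows)
    write_tsv(df, path, stage, config_hash)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex_by_barcode(
    reads: Iterable[tuple[str, str]],
    barcode_table: dict[str, str],
    max_mismatch: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Split reads by exact (or <=1-mismatch) barcode prefix, stripping it.

    ``barcode_table`` maps sample name to barcode; barcodes must be unique
    and equal length.  Unassigned reads land in the ``"unmatched"`` bin
    with their sequence intact.
    """
    barcodes = list(barcode_table.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes")
    if len({len(b) for b in barcodes}) > 1:
        raise ValueError("barcodes must have equal length")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    blen = len(barcodes[0])
    by_barcode = {bc: sample for sample, bc in barcode_table.items()}
    bins: dict[str, list[tuple[str, str]]] = {s: [] for s in barcode_table}
    bins["unmatched"] = []
    for name, seq in reads:
        prefix = seq[:blen]
        sample = by_barcode.get(prefix)
        if sample is None and max_mismatch == 1:
            hits = [s for bc, s in by_barcode.items()
                    if sum(a != b for a, b in zip(bc, prefix)) <= 1]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            bins["unmatched"].append((name, seq))
        else:
            bins[sample].append((name, seq[blen:]))
    return bins


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete configuration of a screen-analysis run."""

    manifest: str = ""
    counts: str = ""
    counts2: str = ""  # optional second library
    out_dir: str = "repairmap_out"
    window_bp: int = DEFAULT_WINDOW_BP
    mh_min: int = DEFAULT_MH_MIN
    min_reads: int = _screen.DEFAULT_MIN_READS
    n_perm: int = _screen.DEFAULT_N_PERM
    seed: int = 0
    lfc_threshold: float = _screen.DEFAULT_LFC_THRESHOLD
    p_threshold: float = _screen.DEFAULT_P_THRESHOLD
    n_top: int = _cluster.DEFAULT_N_TOP
    alignment: dict = field(default_factory=lambda: {
        "match": 2.0, "mismatch": -3.0, "gap_open": -8.0,
        "gap_extend": -1.0, "min_identity": 0.6,
    })

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window_bp < 0 or self.mh_min < 0 or self.n_perm < 1:
            raise ValueError("thresholds out of range")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        # Hash of the analysis parameters only; file locations do not
        # change results, so they are excluded.
        params = {k: v for k, v in dataclasses.asdict(self).items()
                  if k not in ("manifest", "counts", "counts2", "out_dir")}
        blob = json.dumps(params, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:8]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _log(fh, **fields) -> None:
    fields["time"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    fh.write(json.dumps(fields) + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the screen analysis end to end and write all artifacts.

    Stages: load manifest and guide counts -> filter -> per-guide Fisher
    tests -> directional ranking -> gene-level RRA with permutation
    p-values -> (optional) two-library integration -> hit calling -> top-
    gene selection, clustering and correlation.  Returns the final gene
    score table.  A JSON-lines run log records versions, seeds and
    thresholds; a stage failure aborts with a stage-tagged error, keeping
    partial outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    log_path = out / "run_log.jsonl"
    with open(log_path, "a", encoding="utf-8") as logf:
        _log(logf, stage="start", config_hash=h, seed=config.seed,
             n_perm=config.n_perm, min_reads=config.min_reads)
        stage = "load"
        try:
            manifest = read_tsv(config.manifest)
            counts_a = read_tsv(config.counts)
            records_a = counts_a.merge(
                manifest[["guide_id", "gene", "category"]], on="guide_id",
                how="left", suffixes=("", "_manifest"),
            ) if "gene" not in counts_a.columns else counts_a

            stage = "screen"
            scores_a, excl_a = _screen.analyze_library(
                records_a, min_reads=config.min_reads,
                n_perm=config.n_perm, seed=config.seed,
            )
            write_tsv(scores_a, out / "gene_scores_libA.tsv", "screen", h)
            write_tsv(excl_a, out / "excluded_guides_libA.tsv", "screen", h)
            _log(logf, stage="screen", library="A",
                 n_guides=len(records_a), n_excluded=len(excl_a))

            if config.counts2:
                counts_b = read_tsv(config.counts2)
                records_b = counts_b.merge(
                    manifest[["guide_id", "gene", "category"]], on="guide_id",
                    how="left", suffixes=("", "_manifest"),
                ) if "gene" not in counts_b.columns else counts_b
                scores_b, excl_b = _screen.analyze_library(
                    records_b, min_reads=config.min_reads,
                    n_perm=config.n_perm, seed=config.seed + 1,
                )
                write_tsv(scores_b, out / "gene_scores_libB.tsv", "screen", h)
                stage = "integrate"
                combined = _screen.integrate_libraries(scores_a, scores_b)
            else:
                combined = scores_a.rename(columns={
                    "log2fc": "combined_log2fc", "p_empirical": "p_combined",
                })

            stage = "hits"
            hits = _screen.call_hits(
                combined, config.lfc_threshold, config.p_threshold)
            write_tsv(hits, out / "gene_scores.tsv", "hits", h)
            _log(logf, stage="hits", n_hits=int(hits["is_hit"].sum()))

            stage = "cluster"
            selection, matrix = _cluster.select_top_genes(
                hits, n_top=config.n_top)
            write_tsv(selection, out / "top_genes.tsv", "cluster", h)
            std = matrix.standardize()
            if len(std.values) >= 2:
                Z, order = _cluster.hcluster_profiles(std)
                merge = pd.DataFrame(
                    Z, columns=["left", "right", "height", "size"])
                merge.insert(0, "step", range(1, len(merge) + 1))
                write_tsv(merge, out / "gene_dendrogram.tsv", "cluster", h)
                write_tsv(pd.DataFrame({"gene": order}),
                          out / "gene_order.tsv", "cluster", h)
                corr = _cluster.pearson_matrix(std)
                write_tsv(corr.reset_index(names="gene"),
                          out / "gene_correlations.tsv", "cluster", h)
            _log(logf, stage="done", n_genes_selected=len(matrix.values))
            return hits
        except FileNotFoundError as exc:
            _log(logf, stage=stage, error=str(exc))
            raise FileNotFoundError(f"[stage {stage}] {exc}") from exc
        except Exception as exc:
            _log(logf, stage=stage, error=str(exc))
            raise RuntimeError(f"[stage {stage}] {exc}") from exc
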