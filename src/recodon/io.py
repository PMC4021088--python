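"""File formats and run configuration.

FASTA is the canonical sequence interchange (read/written through
Biopython); codon-usage tables, motif lists, violation reports and Ct data
travel as tab-delimited text; run configuration is a flat YAML mapping with
strict key checking.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, EmptyInputError, RecodonError
from .screen import (
    DEFAULT_FORBIDDEN_SITES,
    DEFAULT_MOTIFS,
    DesignConstraints,
    MotifPattern,
    ScreenReport,
)
from .usage import CodonUsageTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA as ``(id, uppercase sequence)`` pairs."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise RecodonError(f"duplicate FASTA ids in {path}: {', '.join(dupes)}")
    out = []
    for r in records:
        seq = str(r.seq)
        if seq != seq.upper():
            logger.info("uppercasing sequence %s on read", r.id)
        out.append((r.id, seq.upper()))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tab-delimited tables


def write_usage_table(table: CodonUsageTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "codon": sorted(table.counts),
            "amino_acid": [table.code.table[c] for c in sorted(table.counts)],
            "count": [table.counts[c] for c in sorted(table.counts)],
            "rel_freq": [round(table.rel_freq[c], 6) for c in sorted(table.counts)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_usage_table(path: str | Path) -> CodonUsageTable:
    """Read a table written by :func:`write_usage_table` (counts column only
    is trusted; relative frequencies are recomputed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "codon" not in df or "count" not in df:
        raise RecodonError(f"{path} lacks codon/count columns")
    counts = dict(zip(df["codon"].str.upper(), df["count"].astype(int)))
    return CodonUsageTable.from_counts(counts, source_label=str(path))


def read_motif_table(path: str | Path) -> list[MotifPattern]:
    """Read a motif list: tab-delimited ``label  category  pattern``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "category", "pattern"}
    if not required <= set(df.columns):
        raise RecodonError(
            f"{path} must have columns {sorted(required)}"
        )
    return [
        MotifPattern(row.pattern, row.label, row.category)
        for row in df.itertuples()
    ]


def write_motif_table(motifs: list[MotifPattern], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [m.label for m in motifs],
            "category": [m.category for m in motifs],
            "pattern": [m.pattern for m in motifs],
        }
    ).to_csv(path, sep="\t", index=False)


def violations_frame(report: ScreenReport) -> pd.DataFrame:
    rows = [
        {
            "kind": v.kind,
            "start": v.start,
            "end": v.end,
            "label": v.label,
            "matched": v.matched,
            "mate_start": v.mate[0] if v.mate else "",
            "mate_end": v.mate[1] if v.mate else "",
            "strand": v.strand,
        }
        for v in report.violations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "start", "end", "label", "matched",
            "mate_start", "mate_end", "strand",
        ],
    )


def write_violations(
    report: ScreenReport, path_or_buffer, *, header_note: str = ""
) -> None:
    df = violations_frame(report)
    buf = _io.StringIO()
    if header_note:
        buf.write(f"# {header_note}\n")
    buf.write(f"# gc_percent={report.gc_percent:.1f} gc_ok={report.gc_ok}\n")
    df.to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        Path(path_or_buffer).write_text(text)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct data: tab-delimited with columns ``sample  condition  ct`` and an
    optional ``log10_dilution`` column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "ct" not in {c.lower() for c in df.columns}:
        raise RecodonError(f"{path} lacks a 'ct' column")
    df.columns = [c.lower() for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the design pipeline, loadable from YAML.

    Defaults reproduce the documented per-module defaults (rare-codon
    threshold 0.20, 12 bp minimum stem, GC window 55 ± 3...).
    """

    threshold: float = 0.20
    seed: int = 0
    restarts: int = 8
    max_rounds: int = 10_000
    min_at_run: int = 6
    min_direct_repeat: int = 10
    min_palindrome: int = 8
    min_stem: int = 12
    gc_target: float = 55.0
    gc_window: float = 3.0
    scan_both_strands: bool = False
    stop_codons: tuple[str, ...] = ("TAA", "TGA")
    flank5: str = "GCGGCCGC"
    flank3: str = "TTAATTAA"
    motifs_file: str | None = None
    verbosity: str = "info"

    def constraints(self) -> DesignConstraints:
        motifs = (
            tuple(read_motif_table(self.motifs_file))
            if self.motifs_file
            else DEFAULT_MOTIFS
        )
        return DesignConstraints(
            motifs=motifs,
            min_at_run=self.min_at_run,
            min_direct_repeat=self.min_direct_repeat,
            min_palindrome=self.min_palindrome,
            min_stem=self.min_stem,
            forbidden_sites=DEFAULT_FORBIDDEN_SITES,
            gc_target=self.gc_target,
            gc_window=self.gc_window,
            scan_both_strands=self.scan_both_strands,
        )

    def to_dict(self) -> dict:
        d = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    def digest(self) -> str:
        """Short hash of the effective configuration, for report provenance."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_CONFIG_TYPES = {
    "threshold": float, "seed": int, "restarts": int, "max_rounds": int,
    "min_at_run": int, "min_direct_repeat": int, "min_palindrome": int,
    "min_stem": int, "gc_target": float, "gc_window": float,
    "scan_both_strands": bool, "stop_codons": list, "flank5": str,
    "flank3": str, "motifs_file": str, "verbosity": str,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys and type clashes error."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a key-value mapping")
    unknown = sorted(set(raw) - set(_CONFIG_TYPES))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    coerced = {}
    for key, value in raw.items():
        want = _CONFIG_TYPES[key]
        if want is float and isinstance(value, int):
            value = float(value)
        if want is str and value is None:
            pass
        elif not isinstance(value, want) or (
            want is not bool and isinstance(value, bool)
        ):
            raise ConfigError(
                f"config key {key!r} expects {want.__name__}, "
                f"got {type(value).__name__}"
            )
        if key == "stop_codons":
            value = tuple(str(s).upper() for s in value)
        coerced[key] = value
    cfg = RunConfig(**coerced)
    logger.info("effective config: %s (digest %s)", cfg.to_dict(), cfg.digest())
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
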