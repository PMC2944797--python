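"""Readers and writers for the formats the pipeline touches.

FASTA (nucleotide and protein), the 12-column tabular similarity-hit
dialect, newick trees, tab-separated report tables, and the run
configuration. All report tables are UTF-8 TSV with a single header row.
"""

from __future__ import annotations

import logging
import tomllib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("hortus")

NUCLEOTIDE_CHARS = set("ACGTN")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
SUPERKINGDOMS = ("Bacterial", "Eukaryotic", "Viral", "Unknown")

__all__ = [
    "SequenceRecord",
    "HitRecord",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_taxonomy",
    "write_taxonomy",
    "write_newick",
    "read_newick",
    "write_table",
]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide or amino-acid sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the full remainder of the header is kept in ``description``.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: str = "nucleotide"  # or "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")
        allowed = NUCLEOTIDE_CHARS if self.alphabet == "nucleotide" else PROTEIN_CHARS
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.seq.upper()) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "nucleotide":
            raise ValueError("reverse complement of a protein sequence")
        return replace(self, seq=str(Seq(self.seq).reverse_complement()))


def infer_alphabet(seq: str) -> str:
    """Guess nucleotide vs protein from sequence characters."""
    return "nucleotide" if set(seq.upper()) <= NUCLEOTIDE_CHARS else "protein"


@dataclass
class HitRecord:
    """One query -> subject similarity result (12-column tabular dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    e_value: float = 0.0
    bit_score: float = 0.0
    subject_genus: str = "Unknown"
    subject_superkingdom: str = "Unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: alignment length "
                f"{self.alignment_length} < 1"
            )
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        if self.subject_superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"superkingdom {self.subject_superkingdom!r} not one of {SUPERKINGDOMS}"
            )


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and knobs.

    Defaults follow the analysis this package reproduces: similarity hits
    are retained at e <= 1e-05, recruited reads are banded at
    95-100 / 90-95 / 85-90 / 80-85 / 75-80 percent identity, and the
    strain-similarity cutoff is a strict >98% identity.
    """

    evalue_max: float = 1e-5
    correlation_method: str = "spearman"  # or "pearson"
    contig_order: str = "ascending"  # or "descending"
    identity_bands: tuple[tuple[float, float], ...] = (
        (95.0, 100.0),
        (90.0, 95.0),
        (85.0, 90.0),
        (80.0, 85.0),
        (75.0, 80.0),
    )
    strain_identity_cutoff: float = 98.0
    min_orf_codons: int = 60
    gc_window_bp: int = 10_000
    gc_step_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.contig_order not in ("ascending", "descending"):
            raise ValueError(f"unknown contig order {self.contig_order!r}")
        if not (self.gc_window_bp >= self.gc_step_bp > 0):
            raise ValueError("need gc_window_bp >= gc_step_bp > 0")
        bands = sorted(self.identity_bands)
        for lo, hi in bands:
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError(f"band ({lo}, {hi}) outside [0, 100]")
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if lo < hi:
                raise ValueError("identity bands overlap")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "identity_bands" in data:
            data["identity_bands"] = tuple(tuple(b) for b in data["identity_bands"])
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, in file order.

    Ids are the first whitespace token of each header. A duplicate id is a
    hard error naming the offending id; an empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        alpha = alphabet or infer_alphabet(seq)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc, alphabet=alpha))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# 12-column tabular hits

_HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "qstart", "qend", "sstart", "send",
    "e_value", "bit_score",
]


def read_tabular_hits(
    path: str | Path,
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
) -> list[HitRecord]:
    """Parse the standard 12-column tab-separated hit format.

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bit score. Extra
    columns are ignored with a warning; fewer columns or unparseable
    numerics raise an error citing the 1-based line number. ``taxonomy``
    optionally maps subject id -> (genus, superkingdom).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[HitRecord] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            if len(fields) > 12 and not warned:
                warnings.warn(f"{path}: extra columns beyond 12 are ignored")
                warned = True
            f = fields[:12]
            try:
                genus, kingdom = ("Unknown", "Unknown")
                if taxonomy and f[1] in taxonomy:
                    genus, kingdom = taxonomy[f[1]]
                hits.append(HitRecord(
                    query_id=f[0], subject_id=f[1],
                    percent_identity=float(f[2]), alignment_length=int(f[3]),
                    mismatches=int(f[4]), gap_opens=int(f[5]),
                    qstart=int(f[6]), qend=int(f[7]),
                    sstart=int(f[8]), send=int(f[9]),
                    e_value=float(f[10]), bit_score=float(f[11]),
                    subject_genus=genus, subject_superkingdom=kingdom,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.e_value:.2e}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# taxonomy tables


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (genome_id, genus, superkingdom)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "genus", "superkingdom"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: taxonomy table needs columns {sorted(required)}")
    bad = set(df["superkingdom"]) - set(SUPERKINGDOMS)
    if bad:
        raise ValueError(f"{path}: unknown superkingdoms {sorted(bad)}")
    return df


def write_taxonomy(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def taxonomy_map(df: pd.DataFrame) -> dict[str, tuple[str, str]]:
    return {
        row.genome_id: (row.genus, row.superkingdom)
        for row in df.itertuples()
    }


# ---------------------------------------------------------------------------
# newick


def write_newick(tree, path: str | Path) -> None:
    """Serialize a ClusterTree (or anything with ``to_newick``) to a file."""
    text = tree.to_newick()
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_newick(path: str | Path):
    """Parse a newick file back into a ClusterTree."""
    from .profile_comparison import parse_newick

    with open(path) as fh:
        return parse_newick(fh.read())


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as single-header-row UTF-8 TSV."""
    df.to_csv(path, sep="\t", index=False)
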