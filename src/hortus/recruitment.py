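"""Fragment recruitment against concatenated-contig pseudogenomes.

Draft-genome contigs are concatenated in a defined length order into a
"pseudogenome" with one global coordinate system; each metagenome read
is assigned to its best-scoring genome ("top hit"), its percent
identity is measured over the full read by semi-global alignment, and
recruited reads are binned into fixed identity bands. The fraction of
recruited reads above a strict identity cutoff (>98% by default) is the
strain-similarity statistic; per-genome identity means and windowed GC
deviation tracks feed the recruitment plots.

Candidate placements are found with the k-mer seed index; significance
is gated on the local-alignment score's e-value, while the recorded
identity comes from aligning the entire read (edit-distance infix
alignment), so with a substitution-only read model the identity of an
error-free read from a strain at divergence d is exactly
100 * (1 - Binomial(L, d) / L).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _align
from .io_formats import SequenceRecord
from .taxonomic_binning import gc_percent

__all__ = [
    "Pseudogenome",
    "RecruitmentResult",
    "build_pseudogenome",
    "recruit_reads",
    "band_summary",
    "identity_summary",
    "gc_track",
    "BELOW_RANGE",
]

BELOW_RANGE = "below-range"

DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (95.0, 100.0), (90.0, 95.0), (85.0, 90.0), (80.0, 85.0), (75.0, 80.0),
)


@dataclass
class Pseudogenome:
    """Contigs concatenated in length order under one coordinate system."""

    genome_id: str
    contig_ids: list[str]
    contig_lengths: list[int]
    offsets: list[int]  # global start of each contig, strictly increasing
    seq: str
    order: str = "ascending"

    @property
    def total_length(self) -> int:
        return self.offsets[-1] + self.contig_lengths[-1]

    def global_to_local(self, pos: int) -> tuple[str, int]:
        if not 0 <= pos < self.total_length:
            raise ValueError(f"position {pos} outside [0, {self.total_length})")
        i = bisect.bisect_right(self.offsets, pos) - 1
        return self.contig_ids[i], pos - self.offsets[i]

    def local_to_global(self, contig_id: str, pos: int) -> int:
        i = self.contig_ids.index(contig_id)
        if not 0 <= pos < self.contig_lengths[i]:
            raise ValueError(f"position {pos} outside contig {contig_id}")
        return self.offsets[i] + pos

    def spans_junction(self, start: int, end: int) -> bool:
        """True when [start, end) crosses a contig boundary."""
        return self.global_to_local(start)[0] != self.global_to_local(end - 1)[0]


def build_pseudogenome(
    contigs: Sequence[SequenceRecord],
    genome_id: str,
    order: str = "ascending",
) -> Pseudogenome:
    """Concatenate contigs sorted by length (ties by id) per ``order``."""
    if not contigs:
        raise ValueError("cannot build a pseudogenome from zero contigs")
    if order not in ("ascending", "descending"):
        raise ValueError(f"unknown contig order {order!r}")
    ordered = sorted(contigs, key=lambda c: (len(c.seq), c.id),
                     reverse=(order == "descending"))
    offsets, pos = [], 0
    for c in ordered:
        offsets.append(pos)
        pos += len(c.seq)
    return Pseudogenome(
        genome_id=genome_id,
        contig_ids=[c.id for c in ordered],
        contig_lengths=[len(c.seq) for c in ordered],
        offsets=offsets,
        seq="".join(c.seq for c in ordered),
        order=order,
    )


@dataclass
class RecruitmentResult:
    """Per-read recruitment assignments (one genome at most per read)."""

    table: pd.DataFrame  # read_id, genome_id, position, identity, band, junction
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def per_genome(self) -> dict[str, pd.DataFrame]:
        return {g: t for g, t in self.table.groupby("genome_id")}


def _band_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


def assign_band(identity: float, bands: Sequence[tuple[float, float]]) -> str:
    """Bands are half-open [lo, hi) except the topmost, closed at its high edge."""
    ordered = sorted(bands)
    top = ordered[-1]
    if top[0] <= identity <= top[1]:
        return _band_label(*top)
    for lo, hi in ordered[:-1]:
        if lo <= identity < hi:
            return _band_label(lo, hi)
    return BELOW_RANGE


def _seed_candidates(
    read: str, k: int, index: dict[str, list[tuple[int, int]]], max_clusters: int = 2
):
    """Seed-supported diagonal clusters, as {genome_idx: [(lo_diag, hi_diag)]}.

    Seed diagonals within 32 bp of each other are merged into one
    cluster; per genome the ``max_clusters`` clusters with the most
    seeds are kept, so an isolated chance k-mer elsewhere in the genome
    cannot blow the alignment window up to the whole sequence.
    """
    diags: dict[int, list[int]] = {}
    for qpos in range(0, len(read) - k + 1):
        for gi, tpos in index.get(read[qpos:qpos + k], ()):
            diags.setdefault(gi, []).append(tpos - qpos)
    out: dict[int, list[tuple[int, int]]] = {}
    for gi, ds in diags.items():
        ds.sort()
        clusters: list[list[int]] = []  # [lo, hi, n_seeds]
        for d in ds:
            if clusters and d - clusters[-1][1] <= 32:
                clusters[-1][1] = d
                clusters[-1][2] += 1
            else:
                clusters.append([d, d, 1])
        clusters.sort(key=lambda c: -c[2])
        out[gi] = [(lo, hi) for lo, hi, _ in clusters[:max_clusters]]
    return out


def recruit_reads(
    reads: Sequence[SequenceRecord],
    genomes: Sequence[Pseudogenome],
    evalue_max: float = 1e-5,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    k: int = 11,
) -> RecruitmentResult:
    """Assign each read to its best genome and record identity and band.

    The best placement across the whole database is retained (ties by
    e-value then lexicographic genome id); reads attaining no placement
    at e <= evalue_max are excluded — absence of a hit is a value, not
    an error. Identity is 100 * (1 - edit distance / read length) from
    the semi-global alignment of the full read; placements crossing a
    contig junction are flagged.
    """
    if not genomes:
        raise ValueError("empty genome database")
    kindex: dict[str, list[tuple[int, int]]] = {}
    for gi, g in enumerate(genomes):
        s = g.seq
        for pos in range(len(s) - k + 1):
            kindex.setdefault(s[pos:pos + k], []).append((gi, pos))
    db_len = sum(g.total_length for g in genomes)
    rows = []
    for read in reads:
        if read.alphabet != "nucleotide":
            raise ValueError(f"read {read.id} is not nucleotide")
        best = None  # (-score, evalue, genome_id, ...)
        for oriented in (read.seq, str(Seq(read.seq).reverse_complement())):
            for gi, clusters in _seed_candidates(oriented, k, kindex).items():
                g = genomes[gi]
                for lo, hi in clusters:
                    pad = len(oriented) // 4 + 16
                    wstart = max(0, lo - pad)
                    wend = min(g.total_length, hi + len(oriented) + pad)
                    window = g.seq[wstart:wend]
                    score = _align.local_score(oriented, window)
                    e, _bits = _align.evalue(score, len(oriented), db_len)
                    if e > evalue_max:
                        continue
                    res = edlib.align(oriented, window, mode="HW", task="locations")
                    (tstart, tend_inc), = res["locations"][:1]
                    # identity over the full read length: path-independent
                    # (edlib reports one of possibly many equal-cost paths,
                    # whose column counts differ) and equal to
                    # 100*(1 - edits/L) for the substitution-dominated reads
                    # this stage recruits
                    L = len(oriented)
                    identity = 100.0 * max(L - res["editDistance"], 0) / L
                    key = (-score, e, g.genome_id)
                    if best is None or key < best[0]:
                        best = (key, g, wstart + tstart, wstart + tend_inc + 1, identity)
        if best is None:
            continue
        _, g, gstart, gend, identity = best
        rows.append({
            "read_id": read.id, "genome_id": g.genome_id,
            "position": gstart, "identity": identity,
            "band": assign_band(identity, bands),
            "junction": g.spans_junction(gstart, gend),
        })
    table = pd.DataFrame(
        rows, columns=["read_id", "genome_id", "position", "identity", "band", "junction"]
    )
    return RecruitmentResult(table=table, bands=tuple(bands))


def band_summary(
    result: RecruitmentResult,
    strain_identity_cutoff: float = 98.0,
) -> pd.DataFrame:
    """Per-genome identity-band counts and the strain-similarity fraction.

    Columns: one per band (highest first) plus the explicit below-range
    bucket, total recruited reads, the count with identity strictly
    above the cutoff, and that count as a fraction of the total.
    """
    if result.table.empty:
        raise ValueError("no recruited reads to summarize")
    band_labels = [_band_label(*b) for b in sorted(result.bands, reverse=True)]
    rows = []
    for genome_id, t in result.table.groupby("genome_id"):
        row: dict = {"genome_id": genome_id}
        for lbl in band_labels + [BELOW_RANGE]:
            row[lbl] = int((t["band"] == lbl).sum())
        row["total"] = len(t)
        n_above = int((t["identity"] > strain_identity_cutoff).sum())
        row[f"reads_gt_{strain_identity_cutoff:g}"] = n_above
        row[f"fraction_gt_{strain_identity_cutoff:g}"] = n_above / len(t)
        rows.append(row)
    return pd.DataFrame(rows)


def identity_summary(result: RecruitmentResult, min_reads: int = 100) -> pd.DataFrame:
    """Per-genome mean +/- sample SD of recruited identities.

    Only genomes with strictly more than ``min_reads`` recruited reads
    are reported.
    """
    rows = []
    for genome_id, t in result.table.groupby("genome_id"):
        if len(t) <= min_reads:
            continue
        rows.append({
            "genome_id": genome_id,
            "n_reads": len(t),
            "mean_identity": float(t["identity"].mean()),
            "sd_identity": float(t["identity"].std(ddof=1)) if len(t) > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["genome_id", "n_reads", "mean_identity", "sd_identity"])


def gc_track(
    pseudogenome: Pseudogenome, window: int = 10_000, step: int = 1_000
) -> pd.DataFrame:
    """Windowed GC deviation from the genome-wide mean GC.

    Windows start every ``step`` bp; the final window is allowed to be
    short so the last window end equals the total length. Columns:
    genome_id, start, end, gc_deviation (percentage points).
    """
    if window < step:
        raise ValueError("window must be >= step")
    L = pseudogenome.total_length
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    mean_gc = gc_percent(pseudogenome.seq)
    rows = []
    start = 0
    while start < L:
        end = min(start + window, L)
        rows.append({
            "genome_id": pseudogenome.genome_id,
            "start": start, "end": end,
            "gc_deviation": gc_percent(pseudogenome.seq[start:end]) - mean_gc,
        })
        if end == L:
            break
        start += step
    return pd.DataFrame(rows)
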