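"""Top-hit similarity search over a k-mer-seeded reference index.

This is the search contract the binning, annotation and recruitment
stages consume: queries are seeded by exact k-mer matches, candidate
references are aligned with the affine-gap local aligner, and the best
hit at or below the configured e-value is retained ("top hit"). The
same contract can be satisfied wholesale by externally computed
12-column tabular hits (``io_formats.read_tabular_hits``).

Ties on bit score are broken by lower e-value, then lexicographically
smallest subject id, so searches are deterministic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from . import _align
from .io_formats import HitRecord, SequenceRecord

__all__ = [
    "HitRecord",
    "SearchIndex",
    "build_index",
    "top_hit",
    "search_all",
    "six_frame_translate",
]


@dataclass
class SearchIndex:
    """Exact k-mer index over a reference collection."""

    references: list[SequenceRecord]
    k: int
    taxonomy: dict[str, tuple[str, str]]  # ref id -> (genus, superkingdom)
    alphabet: str
    kmers: dict[str, list[tuple[int, int]]] = field(repr=False, default_factory=dict)
    total_length: int = 0

    def reference_by_id(self, ref_id: str) -> SequenceRecord:
        for r in self.references:
            if r.id == ref_id:
                return r
        raise KeyError(ref_id)


def build_index(
    references: Sequence[SequenceRecord],
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
    k: int = 11,
) -> SearchIndex:
    """Index every k-mer of every reference to its (reference, position).

    ``k`` must be in [4, 16] for nucleotide references and [3, 6] for
    protein references. References are sorted by id so the index is
    independent of input order.
    """
    refs = sorted(references, key=lambda r: r.id)
    if not refs:
        raise ValueError("cannot build an index over an empty reference list")
    alphabets = {r.alphabet for r in refs}
    if len(alphabets) != 1:
        raise ValueError(f"mixed reference alphabets: {sorted(alphabets)}")
    alphabet = alphabets.pop()
    lo, hi = (4, 16) if alphabet == "nucleotide" else (3, 6)
    if not lo <= k <= hi:
        raise ValueError(f"seed length {k} outside [{lo}, {hi}] for {alphabet}")
    tax = dict(taxonomy) if taxonomy else {}
    kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ridx, ref in enumerate(refs):
        s = ref.seq
        for pos in range(len(s) - k + 1):
            kmers[s[pos:pos + k]].append((ridx, pos))
    return SearchIndex(
        references=refs, k=k, taxonomy=tax, alphabet=alphabet,
        kmers=dict(kmers), total_length=sum(len(r) for r in refs),
    )


def _candidate_windows(query: str, index: SearchIndex) -> dict[int, tuple[int, int]]:
    """Per-reference window (tstart, tend) implied by seed diagonals."""
    k = index.k
    span: dict[int, tuple[int, int]] = {}
    for qpos in range(len(query) - k + 1):
        for ridx, tpos in index.kmers.get(query[qpos:qpos + k], ()):
            diag_start = tpos - qpos
            lo, hi = span.get(ridx, (diag_start, diag_start))
            span[ridx] = (min(lo, diag_start), max(hi, diag_start))
    pad = len(query) // 4 + 16
    out = {}
    for ridx, (lo, hi) in span.items():
        ref_len = len(index.references[ridx])
        out[ridx] = (max(0, lo - pad), min(ref_len, hi + len(query) + pad))
    return out


def _align_candidate(
    query: SequenceRecord, index: SearchIndex, ridx: int, window: tuple[int, int]
) -> HitRecord | None:
    ref = index.references[ridx]
    wstart, wend = window
    # small references: align in full so the result equals the full-DP answer
    if len(ref) <= 2048:
        wstart, wend = 0, len(ref)
    aln = _align.smith_waterman(query.seq, ref.seq[wstart:wend], index.alphabet)
    if aln is None:
        return None
    e, bits = _align.evalue(aln.score, len(query), index.total_length, index.alphabet)
    genus, kingdom = index.taxonomy.get(ref.id, ("Unknown", "Unknown"))
    return HitRecord(
        query_id=query.id, subject_id=ref.id,
        percent_identity=round(aln.identity, 10),
        alignment_length=aln.length, mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        qstart=aln.qstart + 1, qend=aln.qend,
        sstart=wstart + aln.tstart + 1, send=wstart + aln.tend,
        e_value=e, bit_score=bits,
        subject_genus=genus, subject_superkingdom=kingdom,
    )


def search_all(
    query: SequenceRecord, index: SearchIndex, evalue_max: float = 1e-5
) -> list[HitRecord]:
    """Best hit per reference with e <= evalue_max, best-first.

    Nucleotide queries are searched in both orientations; a minus-strand
    hit is reported BLAST-style with sstart > send.
    """
    if query.alphabet != index.alphabet:
        raise ValueError(
            f"query alphabet {query.alphabet!r} does not match index "
            f"({index.alphabet!r})"
        )
    strands = [(query, False)]
    if index.alphabet == "nucleotide":
        strands.append((query.reverse_complement(), True))
    best: dict[str, HitRecord] = {}
    for q, is_rc in strands:
        for ridx, window in _candidate_windows(q.seq, index).items():
            hit = _align_candidate(q, index, ridx, window)
            if hit is None or hit.e_value > evalue_max:
                continue
            if is_rc:
                hit.sstart, hit.send = hit.send, hit.sstart
            prev = best.get(hit.subject_id)
            if prev is None or (hit.bit_score, -hit.e_value) > (prev.bit_score, -prev.e_value):
                best[hit.subject_id] = hit
    return sorted(best.values(), key=lambda h: (-h.bit_score, h.e_value, h.subject_id))


def top_hit(
    query: SequenceRecord, index: SearchIndex, evalue_max: float = 1e-5
) -> HitRecord | None:
    """The single best hit, or None when nothing attains e <= evalue_max."""
    hits = search_all(query, index, evalue_max)
    return hits[0] if hits else None


def six_frame_translate(query: SequenceRecord) -> list[SequenceRecord]:
    """Translate frames +1..+3 and -1..-3 with the standard code.

    Stop codons are rendered as ``*``. Frames shorter than one codon
    yield no record. Returned ids are ``<id>|frame=<+1..-3>``.
    """
    if query.alphabet != "nucleotide":
        raise ValueError("six-frame translation requires a nucleotide sequence")
    out: list[SequenceRecord] = []
    rc = str(Seq(query.seq).reverse_complement())
    for label, s in (("+", query.seq), ("-", rc)):
        for f in range(3):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            if not prot:
                continue
            out.append(SequenceRecord(
                id=f"{query.id}|frame={label}{f + 1}",
                seq=prot, alphabet="protein",
                description=f"translation of {query.id} frame {label}{f + 1}",
            ))
    return out
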