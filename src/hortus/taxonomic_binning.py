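"""Top-hit taxonomic binning and GC content tabulation.

Metagenome sequences are partitioned by the superkingdom of their best
similarity hit (queries with no retained hit fall into Unknown), genus
rank tables are built under sequence-count or nucleotide weighting,
rankings from different binning routes are compared side by side with a
rank correlation, and per-group GC histograms are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HitRecord, SequenceRecord, SUPERKINGDOMS

__all__ = [
    "assign_superkingdom",
    "tabulate_genus_bins",
    "tabulate_protein_bins",
    "compare_rankings",
    "gc_histogram",
    "gc_percent",
    "GcHistogram",
]


def assign_superkingdom(
    hits: Mapping[str, HitRecord | None],
) -> dict[str, str]:
    """Map each query to Bacterial / Eukaryotic / Viral / Unknown.

    ``hits`` holds at most one (best) hit per query; queries whose value
    is None — no hit at the configured e-value — go to Unknown, as do
    hits whose subject taxonomy is unresolvable. The partition is
    exhaustive and exclusive by construction.
    """
    out: dict[str, str] = {}
    for query, hit in hits.items():
        if query in out:
            raise ValueError(f"query {query!r} appears twice")
        out[query] = hit.subject_superkingdom if hit is not None else "Unknown"
    return out


def _rank_table(rows: list[dict], weight_col: str) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df = df.sort_values([weight_col, "genus"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    # flag ties on the ranking weight for the report
    df["tied"] = df.duplicated(weight_col, keep=False)
    return df.reset_index(drop=True)


def tabulate_genus_bins(
    hits: Mapping[str, HitRecord],
    lengths: Mapping[str, int],
    weight: str = "nucleotide",
) -> pd.DataFrame:
    """Genus rank table from best nucleotide hits.

    One row per genus with its taxonomic group (here the subject
    superkingdom), member sequence count, total nucleotides, and rank
    by the chosen weight (``nucleotide`` or ``sequence_count``),
    descending. Ties share consecutive order lexicographically and are
    flagged.
    """
    if not hits:
        raise ValueError("no hits to tabulate")
    if weight not in ("nucleotide", "sequence_count"):
        raise ValueError(f"unknown weight {weight!r}")
    acc: dict[str, dict] = {}
    for query, hit in hits.items():
        if query not in lengths:
            raise ValueError(f"no length for query {query!r}")
        a = acc.setdefault(hit.subject_genus, {
            "genus": hit.subject_genus, "group": hit.subject_superkingdom,
            "sequence_count": 0, "nucleotides": 0,
        })
        a["sequence_count"] += 1
        a["nucleotides"] += int(lengths[query])
    col = "nucleotides" if weight == "nucleotide" else "sequence_count"
    return _rank_table(list(acc.values()), col)


def tabulate_protein_bins(
    hits: Mapping[str, HitRecord],
    residue_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Genus rank table from best protein hits, weighted by coding nucleotides.

    Each protein's coding-region length is 3 x residues + 3 (stop codon
    included).
    """
    if not hits:
        raise ValueError("no hits to tabulate")
    coding = {}
    for query in hits:
        if query not in residue_counts:
            raise ValueError(f"no coding length for protein {query!r}")
        coding[query] = 3 * int(residue_counts[query]) + 3
    return tabulate_genus_bins(hits, coding, weight="nucleotide")


def compare_rankings(
    tables: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side genus ranks across binning methods.

    Returns (side-by-side table over the union of genera, with absent
    genera left missing; pairwise Spearman rank correlation over each
    method pair's shared genera). At least two tables sharing >= 3
    genera are required.
    """
    if len(tables) < 2:
        raise ValueError("need at least two rank tables to compare")
    ranks = {
        name: t.set_index("genus")["rank"]
        for name, t in tables.items()
    }
    side = pd.DataFrame(ranks)
    side.index.name = "genus"
    names = list(ranks)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = side[[a, b]].dropna()
            if len(shared) < 3:
                raise ValueError(
                    f"tables {a!r} and {b!r} share only {len(shared)} genera (< 3)"
                )
            rho = stats.spearmanr(shared[a], shared[b]).statistic
            rows.append({"table_a": a, "table_b": b,
                         "n_shared": len(shared), "spearman_rho": rho})
    return side.reset_index(), pd.DataFrame(rows)


def gc_percent(seq: str) -> float:
    """GC content in percent; ambiguous bases excluded from the denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * gc / denom


@dataclass
class GcHistogram:
    group: str
    edges: np.ndarray  # strictly increasing bin edges, percent GC
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group,
            "bin_low": self.edges[:-1],
            "bin_high": self.edges[1:],
            "count": self.counts,
        })


def gc_histogram(
    sequences: Sequence[SequenceRecord],
    groups: Mapping[str, str],
    bin_width: float = 1.0,
) -> list[GcHistogram]:
    """Per-group histogram of sequence GC percentages.

    ``groups`` maps sequence id -> group label; bins span [0, 100] at
    the requested width (default 1%, per-percentage tabulation). Counts
    in each histogram sum to the number of sequences in the group.
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    edges[-1] = 100.0
    by_group: dict[str, list[float]] = {}
    for rec in sequences:
        g = groups.get(rec.id)
        if g is None:
            continue
        by_group.setdefault(g, []).append(gc_percent(rec.seq))
    out = []
    for g in sorted(by_group):
        counts, _ = np.histogram(by_group[g], bins=edges)
        out.append(GcHistogram(group=g, edges=edges.copy(), counts=counts))
    return out
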