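"""Contact-level QC against a diploid truth reference.

Mirrors the idea of aligning proximity-ligation reads to a two-haplotype
assembly and asking how often both ends of a contact land on the same
haplotype.  Any two mappings of one read ID form an edge; edges are binned
by the minimum mapping quality of the pair, and an edge is *consistent*
when both reference contigs carry the same haplotype label.  The signal
ratio per bin is n_consistent / (n_consistent + n_inconsistent) — the
fraction of phase-informative contacts that agree with the known phasing.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field

import pandas as pd

from .contacts import ContactRecord

__all__ = [
    "DiploidTruth",
    "SignalRatioTable",
    "contact_stats",
    "signal_ratio",
    "read_truth_tsv",
]

logger = logging.getLogger(__name__)

MAX_MAPQ_BIN = 60


@dataclass
class DiploidTruth:
    """Haplotype label per reference contig (each labeled exactly once)."""

    labels: dict[str, str]

    def __post_init__(self):
        values = set(self.labels.values())
        if not values <= {"hap1", "hap2"}:
            raise ValueError(f"haplotype labels must be hap1/hap2, got {values}")


def read_truth_tsv(path) -> DiploidTruth:
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("contig"):
                continue
            contig, hap = line.split("\t")
            if contig in labels:
                raise ValueError(f"contig {contig!r} labeled twice")
            labels[contig] = hap
    return DiploidTruth(labels)


@dataclass
class SignalRatioTable:
    """Consistent/inconsistent contact counts per minimum-mapQ bin."""

    bins: dict[int, tuple[int, int]]  # bin -> (n_consistent, n_inconsistent)
    n_skipped: int = 0  # edges with an unlabeled contig

    def totals(self) -> tuple[int, int]:
        n_cons = sum(c for c, _ in self.bins.values())
        n_incons = sum(i for _, i in self.bins.values())
        return n_cons, n_incons

    def total_ratio(self) -> float:
        n_cons, n_incons = self.totals()
        denom = n_cons + n_incons
        return n_cons / denom if denom else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in sorted(self.bins):
            n_cons, n_incons = self.bins[b]
            denom = n_cons + n_incons
            rows.append(
                {
                    "min_mapq_bin": str(b),
                    "n_consistent": n_cons,
                    "n_inconsistent": n_incons,
                    "ratio": n_cons / denom if denom else float("nan"),
                }
            )
        n_cons, n_incons = self.totals()
        denom = n_cons + n_incons
        rows.append(
            {
                "min_mapq_bin": "total",
                "n_consistent": n_cons,
                "n_inconsistent": n_incons,
                "ratio": n_cons / denom if denom else float("nan"),
            }
        )
        return pd.DataFrame(rows)


def contact_stats(
    grouped: "OrderedDict[str, list[ContactRecord]]",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histograms of mappings-per-read and alignment length.

    Operates on post-filter records; empty input yields empty tables.
    Returns (per-read alignment-count table, alignment-length table).
    """
    per_read = Counter(len(records) for records in grouped.values())
    lengths = Counter(
        r.length for records in grouped.values() for r in records
    )
    count_df = pd.DataFrame(
        [
            {"alignments_per_read": k, "n_reads": v}
            for k, v in sorted(per_read.items())
        ]
    )
    length_df = pd.DataFrame(
        [
            {"alignment_length": k, "n_alignments": v}
            for k, v in sorted(lengths.items())
        ]
    )
    return count_df, length_df


def signal_ratio(
    grouped: "OrderedDict[str, list[ContactRecord]]", truth: DiploidTruth
) -> SignalRatioTable:
    """Per-mapQ-bin consistency of contacts with the diploid truth labels.

    Every unordered pair of mappings of one read is an edge, binned by the
    minimum mapping quality of the pair (integer bins, capped at 60).
    Consistency compares haplotype labels, so a global hap1<->hap2 swap
    leaves the table unchanged.  Edges touching an unlabeled contig are
    skipped and counted.
    """
    bins: dict[int, list[int]] = {}
    n_skipped = 0
    for records in grouped.values():
        for rec_a, rec_b in itertools.combinations(records, 2):
            hap_a = truth.labels.get(rec_a.segment)
            hap_b = truth.labels.get(rec_b.segment)
            if hap_a is None or hap_b is None:
                n_skipped += 1
                continue
            b = min(rec_a.mapq, rec_b.mapq, MAX_MAPQ_BIN)
            entry = bins.setdefault(b, [0, 0])
            entry[0 if hap_a == hap_b else 1] += 1
    if n_skipped:
        logger.warning("skipped %d edges touching unlabeled contigs", n_skipped)
    return SignalRatioTable(
        bins={b: (c, i) for b, (c, i) in bins.items()}, n_skipped=n_skipped
    )
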