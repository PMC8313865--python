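"""Enumerated STR-variant reference and read-to-histogram conversion.

Instead of aligning reads against a whole genome, reads from a targeted STR
panel are classified against an enumerated reference that contains, for
every locus, all plausible repeat-count variants (reference count +/- a
window).  Assigning a read to a variant is equivalent to measuring its
repeat length, so classification is implemented directly with flanking
k-mer anchors: a read maps to (locus, k) when both innermost flank anchors
are found and the spanned interior is a whole number of repeat units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .histogram import RepeatHistogram
from .panel import StrLocus

DEFAULT_ANCHOR_LENGTH = 15
DEFAULT_WINDOW = 10


@dataclass
class StrVariantReference:
    """Per-locus repeat-count variants plus flank k-mer anchors."""

    loci: dict[str, StrLocus]
    window: int
    anchor_length: int
    variants: dict[str, list[tuple[int, str]]]
    anchors: dict[str, tuple[str, str]]  # kmer -> (locus_id, side)
    ambiguous: set[str] = field(default_factory=set)

    def variant_counts(self, locus_id: str) -> list[int]:
        return [k for k, _ in self.variants[locus_id]]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for locus_id in sorted(self.variants):
                for count, seq in self.variants[locus_id]:
                    fh.write(f">{locus_id}|{count}\n{seq}\n")


def build_variant_reference(
    panel: list[StrLocus],
    window: int = DEFAULT_WINDOW,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> StrVariantReference:
    """Enumerate all repeat-count variants (floor 1 repeat) and index the
    innermost flank k-mers; anchors shared between loci are flagged
    ambiguous and excluded from classification."""
    variants: dict[str, list[tuple[int, str]]] = {}
    anchors: dict[str, tuple[str, str]] = {}
    ambiguous: set[str] = set()
    loci_by_id: dict[str, StrLocus] = {}
    for locus in panel:
        if len(locus.flank_left) < anchor_length or len(locus.flank_right) < anchor_length:
            raise ValueError(
                f"locus {locus.locus_id}: flanks shorter than anchor length "
                f"{anchor_length}"
            )
        loci_by_id[locus.locus_id] = locus
        lo = max(1, locus.ref_repeat_count - window)
        hi = locus.ref_repeat_count + window
        variants[locus.locus_id] = [
            (k, locus.flank_left + locus.unit * k + locus.flank_right)
            for k in range(lo, hi + 1)
        ]
        left = locus.flank_left[-anchor_length:]
        right = locus.flank_right[:anchor_length]
        for kmer, side in ((left, "left"), (right, "right")):
            if kmer in anchors and anchors[kmer][0] != locus.locus_id:
                ambiguous.add(kmer)
            else:
                anchors[kmer] = (locus.locus_id, side)
    for kmer in ambiguous:
        anchors.pop(kmer, None)
    return StrVariantReference(
        loci=loci_by_id,
        window=window,
        anchor_length=anchor_length,
        variants=variants,
        anchors=anchors,
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class ReadClassification:
    locus_id: str | None
    repeat_length: int | None
    reason: str = "ok"

    @property
    def mapped(self) -> bool:
        return self.locus_id is not None


def _find_with_mismatch(read: str, kmer: str, max_mismatch: int) -> int | None:
    k = len(kmer)
    for i in range(len(read) - k + 1):
        mism = 0
        for a, b in zip(read[i : i + k], kmer):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return None


def classify_read(
    read: str, ref: StrVariantReference, allow_mismatch: bool = True
) -> ReadClassification:
    """Locate left and right flank anchors and measure the repeat length.

    Exact k-mer lookup first; optionally a one-mismatch scan as fallback.
    The inter-anchor span must be a whole, in-phase number of repeat units,
    otherwise the read is reported unmapped with a reason.
    """
    k = ref.anchor_length
    hits: dict[tuple[str, str], int] = {}
    for i in range(len(read) - k + 1):
        hit = ref.anchors.get(read[i : i + k])
        if hit is not None and hit not in hits:
            hits[hit] = i
    locus_id = None
    for (lid, side), _pos in hits.items():
        if (lid, "left") in hits and (lid, "right") in hits:
            locus_id = lid
            break
    if locus_id is None and allow_mismatch:
        # fallback: one-mismatch scan against each locus with a partial hit,
        # then against all loci
        candidates = {lid for (lid, _s) in hits} or set(ref.loci)
        for lid in sorted(candidates):
            locus = ref.loci[lid]
            left = locus.flank_left[-k:]
            right = locus.flank_right[:k]
            i = _find_with_mismatch(read, left, 1)
            j = _find_with_mismatch(read, right, 1)
            if i is not None and j is not None:
                hits[(lid, "left")] = i
                hits[(lid, "right")] = j
                locus_id = lid
                break
    if locus_id is None:
        return ReadClassification(None, None, "no anchor pair")
    locus = ref.loci[locus_id]
    i = hits[(locus_id, "left")]
    j = hits[(locus_id, "right")]
    span = read[i + k : j]
    unit = locus.unit
    if j <= i + k or len(span) % len(unit) != 0:
        return ReadClassification(None, None, "span not unit-periodic")
    n = len(span) // len(unit)
    if unit * n != span:
        return ReadClassification(None, None, "span not unit-periodic")
    return ReadClassification(locus_id, n)


@dataclass
class MappingReport:
    total: dict[str, int] = field(default_factory=dict)
    mapped: dict[str, int] = field(default_factory=dict)

    def mapped_fraction(self, cell_id: str) -> float:
        t = self.total.get(cell_id, 0)
        return self.mapped.get(cell_id, 0) / t if t else 0.0


def build_histograms(
    reads: "str | Path | list[tuple[str, str]]",
    ref: StrVariantReference,
    allow_mismatch: bool = True,
) -> tuple[list[RepeatHistogram], MappingReport]:
    """Aggregate read classifications into per cell-locus histograms.

    ``reads`` is a FASTQ path or an iterable of ``(read_name, sequence)``;
    the cell id is the read-name prefix before the first ``:``.
    """
    if isinstance(reads, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(reads), "fastq")]
    else:
        records = list(reads)
    acc: dict[tuple[str, str], dict[int, int]] = {}
    report = MappingReport()
    for name, seq in records:
        cell_id = name.split(":", 1)[0]
        report.total[cell_id] = report.total.get(cell_id, 0) + 1
        result = classify_read(seq, ref, allow_mismatch=allow_mismatch)
        if not result.mapped:
            continue
        report.mapped[cell_id] = report.mapped.get(cell_id, 0) + 1
        key = (cell_id, result.locus_id)
        bins = acc.setdefault(key, {})
        bins[result.repeat_length] = bins.get(result.repeat_length, 0) + 1
    histograms = [
        RepeatHistogram(cell_id=c, locus_id=l, counts=bins)
        for (c, l), bins in sorted(acc.items())
    ]
    return histograms, report


def write_reads_fastq(
    histograms: list[RepeatHistogram],
    loci: list[StrLocus],
    path: str | Path,
) -> int:
    """Materialize histograms as merged single-end reads (inverse of
    :func:`build_histograms` for simulated data). Returns the read count."""
    by_id = {l.locus_id: l for l in loci}
    n = 0
    with open(path, "w") as fh:
        for h in histograms:
            locus = by_id[h.locus_id]
            for length, count in sorted(h.counts.items()):
                seq = locus.flank_left + locus.unit * length + locus.flank_right
                for _ in range(count):
                    fh.write(f"@{h.cell_id}:{h.locus_id}:{n}\n{seq}\n+\n{'I' * len(seq)}\n")
                    n += 1
    return n


def subsample_histograms(
    histograms: list[RepeatHistogram],
    target_coverage: int | None = None,
    fraction: float | None = None,
    seed: np.random.Generator | int | None = None,
) -> list[RepeatHistogram]:
    """Downsample reads per cell-locus without replacement.

    Exactly one of ``target_coverage`` / ``fraction`` must be given.  A
    target larger than the available reads leaves the histogram unchanged.
    """
    if (target_coverage is None) == (fraction is None):
        raise ValueError("give exactly one of target_coverage or fraction")
    if fraction is not None and not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for h in histograms:
        total = h.total
        target = (
            int(round(fraction * total)) if fraction is not None else target_coverage
        )
        if target >= total:
            out.append(RepeatHistogram(h.cell_id, h.locus_id, dict(h.counts)))
            continue
        lengths = sorted(h.counts)
        counts = np.array([h.counts[l] for l in lengths])
        drawn = rng.multivariate_hypergeometric(counts, target)
        out.append(
            RepeatHistogram(
                h.cell_id,
                h.locus_id,
                {l: int(c) for l, c in zip(lengths, drawn) if c > 0},
            )
        )
    return out
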