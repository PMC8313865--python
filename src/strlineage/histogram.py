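"""Per cell-locus repeat-length read histograms and their TSV format."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RepeatHistogram:
    """Read counts per repeat length for one (cell, locus) combination."""

    cell_id: str
    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.counts.items():
            if length < 1 or count < 0:
                raise ValueError(
                    f"invalid histogram bin {length}:{count} "
                    f"for {self.cell_id}/{self.locus_id}"
                )
        # drop empty bins for a canonical representation
        self.counts = {k: v for k, v in sorted(self.counts.items()) if v > 0}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def support(self) -> tuple[int, int] | None:
        """(min, max) repeat length with nonzero reads, or None if empty."""
        if not self.counts:
            return None
        keys = self.counts.keys()
        return min(keys), max(keys)

    def normalized(self) -> dict[int, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}


HISTOGRAM_COLUMNS = ["cell_id", "locus_id", "repeat_length", "read_count"]


def write_histograms_tsv(
    histograms: list[RepeatHistogram], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(HISTOGRAM_COLUMNS)
        for h in histograms:
            for length, count in sorted(h.counts.items()):
                writer.writerow([h.cell_id, h.locus_id, length, count])


def read_histograms_tsv(path: str | Path) -> list[RepeatHistogram]:
    acc: dict[tuple[str, str], dict[int, int]] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["cell_id"], row["locus_id"])
            if key not in acc:
                acc[key] = {}
                order.append(key)
            length = int(row["repeat_length"])
            acc[key][length] = acc[key].get(length, 0) + int(row["read_count"])
    return [
        RepeatHistogram(cell_id=c, locus_id=l, counts=acc[(c, l)]) for c, l in order
    ]
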