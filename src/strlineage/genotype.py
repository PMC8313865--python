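"""Stutter-aware genotype calling and genotype-matrix assembly.

A repeat-length read histogram is genotyped by comparing it against the
stutter model's predicted distribution for every candidate genotype
(mono-allelic alleles within the observed support +/- 2, and biallelic
pairs at equal mixture).  The score is the Pearson correlation between the
normalized observed histogram and the prediction over the union of their
supports (zero bins included); a call is emitted only when the histogram
has at least ``min_coverage`` reads (default 10) and the best correlation
reaches ``1 - confidence_threshold`` (default 0.95).

Biallelic loci are subsequently split into two mono-allelic pseudo-loci
using a population-wide largest-gap clustering of the called alleles;
loci whose allele clusters are separated by three repeat units or fewer
are kept as a single low-heterogeneity column (lower allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .histogram import RepeatHistogram
from .stutter import StutterModel, predict_histogram

DEFAULT_MIN_COVERAGE = 10
DEFAULT_CONFIDENCE_THRESHOLD = 0.05
DEFAULT_BIALLELIC_MARGIN = 0.01
DEFAULT_CANDIDATE_PAD = 2
DEFAULT_MIN_SEPARATION = 3


@dataclass(frozen=True)
class GenotypeCall:
    cell_id: str
    locus_id: str
    alleles: tuple[int, ...]
    confidence: float  # 1 - correlation, in [0, 1]
    coverage: int

    def __post_init__(self) -> None:
        if len(self.alleles) == 2 and not self.alleles[0] < self.alleles[1]:
            raise ValueError("biallelic calls must have allele1 < allele2")


class GenotypeCaller:
    """Histogram genotyper for a fixed stutter model.

    Predicted distributions are cached per (unit, allele), which makes
    calling hundreds of thousands of histograms cheap.
    """

    def __init__(
        self,
        model: StutterModel,
        min_coverage: int = DEFAULT_MIN_COVERAGE,
        confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
        biallelic_margin: float = DEFAULT_BIALLELIC_MARGIN,
        candidate_pad: int = DEFAULT_CANDIDATE_PAD,
        support_eps: float = 1e-9,
        max_candidate_span: int = 30,
    ) -> None:
        self.model = model
        self.min_coverage = min_coverage
        self.confidence_threshold = confidence_threshold
        self.biallelic_margin = biallelic_margin
        self.candidate_pad = candidate_pad
        self.support_eps = support_eps
        self.max_candidate_span = max_candidate_span
        self._pred_cache: dict[tuple[str, int], np.ndarray] = {}
        self._bounds_cache: dict[tuple[str, int], tuple[int, int]] = {}

    # -- predictions -------------------------------------------------------
    def _pred(self, unit: str, allele: int) -> np.ndarray:
        """Predicted probabilities over repeat lengths 1..allele+cycles."""
        key = (unit, allele)
        if key not in self._pred_cache:
            self._pred_cache[key] = predict_histogram(
                self.model, allele, unit
            ).probabilities
        return self._pred_cache[key]

    def _pred_window(
        self, unit: str, alleles: tuple[int, ...], lo: int, hi: int
    ) -> np.ndarray:
        """Prediction for a (possibly biallelic) genotype on lengths lo..hi."""
        out = np.zeros(hi - lo + 1)
        for a in alleles:
            p = self._pred(unit, a)
            src_lo = max(lo, 1)
            src_hi = min(hi, p.size)
            if src_hi >= src_lo:
                out[src_lo - lo : src_hi - lo + 1] += p[src_lo - 1 : src_hi]
        return out / len(alleles)

    def _support_bounds(self, unit: str, alleles: tuple[int, ...]) -> tuple[int, int]:
        lo, hi = None, None
        for a in alleles:
            key = (unit, a)
            if key not in self._bounds_cache:
                p = self._pred(unit, a)
                nz = np.nonzero(p > self.support_eps)[0]
                self._bounds_cache[key] = (int(nz[0]) + 1, int(nz[-1]) + 1)
            alo, ahi = self._bounds_cache[key]
            lo = alo if lo is None else min(lo, alo)
            hi = ahi if hi is None else max(hi, ahi)
        return lo, hi

    # -- scoring -------------------------------------------------------------
    def score_candidates(
        self, h: RepeatHistogram, unit: str = "AC"
    ) -> list[tuple[tuple[int, ...], float]]:
        """Pearson correlation for every candidate genotype (diagnostics)."""
        if h.total == 0:
            return []
        lo_o, hi_o = h.support
        lo_c = max(1, lo_o - self.candidate_pad)
        hi_c = hi_o + self.candidate_pad
        if hi_c - lo_c + 1 > self.max_candidate_span:
            hi_c = lo_c + self.max_candidate_span - 1
        monos = [(a,) for a in range(lo_c, hi_c + 1)]
        pairs = [tuple(p) for p in combinations(range(lo_c, hi_c + 1), 2)]
        candidates = monos + pairs

        # candidate-specific union-of-supports windows, evaluated jointly on
        # a common axis with a mask
        bounds = [self._support_bounds(unit, c) for c in candidates]
        windows = [
            (min(lo_o, blo), max(hi_o, bhi)) for blo, bhi in bounds
        ]
        glo = min(w[0] for w in windows)
        ghi = max(w[1] for w in windows)
        width = ghi - glo + 1
        axis = np.arange(glo, ghi + 1)

        x = np.zeros(width)
        total = h.total
        for length, count in h.counts.items():
            x[length - glo] = count / total

        m = len(candidates)
        preds = np.zeros((m, width))
        mask = np.zeros((m, width), dtype=bool)
        for i, (cand, (wlo, whi)) in enumerate(zip(candidates, windows)):
            preds[i] = self._pred_window(unit, cand, glo, ghi)
            mask[i, wlo - glo : whi - glo + 1] = True

        r = _masked_pearson(x, preds, mask)
        return [(cand, float(ri)) for cand, ri in zip(candidates, r)]

    def call(
        self, h: RepeatHistogram, unit: str = "AC"
    ) -> GenotypeCall | None:
        """Best-scoring genotype call, or ``None`` (no-call)."""
        if h.total < self.min_coverage:
            return None
        scored = self.score_candidates(h, unit)
        if not scored:
            return None
        best_mono = max(
            ((c, r) for c, r in scored if len(c) == 1), key=lambda t: t[1]
        )
        biallelic = [(c, r) for c, r in scored if len(c) == 2]
        best = best_mono
        if biallelic:
            best_bi = max(biallelic, key=lambda t: t[1])
            if best_bi[1] > best_mono[1] + self.biallelic_margin:
                best = best_bi
        alleles, corr = best
        if corr < 1.0 - self.confidence_threshold:
            return None
        confidence = min(max(1.0 - corr, 0.0), 1.0)
        return GenotypeCall(
            cell_id=h.cell_id,
            locus_id=h.locus_id,
            alleles=alleles,
            confidence=confidence,
            coverage=h.total,
        )


def _masked_pearson(x: np.ndarray, preds: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of ``x`` vs ``preds`` over ``mask``.

    Degenerate rows (zero variance on either side) score 1.0 when the two
    vectors coincide on the window and 0.0 otherwise.
    """
    cnt = mask.sum(axis=1)
    xm = np.where(mask, x[None, :], 0.0)
    pm = np.where(mask, preds, 0.0)
    sx = xm.sum(axis=1)
    sy = pm.sum(axis=1)
    sxx = (xm * xm).sum(axis=1)
    syy = (pm * pm).sum(axis=1)
    sxy = (xm * pm).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / cnt
        vx = sxx - sx * sx / cnt
        vy = syy - sy * sy / cnt
        r = cov / np.sqrt(vx * vy)
    identical = np.abs(xm - pm).max(axis=1) < 1e-12
    degenerate = (vx <= 1e-18) | (vy <= 1e-18) | ~np.isfinite(r)
    r = np.where(degenerate, np.where(identical, 1.0, 0.0), r)
    return np.clip(r, -1.0, 1.0)


def call_locus(
    h: RepeatHistogram,
    model: StutterModel,
    unit: str = "AC",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    **kwargs,
) -> GenotypeCall | None:
    """One-shot convenience wrapper around :class:`GenotypeCaller`."""
    caller = GenotypeCaller(
        model,
        min_coverage=min_coverage,
        confidence_threshold=confidence_threshold,
        **kwargs,
    )
    return caller.call(h, unit)


def call_histograms(
    histograms: list[RepeatHistogram],
    caller: GenotypeCaller,
    units: dict[str, str] | str = "AC",
) -> list[GenotypeCall]:
    """Call every histogram; ``units`` maps locus_id to its repeat unit."""
    calls = []
    for h in histograms:
        unit = units if isinstance(units, str) else units[h.locus_id]
        call = caller.call(h, unit)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyReport:
    n_cells: int = 0
    n_loci: int = 0
    n_calls: int = 0
    call_rate: float = 0.0
    low_heterogeneity: list[str] = field(default_factory=list)
    conflicts: int = 0
    per_cell_call_rate: dict[str, float] = field(default_factory=dict)


def split_biallelic(
    calls: list[GenotypeCall],
    min_separation: int = DEFAULT_MIN_SEPARATION,
    cells: list[str] | None = None,
    keep_low_heterogeneity: bool = True,
) -> tuple[pd.DataFrame, AssemblyReport]:
    """Assemble the mono-allelic pseudo-locus matrix from genotype calls.

    Loci with any biallelic call are split population-wide: pooled allele
    values are partitioned into two clusters at the largest gap.  If the
    cluster centers are separated by more than ``min_separation`` repeat
    units the locus becomes two pseudo-locus columns (``<locus>/1`` and
    ``<locus>/2``, each cell's alleles assigned to the nearer center);
    otherwise it stays a single column holding the lower allele per cell
    (flagged low-heterogeneity, and dropped entirely when
    ``keep_low_heterogeneity`` is false).
    """
    by_locus: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        by_locus.setdefault(c.locus_id, []).append(c)
    if cells is None:
        cells = sorted({c.cell_id for c in calls})
    report = AssemblyReport(n_cells=len(cells))
    columns: dict[str, dict[str, float]] = {}

    for locus_id in sorted(by_locus):
        locus_calls = by_locus[locus_id]
        has_biallelic = any(len(c.alleles) == 2 for c in locus_calls)
        if not has_biallelic:
            columns[locus_id] = {c.cell_id: float(c.alleles[0]) for c in locus_calls}
            continue
        pooled = np.array(sorted(a for c in locus_calls for a in c.alleles), dtype=float)
        uniq = np.unique(pooled)
        if uniq.size < 2:
            columns[locus_id] = {
                c.cell_id: float(min(c.alleles)) for c in locus_calls
            }
            report.low_heterogeneity.append(locus_id)
            continue
        gaps = np.diff(uniq)
        cut = int(np.argmax(gaps))  # split between uniq[cut] and uniq[cut+1]
        low_center = pooled[pooled <= uniq[cut]].mean()
        high_center = pooled[pooled > uniq[cut]].mean()
        separation = high_center - low_center
        if separation > min_separation:
            col1: dict[str, float] = {}
            col2: dict[str, float] = {}
            for c in locus_calls:
                assigned: dict[int, list[int]] = {0: [], 1: []}
                for a in c.alleles:
                    nearer = 0 if abs(a - low_center) <= abs(a - high_center) else 1
                    assigned[nearer].append(a)
                if len(c.alleles) == 2 and (not assigned[0] or not assigned[1]):
                    report.conflicts += 1  # both alleles nearer one center
                    continue
                if assigned[0]:
                    col1[c.cell_id] = float(assigned[0][0])
                if assigned[1]:
                    col2[c.cell_id] = float(assigned[1][0])
            columns[f"{locus_id}/1"] = col1
            columns[f"{locus_id}/2"] = col2
        else:
            report.low_heterogeneity.append(locus_id)
            if keep_low_heterogeneity:
                columns[locus_id] = {
                    c.cell_id: float(min(c.alleles)) for c in locus_calls
                }

    matrix = pd.DataFrame(
        {name: pd.Series(columns[name], dtype=float) for name in sorted(columns)},
        index=pd.Index(cells, name="cell_id"),
    )
    if not columns:
        matrix = pd.DataFrame(index=pd.Index(cells, name="cell_id"), dtype=float)
    report.n_loci = matrix.shape[1]
    total = matrix.size
    report.n_calls = int(matrix.notna().to_numpy().sum())
    report.call_rate = report.n_calls / total if total else 0.0
    report.per_cell_call_rate = {
        cell: float(matrix.loc[cell].notna().mean()) if matrix.shape[1] else 0.0
        for cell in matrix.index
    }
    return matrix, report


def assemble_matrix(
    calls: list[GenotypeCall],
    cells: list[str] | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    keep_low_heterogeneity: bool = True,
) -> tuple[pd.DataFrame, AssemblyReport]:
    """Cells x pseudo-loci matrix with explicit missing values."""
    return split_biallelic(
        calls,
        min_separation=min_separation,
        cells=cells,
        keep_low_heterogeneity=keep_low_heterogeneity,
    )


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="cell_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id", na_values="NA")


def write_calls_tsv(calls: list[GenotypeCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tlocus_id\talleles\tconfidence\tcoverage\n")
        for c in calls:
            alleles = ",".join(str(a) for a in c.alleles)
            fh.write(f"{c.cell_id}\t{c.locus_id}\t{alleles}\t{c.confidence:.6g}\t{c.coverage}\n")
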