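"""Design of targeted STR panels and duplex-MIP precursor oligos.

A duplex molecular inversion probe (MIP) is synthesized as a ~150 nt
precursor carrying two universal PCR adapters that each embed an MlyI
recognition site.  MlyI digestion (GAGTC(N5), blunt) releases the active
probe: two locus-specific targeting arms flanking a constant backbone with
two 3-nt randomized UMIs.  This module implements the locus-selection
filters, a documented arm-picking heuristic, precursor assembly with the
printed adapter/backbone constants, and an in-silico MlyI digestion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .dna import (
    find_motif,
    gc_fraction,
    is_dna,
    is_primitive,
    max_homopolymer,
    minimal_rotation,
    revcomp,
    wallace_tm,
)

# Universal adapter / linker constants of the precursor design.
MLY1_F = "GTCTATGAGTGTGGAGTCGTTGC"
MLY1_R = "CTAGCTTCCTGATGAGTCCGATG"
BACKBONE = "AGATCGGAAGAGCACACGTCTGAACTCTTTCCCTACACGACGCTCTTCCGATCT"
UMI_LENGTH = 3
MAX_PRECURSOR_LENGTH = 150

MLYI_SITE = "GAGTC"           # forward-strand recognition
MLYI_SITE_RC = "GACTC"        # recognition on the opposite strand
MLYI_CUT_OFFSET = 5           # blunt cut 5 nt downstream of the site

# Hyper-mutability selection thresholds: di-nucleotide repeats must exceed
# 10 repeat units, mono-nucleotide repeats must exceed 6 ("longer than" is
# strict in both cases).
DI_UNITS = frozenset({"AC", "AG"})
MONO_UNITS = frozenset({"A", "G"})
MIN_DI_REPEATS = 10
MIN_MONO_REPEATS = 6


class PanelDesignError(ValueError):
    """A locus or precursor violates a design rule."""


@dataclass(frozen=True)
class StrLocus:
    """One targeted STR locus (0-based half-open genomic coordinates)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    ref_repeat_count: int
    flank_left: str = ""
    flank_right: str = ""

    def __post_init__(self) -> None:
        if not is_dna(self.unit):
            raise PanelDesignError(
                f"locus {self.locus_id}: malformed repeat unit {self.unit!r}"
            )
        if not is_primitive(self.unit):
            raise PanelDesignError(
                f"locus {self.locus_id}: unit {self.unit!r} is not primitive"
            )
        if self.ref_repeat_count < 1:
            raise PanelDesignError(
                f"locus {self.locus_id}: ref_repeat_count must be >= 1"
            )
        if self.end - self.start != len(self.unit) * self.ref_repeat_count:
            raise PanelDesignError(
                f"locus {self.locus_id}: interval length "
                f"{self.end - self.start} != unit x repeat count"
            )

    @property
    def repeat_sequence(self) -> str:
        return self.unit * self.ref_repeat_count

    def region_sequence(self) -> str:
        """flank_left + repeats + flank_right."""
        return self.flank_left + self.repeat_sequence + self.flank_right


def normalize_unit(unit: str, unify_revcomp: bool = True) -> str:
    """Canonical repeat unit: minimal rotation, optionally unified with the
    reverse-complement strand (GT -> AC, CT -> AG, T -> A, C -> G).

    When both strand representations are candidates, the one belonging to a
    recognized selection class (AC, AG, A, G) is preferred, falling back to
    the lexicographically smaller rotation.
    """
    u = minimal_rotation(unit)
    if not unify_revcomp:
        return u
    u_rc = minimal_rotation(revcomp(unit))
    known = DI_UNITS | MONO_UNITS
    for candidate in sorted((u, u_rc)):
        if candidate in known:
            return candidate
    return min(u, u_rc)


def is_hypermutable(locus: StrLocus, unify_revcomp: bool = True) -> bool:
    unit = normalize_unit(locus.unit, unify_revcomp=unify_revcomp)
    if unit in DI_UNITS:
        return locus.ref_repeat_count > MIN_DI_REPEATS
    if unit in MONO_UNITS:
        return locus.ref_repeat_count > MIN_MONO_REPEATS
    return False


def select_hypermutable_loci(
    loci: list[StrLocus], unify_revcomp: bool = True
) -> list[StrLocus]:
    """Keep AC/AG-type loci with > 10 repeats and A/G-type loci with > 6
    repeats; all other unit types are dropped."""
    return [l for l in loci if is_hypermutable(l, unify_revcomp=unify_revcomp)]


@dataclass(frozen=True)
class AmpliconCheck:
    ok: bool
    reasons: tuple[str, ...] = ()


def check_amplicon(
    sequence: str, target_length: int = 150, tol: int = 30
) -> AmpliconCheck:
    """Target amplicons must be ~150 bp and must not contain TTAA
    (incompatible with the Ampli1 WGA chemistry)."""
    if not is_dna(sequence, allow_n=True):
        raise PanelDesignError("amplicon contains non-ACGTN characters")
    reasons = []
    if "TTAA" in sequence:
        reasons.append("TTAA")
    if not (target_length - tol <= len(sequence) <= target_length + tol):
        reasons.append("length")
    return AmpliconCheck(ok=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class MipPrecursor:
    locus_id: str
    fw_arm: str
    rv_arm: str
    full_sequence: str
    active_sequence: str


def _expected_mlyi_positions(length: int) -> tuple[set[int], set[int]]:
    """Whitelisted recognition positions inside the two adapters."""
    fwd = {MLY1_F.index(MLYI_SITE)}
    rc_adapter = revcomp(MLY1_R)
    rev = {length - len(rc_adapter) + rc_adapter.index(MLYI_SITE_RC)}
    return fwd, rev


def assemble_precursor(
    locus_id: str, fw_arm: str, rv_arm: str, umi_length: int = UMI_LENGTH
) -> MipPrecursor:
    """Assemble a precursor in the fixed element order

    5'-[Mly1_F][FW arm][UMI][Backbone][UMI][revcomp RV arm][revcomp Mly1_R]-3'

    and reject any precursor longer than 150 nt or harboring an MlyI
    recognition site beyond the two adapter-internal ones.
    """
    for name, arm in (("fw_arm", fw_arm), ("rv_arm", rv_arm)):
        if not is_dna(arm):
            raise PanelDesignError(f"{locus_id}: {name} is not valid DNA")
        if find_motif(arm, MLYI_SITE) or find_motif(arm, MLYI_SITE_RC):
            raise PanelDesignError(
                f"{locus_id}: {name} contains an MlyI recognition site"
            )
    umi = "N" * umi_length
    full = MLY1_F + fw_arm + umi + BACKBONE + umi + revcomp(rv_arm) + revcomp(MLY1_R)
    if len(full) > MAX_PRECURSOR_LENGTH:
        raise PanelDesignError(
            f"{locus_id}: precursor length {len(full)} exceeds "
            f"{MAX_PRECURSOR_LENGTH} nt"
        )
    fwd_exp, rev_exp = _expected_mlyi_positions(len(full))
    fwd_hits = set(find_motif(full, MLYI_SITE))
    rev_hits = set(find_motif(full, MLYI_SITE_RC))
    if fwd_hits != fwd_exp or rev_hits != rev_exp:
        extra = sorted((fwd_hits - fwd_exp) | (rev_hits - rev_exp))
        raise PanelDesignError(
            f"{locus_id}: unexpected MlyI recognition site(s) at {extra}"
        )
    active = _digest(full)
    return MipPrecursor(
        locus_id=locus_id,
        fw_arm=fw_arm,
        rv_arm=rv_arm,
        full_sequence=full,
        active_sequence=active,
    )


def _digest(full: str) -> str:
    """Simulated MlyI digestion of a precursor.

    MlyI cuts blunt 5 nt downstream of GAGTC.  The forward adapter carries
    GAGTC reading inward, the reverse adapter carries GACTC (the site on the
    bottom strand), so the two cuts excise exactly the two 23-nt adapters.
    """
    fwd = find_motif(full, MLYI_SITE)
    rev = find_motif(full, MLYI_SITE_RC)
    if not full.startswith(MLY1_F) or not full.endswith(revcomp(MLY1_R)):
        raise PanelDesignError("precursor lacks the adapter constants")
    left_cut = fwd[0] + len(MLYI_SITE) + MLYI_CUT_OFFSET
    right_cut = rev[-1] - MLYI_CUT_OFFSET
    return full[left_cut:right_cut]


def digest_precursor(p: MipPrecursor) -> str:
    """Active MIP released by MlyI digestion (~105 nt for a 150-nt precursor)."""
    return _digest(p.full_sequence)


# ---------------------------------------------------------------------------
# Arm selection heuristic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmCriteria:
    """Primer-arm acceptance band.

    A deliberately simple, fully documented stand-in for thermodynamic
    primer scoring: length 18-25 nt, GC fraction 30-70%, no homopolymer of
    5+, Wallace-rule Tm within [48, 72] C, and no MlyI site.
    """

    min_length: int = 18
    max_length: int = 25
    min_gc: float = 0.30
    max_gc: float = 0.70
    max_homopolymer: int = 4
    min_tm: float = 48.0
    max_tm: float = 72.0

    def accepts(self, arm: str) -> bool:
        return (
            self.min_length <= len(arm) <= self.max_length
            and self.min_gc <= gc_fraction(arm) <= self.max_gc
            and max_homopolymer(arm) <= self.max_homopolymer
            and self.min_tm <= wallace_tm(arm) <= self.max_tm
            and not find_motif(arm, MLYI_SITE)
            and not find_motif(arm, MLYI_SITE_RC)
        )


def _fixed_overhead(umi_length: int = UMI_LENGTH) -> int:
    return len(MLY1_F) + len(MLY1_R) + len(BACKBONE) + 2 * umi_length


def design_arms(
    locus: StrLocus,
    criteria: ArmCriteria | None = None,
    amplicon_target: int = 150,
) -> tuple[str, str, str] | None:
    """Pick targeting arms from the locus flanks.

    Arms are sliding windows inside the flanks.  The captured amplicon runs
    from the outer end of the forward arm, across the repeat, to the outer
    end of the reverse arm, so the window offsets control the amplicon
    length; among pairs passing the criteria and the combined length budget
    the pair whose amplicon is closest to ``amplicon_target`` (shorter arms
    on ties) is returned, or ``None`` if no pair qualifies.
    """
    criteria = criteria or ArmCriteria()
    budget = MAX_PRECURSOR_LENGTH - _fixed_overhead()
    repeat_len = len(locus.unit) * locus.ref_repeat_count

    def candidates(flank: str, side: str) -> dict[int, str]:
        """Best passing arm per amplicon extent into this flank."""
        by_extent: dict[int, str] = {}
        for length in range(criteria.min_length, criteria.max_length + 1):
            for offset in range(0, len(flank) - length + 1):
                window = flank[offset : offset + length]
                # extent of the captured region into this flank
                extent = len(flank) - offset if side == "left" else offset + length
                if extent in by_extent and len(by_extent[extent]) <= length:
                    continue
                if criteria.accepts(window):
                    by_extent[extent] = window
        return by_extent

    fw_opts = candidates(locus.flank_left, "left")
    rv_opts = candidates(locus.flank_right, "right")
    best = None
    for fw_extent, fw in fw_opts.items():
        for rv_extent, rv in rv_opts.items():
            if len(fw) + len(rv) > budget:
                continue
            amplicon_len = fw_extent + repeat_len + rv_extent
            key = (abs(amplicon_len - amplicon_target), len(fw) + len(rv), fw, rv)
            if best is None or key < best[0]:
                best = (key, fw, rv, fw_extent, rv_extent)
    if best is None:
        return None
    _, fw, rv, fw_extent, rv_extent = best
    amplicon = (
        locus.flank_left[len(locus.flank_left) - fw_extent :]
        + locus.repeat_sequence
        + locus.flank_right[:rv_extent]
    )
    return fw, rv, amplicon


@dataclass
class PanelDesign:
    precursors: list[MipPrecursor] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)


def design_panel(
    loci: list[StrLocus],
    criteria: ArmCriteria | None = None,
    amplicon_tol: int = 30,
    unify_revcomp: bool = True,
) -> PanelDesign:
    """Full panel design: hypermutability filter, amplicon checks, arm
    selection, precursor assembly."""
    design = PanelDesign()
    for locus in loci:
        if not is_hypermutable(locus, unify_revcomp=unify_revcomp):
            design.rejected[locus.locus_id] = "not hyper-mutable"
            continue
        arms = design_arms(locus, criteria)
        if arms is None:
            design.rejected[locus.locus_id] = "no acceptable arms"
            continue
        fw, rv, amplicon = arms
        check = check_amplicon(amplicon, tol=amplicon_tol)
        if not check.ok:
            design.rejected[locus.locus_id] = "amplicon: " + ",".join(check.reasons)
            continue
        try:
            design.precursors.append(assemble_precursor(locus.locus_id, fw, rv))
        except PanelDesignError as exc:
            design.rejected[locus.locus_id] = str(exc)
    return design


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

LOCI_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "unit",
    "ref_repeat_count",
    "flank_left",
    "flank_right",
]


def read_loci_tsv(path: str | Path) -> list[StrLocus]:
    loci = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            loci.append(
                StrLocus(
                    locus_id=row["locus_id"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    unit=row["unit"],
                    ref_repeat_count=int(row["ref_repeat_count"]),
                    flank_left=row.get("flank_left", ""),
                    flank_right=row.get("flank_right", ""),
                )
            )
    return loci


def write_loci_tsv(loci: list[StrLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LOCI_COLUMNS)
        for l in loci:
            writer.writerow(
                [l.locus_id, l.chrom, l.start, l.end, l.unit,
                 l.ref_repeat_count, l.flank_left, l.flank_right]
            )


def write_oligo_pool(
    design: PanelDesign, tsv_path: str | Path, fasta_path: str | Path | None = None
) -> None:
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["locus_id", "fw_arm", "rv_arm", "full_sequence", "active_sequence"])
        for p in design.precursors:
            writer.writerow(
                [p.locus_id, p.fw_arm, p.rv_arm, p.full_sequence, p.active_sequence]
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for p in design.precursors:
                fh.write(f">{p.locus_id}\n{p.full_sequence}\n")
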