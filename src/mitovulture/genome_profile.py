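"""Gene-table arithmetic and sequence-level mitogenome characterization.

Covers the descriptive layer of a comparative mitogenome study: feature
length validation, nucleotide composition, the protein-coding span and its
fraction of the genome, observed start/stop codons, and translation under a
chosen genetic code (vertebrate mitochondrial by default).

Numeric conventions: composition is reported to 1 decimal and fractions to
2 decimals, both rounded half-up, matching the precision such values are
printed at in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import Feature, FeatureTable, GenomeRecord

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "STANDARD_CODE",
    "get_code",
    "round_half_up",
    "normalize_feature",
    "ValidationFinding",
    "validate_feature_table",
    "genome_length_of",
    "composition",
    "pcg_span_stats",
    "CdsExtract",
    "extract_cds",
    "Translation",
    "translate",
    "GenomeProfile",
    "profile_genome",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Genetic codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table with stop and allowed start codon sets.

    Stops are encoded as ``'*'`` in the codon map.  The default throughout
    the package is the vertebrate mitochondrial code, in which AGA/AGG are
    stops, ATA is Met and TGA is Trp, and both ATG and GTG are allowed
    initiation codons.
    """

    name: str
    codon_map: dict[str, str]
    stop_codons: frozenset[str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValueError(f"codon map has {len(self.codon_map)} entries, need 64")

    def amino_acid(self, codon: str) -> str:
        return self.codon_map[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid (or ``'*'`` for the stop family) -> its codon set."""
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.codon_map):
            fams.setdefault(self.codon_map[codon], []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}


def _from_ncbi(table_id: int, name: str) -> GeneticCode:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    codon_map = dict(t.forward_table)
    for stop in t.stop_codons:
        codon_map[stop] = "*"
    return GeneticCode(
        name=name,
        codon_map=codon_map,
        stop_codons=frozenset(t.stop_codons),
        start_codons=frozenset(t.start_codons),
    )


VERTEBRATE_MITO = _from_ncbi(2, "vertebrate_mito")
STANDARD_CODE = _from_ncbi(1, "standard")

_CODES = {"vertebrate_mito": VERTEBRATE_MITO, "standard": STANDARD_CODE}


def get_code(name: str) -> GeneticCode:
    try:
        return _CODES[name]
    except KeyError:
        raise KeyError(
            f"unknown genetic code {name!r}; choose from {sorted(_CODES)}"
        ) from None


# ---------------------------------------------------------------------------
# Feature arithmetic
# ---------------------------------------------------------------------------


def normalize_feature(
    coord_a: int,
    coord_b: int,
    direction: str,
    ftype: str,
    name: str = "-",
    **kwargs,
) -> Feature:
    """Build a normalized :class:`Feature` from a raw table row.

    Accepts the two coordinates in either order (published minus-strand rows
    often run high-to-low); ``start`` becomes the minimum, ``end`` the
    maximum, and the computed length is ``end - start + 1``.
    """
    if min(coord_a, coord_b) < 1:
        raise ValueError("coordinates are 1-based; got a value < 1")
    strand = "+" if direction.strip() == "+" else "-"
    return Feature(
        name=name,
        ftype=ftype,
        start=min(coord_a, coord_b),
        end=max(coord_a, coord_b),
        strand=strand,
        **kwargs,
    )


@dataclass(frozen=True)
class ValidationFinding:
    """One report-only observation about a feature table row."""

    feature: str
    kind: str  # 'length_mismatch' | 'cds_not_codon_multiple' | 'overlap'
    message: str


def validate_feature_table(table: FeatureTable) -> list[ValidationFinding]:
    """Cross-check declared against computed values; never raises on findings.

    Produces one ``length_mismatch`` finding per row whose declared length
    differs from ``end - start + 1``, an informational finding for each CDS
    whose span is not a multiple of 3 (incomplete stop codons are normal in
    mitogenomes), and one finding per overlapping feature pair.
    """
    findings: list[ValidationFinding] = []
    for f in table:
        if f.declared_length is not None and f.declared_length != f.length:
            findings.append(
                ValidationFinding(
                    f.label,
                    "length_mismatch",
                    f"declared length {f.declared_length} != computed "
                    f"{f.length} ({f.start}..{f.end})",
                )
            )
        if f.ftype == "CDS" and f.length % 3 != 0:
            findings.append(
                ValidationFinding(
                    f.label,
                    "cds_not_codon_multiple",
                    f"length {f.length} not divisible by 3 "
                    f"(incomplete stop codon likely)",
                )
            )
    feats = table.features
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            if a.start <= b.end and b.start <= a.end:
                findings.append(
                    ValidationFinding(
                        a.label,
                        "overlap",
                        f"overlaps {b.label} over "
                        f"{max(a.start, b.start)}..{min(a.end, b.end)}",
                    )
                )
    return findings


def genome_length_of(table: FeatureTable, genome: GenomeRecord | None = None) -> int:
    """Genome length: the sequence length if supplied, else the maximum end."""
    if genome is not None:
        return len(genome)
    if len(table) == 0:
        raise ValueError("empty feature table and no genome sequence")
    return max(f.end for f in table)


def composition(genome: GenomeRecord) -> tuple[float, float]:
    """AT% and GC% over non-N positions, each rounded half-up to 1 decimal."""
    seq = genome.sequence
    counts = {b: seq.count(b) for b in _BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError(f"record {genome.identifier!r}: no unambiguous bases")
    at = 100.0 * (counts["A"] + counts["T"]) / denom
    gc = 100.0 * (counts["G"] + counts["C"]) / denom
    return round_half_up(at, 1), round_half_up(gc, 1)


def pcg_span_stats(table: FeatureTable, genome_length: int) -> tuple[int, float]:
    """Total protein-coding bp and its percentage of the genome.

    Lengths are summed over all CDS rows without deduplicating the small
    inter-gene overlaps (plain summation is how such spans are reported in
    mitogenome papers).  The declared length of a row is used when present,
    the computed span otherwise, so the statistic reproduces the source
    table's own arithmetic even where a printed coordinate disagrees with a
    printed length.  The fraction is rounded half-up to 2 decimals.
    """
    cds = table.of_type("CDS")
    if not cds:
        raise ValueError("feature table contains no CDS")
    total = sum(f.declared_length if f.declared_length is not None else f.length for f in cds)
    return total, round_half_up(100.0 * total / genome_length, 2)


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdsExtract:
    """An oriented coding sequence with its observed boundary codons."""

    sequence: str
    observed_start_codon: str
    observed_stop_codon: str  # trailing 3 nt, or fewer when incomplete
    stop_complete: bool


def extract_cds(genome: GenomeRecord, feature: Feature) -> CdsExtract:
    """Extract and orient a coding sequence; report observed boundary codons.

    Minus-strand features are reverse-complemented.  When the span is not a
    multiple of 3 the trailing 1–2 nt are reported as an incomplete stop
    (completed by post-transcriptional polyadenylation in vertebrate
    mitochondria).  Origin-spanning features are not supported.
    """
    if feature.end > len(genome):
        raise ValueError(
            f"feature {feature.label!r} ({feature.start}..{feature.end}) exceeds "
            f"genome length {len(genome)}; wrap-around features are unsupported"
        )
    seq = genome.sequence[feature.start - 1 : feature.end]
    if feature.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    rem = len(seq) % 3
    if rem == 0:
        stop, complete = seq[-3:], True
    else:
        stop, complete = seq[-rem:], False
    return CdsExtract(
        sequence=seq,
        observed_start_codon=seq[:3],
        observed_stop_codon=stop,
        stop_complete=complete,
    )


@dataclass(frozen=True)
class Translation:
    """A protein with translation findings (internal stops shown as '*')."""

    protein: str
    terminal_stop: str | None
    internal_stop_positions: tuple[int, ...]  # 1-based codon numbers
    incomplete_tail: bool


def translate(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> Translation:
    """Translate an oriented CDS codon by codon.

    The terminal stop codon is reported separately and not included in the
    protein.  Internal stops appear as ``'*'`` and are reported as findings,
    not errors — a comparative pipeline must be able to describe imperfect
    annotations.  A trailing partial codon is ignored and flagged.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError(f"CDS of length {len(cds)} cannot be translated")
    n_codons = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    terminal = codons[-1] if code.is_stop(codons[-1]) else None
    if terminal is not None:
        codons = codons[:-1]
    protein = []
    internal = []
    for i, codon in enumerate(codons, start=1):
        if "N" in codon:
            protein.append("X")
            continue
        aa = code.amino_acid(codon)
        if aa == "*":
            internal.append(i)
        protein.append(aa)
    return Translation(
        protein="".join(protein),
        terminal_stop=terminal,
        internal_stop_positions=tuple(internal),
        incomplete_tail=len(cds) % 3 != 0,
    )


# ---------------------------------------------------------------------------
# Whole-genome profile
# ---------------------------------------------------------------------------


@dataclass
class GenomeProfile:
    """Summary of a mitogenome against its feature table."""

    genome_length: int
    at_fraction: float | None
    gc_fraction: float | None
    pcg_total_bp: int
    pcg_fraction: float
    counts_by_type: dict[str, int]
    per_feature: pd.DataFrame
    findings: list[ValidationFinding] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            ("genome_length_bp", self.genome_length),
            ("at_percent", self.at_fraction),
            ("gc_percent", self.gc_fraction),
            ("pcg_total_bp", self.pcg_total_bp),
            ("pcg_percent", self.pcg_fraction),
        ] + [(f"n_{t}", n) for t, n in self.counts_by_type.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def profile_genome(
    table: FeatureTable,
    genome: GenomeRecord | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
) -> GenomeProfile:
    """Build the full descriptive profile (the tabular genome-report analogue).

    With a sequence, observed start/stop codons are read off each CDS and
    composition is computed; without one, the profile is table-only.
    """
    glen = genome_length_of(table, genome)
    at = gc = None
    if genome is not None:
        at, gc = composition(genome)
    pcg_bp, pcg_frac = pcg_span_stats(table, glen)
    rows = []
    for f in table:
        row = {
            "name": f.label,
            "type": f.ftype,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "length": f.length,
            "declared_length": f.declared_length,
            "declared_start_codon": f.declared_start_codon,
            "declared_stop_codon": f.declared_stop_codon,
            "observed_start_codon": None,
            "observed_stop_codon": None,
            "stop_complete": None,
        }
        if genome is not None and f.ftype == "CDS":
            ext = extract_cds(genome, f)
            row["observed_start_codon"] = ext.observed_start_codon
            row["observed_stop_codon"] = ext.observed_stop_codon
            row["stop_complete"] = ext.stop_complete
        rows.append(row)
    return GenomeProfile(
        genome_length=glen,
        at_fraction=at,
        gc_fraction=gc,
        pcg_total_bp=pcg_bp,
        pcg_fraction=pcg_frac,
        counts_by_type=table.counts_by_type(),
        per_feature=pd.DataFrame(rows),
        findings=validate_feature_table(table),
    )
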