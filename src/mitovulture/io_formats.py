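"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`GenomeRecord`, :class:`Feature` / :class:`FeatureTable`,
:class:`AlignmentBlock` and :class:`GroupPartition`.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout, as in GenBank-style
  annotation tables.  There are no half-open intervals on the public surface.
* Minus-strand rows of a feature table may list coordinates high-to-low
  (a common convention in published mitogenome tables); they are normalized
  to ``start <= end`` with strand ``'-'`` on input.
* Any dash glyph (ASCII hyphen, en dash, minus sign) in the direction column
  is accepted as the minus strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomeRecord",
    "Feature",
    "FeatureTable",
    "AlignmentBlock",
    "GroupPartition",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_alignment",
    "write_alignment",
    "read_groups",
    "write_groups",
    "write_tsv_report",
    "packaged_feature_table",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "control_region")

#: Glyphs accepted as "minus strand" in the Direction column of feature tables.
_DASH_GLYPHS = {"-", "−", "–", "—"}

_FEATURE_COLUMNS = (
    "Start",
    "End",
    "Length (bp)",
    "Direction",
    "Type",
    "Gene name",
    "Gene product",
    "Anti-codon",
    "Start codon",
    "Stop codon",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence, optionally circular.

    The sequence is stored uppercase over the alphabet ``{A, C, G, T, N}``;
    ``U`` is mapped to ``T`` on construction so RNA-style inputs are accepted.
    """

    identifier: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise FormatError(f"record {self.identifier!r}: empty sequence")
        bad = next((i for i, c in enumerate(seq) if c not in NUCLEOTIDE_ALPHABET), None)
        if bad is not None:
            raise FormatError(
                f"record {self.identifier!r}: non-IUPAC character "
                f"{seq[bad]!r} at position {bad + 1}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """One annotated element of a mitogenome.

    ``start``/``end`` are 1-based inclusive with ``start <= end`` regardless
    of strand; the strand carries the orientation.  ``declared_length`` and the
    declared start/stop codons are retained verbatim from the source table so
    annotation errors can be *reported* rather than silently repaired.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str
    product: str = ""
    anticodon: str | None = None
    declared_length: int | None = None
    declared_start_codon: str | None = None
    declared_stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise FormatError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"coordinates are 1-based; got start={self.start}")
        if self.start > self.end:
            raise ValueError(
                f"feature {self.name!r}: start {self.start} > end {self.end} "
                "(normalize coordinates before constructing)"
            )

    @property
    def length(self) -> int:
        """Computed span in bp (``end - start + 1``)."""
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        """Display label: gene name, with the anticodon attached for tRNAs."""
        if self.ftype == "tRNA" and self.anticodon:
            return f"{self.name}({self.anticodon.lower()})"
        return self.name


class FeatureTable:
    """An ordered collection of :class:`Feature` (a gene-table analogue).

    Overlapping features are permitted — avian mitogenomes contain genuine
    overlaps (e.g. *ATP8*/*ATP6*, or *trnM*/*trnQ* abutting on opposite
    strands).  Duplicated tRNA names (two *trnL*, two *trnS*) are
    distinguished by their anticodons; unnamed control regions are labelled
    ``CR1``, ``CR2``, ... in table order.
    """

    def __init__(
        self,
        features: Iterable[Feature],
        genome_length_hint: int | None = None,
    ) -> None:
        feats = list(features)
        cr_n = 0
        for i, f in enumerate(feats):
            if f.ftype == "control_region" and f.name in ("", "-"):
                cr_n += 1
                feats[i] = replace(f, name=f"CR{cr_n}")
        self.features: list[Feature] = feats
        self.genome_length_hint = genome_length_hint

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i):
        return self.features[i]

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    def by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in FEATURE_TYPES}
        for f in self.features:
            out[f.ftype] += 1
        return out


@dataclass(frozen=True)
class AlignmentBlock:
    """A per-gene amino-acid alignment: taxon label -> gapped row ('-' gaps)."""

    gene: str
    rows: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError(f"alignment {self.gene!r}: needs >= 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"alignment {self.gene!r}: ragged rows (lengths {sorted(lengths)})"
            )
        object.__setattr__(self, "rows", dict(self.rows))

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)


@dataclass(frozen=True)
class GroupPartition:
    """Taxon -> group assignment, with an optional focal taxon."""

    assignment: Mapping[str, str]
    focal: str | None = None

    def __post_init__(self) -> None:
        if not self.assignment:
            raise FormatError("group partition is empty")
        if self.focal is not None and self.focal not in self.assignment:
            raise FormatError(f"focal taxon {self.focal!r} is not assigned to a group")
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for taxon, group in self.assignment.items():
            out.setdefault(group, []).append(taxon)
        return out

    def members(self, group: str) -> list[str]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"no taxa assigned to group {group!r}") from None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and ``U`` is mapped to ``T``.  Records are
    returned in file order.  An empty file or a sequence containing characters
    outside ``{A, C, G, T, N, U}`` raises :class:`FormatError` naming the
    offending position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(identifier=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA (read/write round-trips modulo wrapping)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.identifier, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Feature table (annotation-table TSV dialect)
# ---------------------------------------------------------------------------


def _is_dashy(token: str) -> bool:
    t = token.strip()
    return t != "" and all(c in _DASH_GLYPHS for c in t)


def _clean_cell(token: str) -> str | None:
    t = token.strip().strip("*").strip()
    if t == "" or _is_dashy(t):
        return None
    return t


def _parse_ftype(token: str, lineno: int) -> str:
    t = token.strip().lower().replace(" ", "_")
    aliases = {"cds": "CDS", "trna": "tRNA", "rrna": "rRNA", "control_region": "control_region", "d-loop": "control_region", "d_loop": "control_region"}
    if t not in aliases:
        raise FormatError(f"line {lineno}: unknown feature type {token!r}")
    return aliases[t]


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a ten-column annotation-table TSV into a :class:`FeatureTable`.

    The dialect mirrors published mitogenome gene tables: columns are
    Start, End, Length (bp), Direction, Type, Gene name, Gene product,
    Anti-codon, Start codon, Stop codon.  The header row is optional.
    Minus-strand rows may list coordinates high-to-low; they are normalized
    so that ``start <= end``.  Declared lengths and codons are kept verbatim
    for later validation — the reader never corrects the table.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        return _parse_feature_rows(fh, str(path))


def _parse_feature_rows(fh: io.TextIOBase, source: str) -> FeatureTable:
    features: list[Feature] = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cells = line.split("\t")
        if lineno == 1 and cells[0].strip().lower() == "start":
            continue  # header
        cells += [""] * (len(_FEATURE_COLUMNS) - len(cells))
        try:
            a = int(cells[0].strip())
            b = int(cells[1].strip())
        except ValueError:
            raise FormatError(
                f"{source}, line {lineno}: non-integer coordinates "
                f"{cells[0]!r}/{cells[1]!r}"
            ) from None
        decl_len_cell = _clean_cell(cells[2])
        if decl_len_cell is not None:
            try:
                declared_length: int | None = int(decl_len_cell)
            except ValueError:
                raise FormatError(
                    f"{source}, line {lineno}: non-integer length {cells[2]!r}"
                ) from None
        else:
            declared_length = None
        direction = cells[3].strip()
        if direction == "+":
            strand = "+"
        elif _is_dashy(direction):
            strand = "-"
        else:
            raise FormatError(f"{source}, line {lineno}: bad direction {direction!r}")
        ftype = _parse_ftype(cells[4], lineno)
        name_cell = _clean_cell(cells[5])
        name = name_cell if name_cell is not None else "-"
        # "trnL (uag)"-style names: fold the parenthesised anticodon away
        anticodon = _clean_cell(cells[7])
        if "(" in name:
            base, _, rest = name.partition("(")
            name = base.strip()
            if anticodon is None:
                anticodon = rest.strip(") ").upper()
        start, end = min(a, b), max(a, b)
        if start < 1:
            raise FormatError(f"{source}, line {lineno}: coordinate < 1")
        features.append(
            Feature(
                name=name,
                ftype=ftype,
                start=start,
                end=end,
                strand=strand,
                product=_clean_cell(cells[6]) or "",
                anticodon=anticodon,
                declared_length=declared_length,
                declared_start_codon=_clean_cell(cells[8]),
                declared_stop_codon=_clean_cell(cells[9]),
            )
        )
    if not features:
        raise FormatError(f"{source}: no feature rows")
    return FeatureTable(features)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a :class:`FeatureTable` back to the ten-column TSV dialect.

    Output is always normalized (start <= end, '-' for minus strand, '-' for
    empty cells), so read∘write is an identity on normalized tables.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_FEATURE_COLUMNS) + "\n")
        for f in table:
            cells = [
                str(f.start),
                str(f.end),
                str(f.declared_length if f.declared_length is not None else f.length),
                f.strand,
                "control region" if f.ftype == "control_region" else f.ftype,
                f.name,
                f.product or "-",
                f.anticodon or "-",
                f.declared_start_codon or "-",
                f.declared_stop_codon or "-",
            ]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Alignments, group files, reports
# ---------------------------------------------------------------------------

_AA_GAP_OK = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-.")


def read_alignment(path: str | Path, gene: str | None = None) -> AlignmentBlock:
    """Read an aligned amino-acid FASTA into an :class:`AlignmentBlock`.

    All rows must have equal length; duplicate taxon labels are an error.
    The gene name defaults to the file stem.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FormatError(f"{path}: duplicate taxon label {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = next((c for c in seq if c not in _AA_GAP_OK), None)
        if bad is not None:
            raise FormatError(f"{path}, taxon {rec.id!r}: unexpected character {bad!r}")
        rows[rec.id] = seq
    if not rows:
        raise FormatError(f"{path}: no alignment rows")
    return AlignmentBlock(gene=gene or path.stem, rows=rows)


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in block.rows.items():
            fh.write(f">{taxon}\n{row}\n")


def read_groups(path: str | Path) -> GroupPartition:
    """Read a two-column TSV ``taxon<TAB>group`` file.

    A line ``focal:<TAB>taxon`` (or ``focal: taxon``) names the focal taxon.
    Duplicate taxa and empty files are format errors.
    """
    path = Path(path)
    assignment: dict[str, str] = {}
    focal: str | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("focal:"):
                focal = line.split(":", 1)[1].strip().split("\t")[-1].strip()
                continue
            parts = [p.strip() for p in line.split("\t") if p.strip()]
            if len(parts) != 2:
                raise FormatError(f"{path}, line {lineno}: expected 'taxon<TAB>group'")
            taxon, group = parts
            if taxon in assignment:
                raise FormatError(f"{path}, line {lineno}: duplicate taxon {taxon!r}")
            assignment[taxon] = group
    if not assignment:
        raise FormatError(f"{path}: empty group file")
    return GroupPartition(assignment=assignment, focal=focal)


def write_groups(partition: GroupPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, group in partition.assignment.items():
            fh.write(f"{taxon}\t{group}\n")
        if partition.focal is not None:
            fh.write(f"focal:\t{partition.focal}\n")


def write_tsv_report(table, path: str | Path) -> None:
    """Write a pandas DataFrame report as plain TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged reference annotation
# ---------------------------------------------------------------------------


def packaged_feature_table() -> FeatureTable:
    """The packaged gene table of the *Sarcogyps calvus* mitogenome (OR896160).

    A verbatim transcription of the published annotation: 13 protein-coding
    genes, 22 tRNAs, 2 rRNAs and 2 control regions over 17,750 bp.  Printed
    inconsistencies in the source (the ND3 declared length, the COX3 stop
    codon) are preserved as printed; see ``validate_feature_table``.
    """
    text = (
        resources.files("mitovulture.data")
        .joinpath("sarcogyps_calvus_features.tsv")
        .read_text(encoding="utf-8")
    )
    return _parse_feature_rows(io.StringIO(text), "sarcogyps_calvus_features.tsv")
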