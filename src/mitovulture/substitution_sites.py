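"""Group-conserved amino-acid substitution detection and chemical classing.

The central comparative question: at which alignment columns are two clades
(e.g. Old World vultures / Gypini vs New World vultures / Cathartidae) each
internally monomorphic yet different from one another?  Each such site is
annotated with the side-chain chemical class of both residues, and a
focal-taxon variant finds columns where one taxon differs from an otherwise
monomorphic rest-of-group.

Classing notes
--------------
The default :class:`PropertyScheme` is the five-way side-chain grouping
common in the comparative literature: hydrophobic {A,V,L,I,M,F,W,Y}, polar
uncharged {S,T,N,Q}, positive {K,R,H}, negative {D,E} and the special-case
residues {C,G,P}.  When deciding whether a substitution crosses chemical
classes, each special-case residue counts as its own singleton class: Cys,
Gly and Pro play such distinct structural roles (disulfide bonds, backbone
flexibility, backbone rigidity) that a C→G swap is a real chemical change
even though both are "special".
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io_formats import AlignmentBlock, GroupPartition

__all__ = [
    "PropertyScheme",
    "DEFAULT_SCHEME",
    "SubstitutionSite",
    "SiteSummary",
    "classify_residue",
    "effective_class",
    "find_group_conserved_sites",
    "focal_vs_group_sites",
    "summarize_sites",
    "sites_frame",
    "load_reference_sites",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

HYDROPHOBIC = "Hydrophobic"
POLAR = "Polar uncharged"
POSITIVE = "Positive"
NEGATIVE = "Negative"
SPECIAL = "Special case"


@dataclass(frozen=True)
class PropertyScheme:
    """Residue -> side-chain class mapping over the 20 standard residues."""

    mapping: dict[str, str]
    special_residues: frozenset[str] = frozenset("CGP")

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.mapping)
        if missing:
            raise ValueError(f"scheme misses residues: {sorted(missing)}")
        object.__setattr__(self, "mapping", dict(self.mapping))


def _default_mapping() -> dict[str, str]:
    m: dict[str, str] = {}
    for r in "AVLIMFWY":
        m[r] = HYDROPHOBIC
    for r in "STNQ":
        m[r] = POLAR
    for r in "KRH":
        m[r] = POSITIVE
    for r in "DE":
        m[r] = NEGATIVE
    for r in "CGP":
        m[r] = SPECIAL
    return m


DEFAULT_SCHEME = PropertyScheme(mapping=_default_mapping())


def classify_residue(residue: str, scheme: PropertyScheme = DEFAULT_SCHEME) -> str:
    """Side-chain class label of a standard one-letter residue."""
    r = residue.upper()
    if r not in scheme.mapping:
        raise KeyError(f"not a standard residue: {residue!r}")
    return scheme.mapping[r]


def effective_class(residue: str, scheme: PropertyScheme = DEFAULT_SCHEME) -> str:
    """Class used for cross-class comparison: special residues are singletons."""
    r = residue.upper()
    label = classify_residue(r, scheme)
    if r in scheme.special_residues:
        return f"{SPECIAL}:{r}"
    return label


@dataclass(frozen=True)
class SubstitutionSite:
    """One qualifying alignment column between two groups (or focal vs rest).

    ``position`` is the 1-based residue number in the ungapped reference row
    (first group-a taxon, or the focal taxon for focal analyses).
    ``cross_class`` is true iff the two residues' effective classes differ;
    ``special_involved`` iff either residue is C, G or P.
    """

    gene: str
    position: int
    residue_a: str
    residue_b: str
    class_a: str
    class_b: str
    cross_class: bool
    special_involved: bool
    unique_class: bool | None = None  # focal analyses only

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("a substitution site needs two different residues")


@dataclass
class SiteSummary:
    """Aggregated view of a site collection."""

    per_gene: dict[str, int]
    total: int
    cross_class_total: int
    max_genes: frozenset[str]
    special_residue_tallies: dict[str, int]
    per_gene_cross_class: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "sites": n,
                "cross_class_sites": self.per_gene_cross_class.get(g, 0),
            }
            for g, n in sorted(self.per_gene.items())
        ]
        rows.append(
            {"gene": "Total", "sites": self.total, "cross_class_sites": self.cross_class_total}
        )
        return pd.DataFrame(rows)


def _qualify_column(residues: list[str]) -> str | None:
    """Monomorphic standard residue shared by all rows, else None."""
    first = residues[0]
    if first not in STANDARD_RESIDUES:
        return None
    for r in residues[1:]:
        if r != first:
            return None
    return first


def _ungapped_positions(reference_row: str) -> list[int]:
    """Column index -> 1-based ungapped position in the reference (0 at gaps)."""
    pos = 0
    out = []
    for c in reference_row:
        if c != "-":
            pos += 1
            out.append(pos)
        else:
            out.append(0)
    return out


def _make_site(
    gene: str,
    position: int,
    res_a: str,
    res_b: str,
    scheme: PropertyScheme,
    unique_class: bool | None = None,
) -> SubstitutionSite:
    eff_a = effective_class(res_a, scheme)
    eff_b = effective_class(res_b, scheme)
    return SubstitutionSite(
        gene=gene,
        position=position,
        residue_a=res_a,
        residue_b=res_b,
        class_a=classify_residue(res_a, scheme),
        class_b=classify_residue(res_b, scheme),
        cross_class=eff_a != eff_b,
        special_involved=bool({res_a, res_b} & scheme.special_residues),
        unique_class=unique_class,
    )


def find_group_conserved_sites(
    block: AlignmentBlock,
    partition: GroupPartition,
    group_a: str,
    group_b: str,
    scheme: PropertyScheme = DEFAULT_SCHEME,
) -> list[SubstitutionSite]:
    """Columns where each group is monomorphic and the two groups differ.

    A column qualifies iff every group-a row carries one standard residue,
    every group-b row carries one standard residue, and the two residues
    differ.  Any gap or non-standard character in a qualifying row
    disqualifies the column.  Positions are numbered in the ungapped
    coordinates of the first group-a taxon present in the alignment.
    """
    taxa_a = [t for t in block.taxa if partition.assignment.get(t) == group_a]
    taxa_b = [t for t in block.taxa if partition.assignment.get(t) == group_b]
    for label, taxa, want in ((group_a, taxa_a, partition.members(group_a)), (group_b, taxa_b, partition.members(group_b))):
        if not taxa:
            raise ValueError(f"group {label!r} has no taxa in alignment {block.gene!r}")
        absent = set(want) - set(block.taxa)
        if absent:
            raise ValueError(
                f"alignment {block.gene!r} misses group {label!r} taxa: {sorted(absent)}"
            )
    rows_a = [block.rows[t] for t in taxa_a]
    rows_b = [block.rows[t] for t in taxa_b]
    positions = _ungapped_positions(rows_a[0])
    sites = []
    for col in range(block.n_columns):
        res_a = _qualify_column([r[col] for r in rows_a])
        res_b = _qualify_column([r[col] for r in rows_b])
        if res_a is None or res_b is None or res_a == res_b:
            continue
        sites.append(_make_site(block.gene, positions[col], res_a, res_b, scheme))
    return sites


def focal_vs_group_sites(
    block: AlignmentBlock,
    partition: GroupPartition,
    group: str,
    scheme: PropertyScheme = DEFAULT_SCHEME,
) -> list[SubstitutionSite]:
    """Columns where the focal taxon differs from its otherwise uniform group.

    ``residue_a`` is the residue shared by all non-focal group members,
    ``residue_b`` the focal taxon's private residue.  ``unique_class`` is set
    when the focal residue's effective class differs from the rest-group
    class.  Positions are numbered in the focal taxon's ungapped coordinates.
    """
    focal = partition.focal
    if focal is None or focal not in block.taxa:
        raise ValueError(f"focal taxon absent from alignment {block.gene!r}")
    others = [t for t in block.taxa if t != focal and partition.assignment.get(t) == group]
    if len(others) < 2:
        raise ValueError(f"group {group!r} needs >= 2 non-focal members")
    focal_row = block.rows[focal]
    rows = [block.rows[t] for t in others]
    positions = _ungapped_positions(focal_row)
    sites = []
    for col in range(block.n_columns):
        res_f = focal_row[col]
        if res_f not in STANDARD_RESIDUES:
            continue
        res_o = _qualify_column([r[col] for r in rows])
        if res_o is None or res_o == res_f:
            continue
        unique = effective_class(res_o, scheme) != effective_class(res_f, scheme)
        sites.append(
            _make_site(block.gene, positions[col], res_o, res_f, scheme, unique_class=unique)
        )
    return sites


def summarize_sites(sites: list[SubstitutionSite]) -> SiteSummary:
    """Per-gene totals, cross-class totals and special-residue tallies.

    A site contributes once to the tally of each special-case residue (C, G
    or P) it involves, on either side of the substitution.  Genes achieving
    the per-gene maximum are reported as a set (ties possible).
    """
    per_gene: dict[str, int] = {}
    per_gene_cc: dict[str, int] = {}
    special: dict[str, int] = {"C": 0, "G": 0, "P": 0}
    cross = 0
    for s in sites:
        per_gene[s.gene] = per_gene.get(s.gene, 0) + 1
        if s.cross_class:
            cross += 1
            per_gene_cc[s.gene] = per_gene_cc.get(s.gene, 0) + 1
        for r in {s.residue_a, s.residue_b} & set("CGP"):
            special[r] += 1
    if per_gene:
        top = max(per_gene.values())
        max_genes = frozenset(g for g, n in per_gene.items() if n == top)
    else:
        max_genes = frozenset()
    return SiteSummary(
        per_gene=per_gene,
        total=len(sites),
        cross_class_total=cross,
        max_genes=max_genes,
        special_residue_tallies=special,
        per_gene_cross_class=per_gene_cc,
    )


def sites_frame(sites: list[SubstitutionSite]) -> pd.DataFrame:
    """Long-format site report mirroring published substitution tables."""
    rows = []
    for s in sites:
        row = {
            "gene": s.gene,
            "position": s.position,
            "residue_a": s.residue_a,
            "residue_b": s.residue_b,
            "class_a": s.class_a,
            "class_b": s.class_b,
            "cross_class": s.cross_class,
            "special_involved": s.special_involved,
        }
        if s.unique_class is not None:
            row["unique_class"] = s.unique_class
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged reference site lists
# ---------------------------------------------------------------------------

_REFERENCE_FILES = {
    "owv_nwv": "owv_nwv_substitutions.tsv",
    "calvus_gypini": "calvus_vs_gypini_substitutions.tsv",
}


def load_reference_sites(which: str = "owv_nwv") -> pd.DataFrame:
    """Published cross-class substitution lists, transcribed verbatim.

    ``"owv_nwv"``: the 67 Gypini-vs-Cathartidae sites whose residues were
    reported with differing side-chain classes.  ``"calvus_gypini"``: the 43
    sites separating *Sarcogyps calvus* from the other Gypini (these columns
    include the printed class labels, one of which — ND3 108, Thr labelled
    hydrophobic — is a documented inconsistency in the source).
    """
    try:
        fname = _REFERENCE_FILES[which]
    except KeyError:
        raise KeyError(f"unknown reference set {which!r}; choose from {sorted(_REFERENCE_FILES)}") from None
    text = resources.files("mitovulture.data").joinpath(fname).read_text(encoding="utf-8")
    return pd.read_csv(io.StringIO(text), sep="\t")


def sites_from_frame(frame: pd.DataFrame, scheme: PropertyScheme = DEFAULT_SCHEME) -> list[SubstitutionSite]:
    """Re-derive :class:`SubstitutionSite` objects from a (gene, position,
    residue pair) table, classifying with ``scheme`` rather than trusting any
    class columns the table may carry."""
    res_cols = [c for c in frame.columns if c.startswith("residue_")]
    a_col, b_col = res_cols[0], res_cols[1]
    return [
        _make_site(str(r["gene"]), int(r["position"]), str(r[a_col]), str(r[b_col]), scheme)
        for _, r in frame.iterrows()
        if str(r[a_col]) != str(r[b_col])
    ]
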