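"""Codon counting and relative synonymous codon usage (RSCU).

RSCU(c) = n_c / mean(n over c's synonymous family).  Values above 1 indicate
positive codon bias, below 1 negative bias, exactly 1 no bias.  Families are
defined by the supplied genetic code; under the vertebrate mitochondrial code
the four stop codons {TAA, TAG, AGA, AGG} form their own family, so the
family-sum invariant Σ_family RSCU = |family| holds for stops as well.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .genome_profile import GeneticCode, VERTEBRATE_MITO

__all__ = ["ALL_CODONS", "CodonUsageTable", "RscuTable", "count_codons", "rscu", "rank_codons", "rscu_report"]

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)


@dataclass
class CodonUsageTable:
    """Per-codon counts (all 64 keys present, zero-filled) plus bookkeeping."""

    counts: dict[str, int]
    source_genes: tuple[str, ...] = ()
    n_skipped_with_n: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        full.update({k.upper(): int(v) for k, v in self.counts.items()})
        unknown = set(full) - set(ALL_CODONS)
        if unknown:
            raise ValueError(f"non-DNA codons in usage table: {sorted(unknown)}")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def scaled(self, k: int) -> "CodonUsageTable":
        return CodonUsageTable({c: n * k for c, n in self.counts.items()})


@dataclass
class RscuTable:
    """RSCU values plus the family map used to compute them.

    Codons of families with zero total usage carry value 0.0 and are listed
    in ``unused_families`` rather than raising.
    """

    values: dict[str, float]
    families: dict[str, tuple[str, ...]]
    unused_families: tuple[str, ...] = ()


def count_codons(
    cds_list: list[str] | dict[str, str],
    include_stops: bool = True,
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonUsageTable:
    """Count in-frame, non-overlapping triplets from position 1 of each CDS.

    Trailing partial codons are ignored; codons containing N are skipped and
    tallied in ``n_skipped_with_n``.  With ``include_stops=False`` codons that
    are stops under ``code`` are excluded from the table.
    """
    if isinstance(cds_list, dict):
        genes = tuple(cds_list)
        seqs = list(cds_list.values())
    else:
        genes = ()
        seqs = list(cds_list)
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon not in counts:  # contains N or other ambiguity
                skipped += 1
                continue
            if not include_stops and code.is_stop(codon):
                continue
            counts[codon] += 1
    return CodonUsageTable(counts=counts, source_genes=genes, n_skipped_with_n=skipped)


def rscu(usage: CodonUsageTable, code: GeneticCode = VERTEBRATE_MITO) -> RscuTable:
    """Relative synonymous codon usage under ``code``.

    For every family with at least one count, RSCU values sum to the family
    size; uniform usage gives 1.0 everywhere.  RSCU is invariant under
    uniform scaling of all counts.
    """
    families = code.synonymous_families()
    values: dict[str, float] = {}
    unused: list[str] = []
    for aa, fam in families.items():
        fam_total = sum(usage.counts[c] for c in fam)
        if fam_total == 0:
            unused.append(aa)
            for c in fam:
                values[c] = 0.0
            continue
        mean = fam_total / len(fam)
        for c in fam:
            values[c] = usage.counts[c] / mean
    return RscuTable(values=values, families=families, unused_families=tuple(unused))


def rank_codons(usage: CodonUsageTable) -> list[str]:
    """Codons ordered by count descending, ties broken lexicographically."""
    return sorted(ALL_CODONS, key=lambda c: (-usage.counts[c], c))


def _to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def rscu_report(
    usage: CodonUsageTable,
    code: GeneticCode = VERTEBRATE_MITO,
    rna_alphabet: bool = False,
) -> pd.DataFrame:
    """Tabular RSCU report: codon, amino acid, count, RSCU, family size.

    ``rna_alphabet=True`` renders codons as UAA-style for parity with how
    codon-usage figures are usually labelled.
    """
    table = rscu(usage, code)
    rows = []
    for aa, fam in sorted(table.families.items()):
        for c in fam:
            rows.append(
                {
                    "codon": _to_rna(c) if rna_alphabet else c,
                    "amino_acid": "STOP" if aa == "*" else aa,
                    "count": usage.counts[c],
                    "rscu": round(table.values[c], 4),
                    "family_size": len(fam),
                }
            )
    return pd.DataFrame(rows)
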