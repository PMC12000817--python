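"""Perfect-microsatellite (SSR) detection and per-region census.

Finds maximal perfect tandem repeats of primitive motifs of length 1–6 bp
(MISA-style), then assigns each hit to the annotated feature containing its
start position to build a region-by-motif-class census table.

Scanning is linear even for circular genomes, matching standard SSR tools;
origin-spanning repeats are out of scope.  Runs containing N never form part
of a hit.  Compound or interrupted repeats are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import FeatureTable, GenomeRecord

__all__ = ["SsrThresholds", "SsrHit", "find_ssrs", "primitive_motif", "assign_regions", "census_frame", "UNIDENTIFIED_REGION"]

UNIDENTIFIED_REGION = "(unidentified region)"

#: Census column label per motif length; 5 and 6 are pooled, as such tables
#: conventionally group the rare penta-/hexanucleotide repeats together.
_CLASS_LABELS = {1: "MRS", 2: "DRS", 3: "TriRS", 4: "TetRS", 5: "Microsatellite sequences", 6: "Microsatellite sequences"}
_CENSUS_COLUMNS = ["MRS", "DRS", "TriRS", "TetRS", "Microsatellite sequences"]


@dataclass(frozen=True)
class SsrThresholds:
    """Minimum repeat count per motif length 1..6 (all must be >= 2).

    Defaults (4, 3, 3, 3, 3, 3) are deliberately conservative, comparable to
    common MISA configurations scaled to a ~17 kb mitogenome.
    """

    mono: int = 4
    di: int = 3
    tri: int = 3
    tetra: int = 3
    penta: int = 3
    hexa: int = 3

    def __post_init__(self) -> None:
        if any(t < 2 for t in self.as_dict().values()):
            raise ValueError("all SSR thresholds must be >= 2")

    def as_dict(self) -> dict[int, int]:
        return {1: self.mono, 2: self.di, 3: self.tri, 4: self.tetra, 5: self.penta, 6: self.hexa}

    @classmethod
    def parse(cls, spec: str) -> "SsrThresholds":
        """Parse a ``1:4,2:3,...`` CLI-style threshold specification."""
        names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
        kwargs = {}
        for part in spec.split(","):
            k, _, v = part.partition(":")
            kwargs[names[int(k)]] = int(v)
        return cls(**kwargs)


@dataclass(frozen=True)
class SsrHit:
    """One perfect tandem repeat: primitive motif, repeat count, 1-based span."""

    motif: str
    repeats: int
    start: int
    end: int
    region: str = UNIDENTIFIED_REGION

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeats:
            raise ValueError("span must equal motif length x repeats")

    @property
    def motif_length(self) -> int:
        return len(self.motif)


def primitive_motif(motif: str) -> bool:
    """True iff the motif is not itself a repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssrs(
    genome: GenomeRecord | str,
    thresholds: SsrThresholds = SsrThresholds(),
) -> list[SsrHit]:
    """All maximal perfect repeats of primitive 1–6 bp motifs meeting thresholds.

    For each motif length *k*, a region has period *k* where ``s[i] == s[i+k]``
    chains; each maximal such run yields one hit covering its whole repeats
    (any trailing partial period is excluded from the hit span, so
    ``end - start + 1 = k * repeats`` exactly).  Runs whose motif is a power
    of a shorter motif are suppressed: the shorter-motif scan already reports
    the identical span (primitive-motif rule).  Hits are returned left to
    right, shorter motifs first at equal start.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    n = len(seq)
    mins = thresholds.as_dict()
    hits: list[SsrHit] = []
    for k in range(1, 7):
        i = 0
        while i + k < n:
            if seq[i] == "N" or seq[i] != seq[i + k]:
                i += 1
                continue
            j = i
            while j + k < n and seq[j] != "N" and seq[j] == seq[j + k]:
                j += 1
            # period-k run covers seq[i : j+k]; full repeats only
            span = j - i + k
            repeats = span // k
            motif = seq[i : i + k]
            if repeats >= mins[k] and "N" not in motif and primitive_motif(motif):
                hits.append(
                    SsrHit(motif=motif, repeats=repeats, start=i + 1, end=i + k * repeats)
                )
            i = j + 1
    hits.sort(key=lambda h: (h.start, h.motif_length))
    return hits


def assign_regions(hits: list[SsrHit], table: FeatureTable) -> list[SsrHit]:
    """Assign each hit to the feature containing its start position.

    When several features cover the start (overlaps are real in mitogenomes),
    the first feature in table order wins.  Starts covered by no feature are
    labelled ``(unidentified region)``.
    """
    out = []
    for h in hits:
        region = UNIDENTIFIED_REGION
        for f in table:
            if f.start <= h.start <= f.end:
                region = f.label
                break
        out.append(SsrHit(h.motif, h.repeats, h.start, h.end, region))
    return out


def census_frame(hits: list[SsrHit]) -> pd.DataFrame:
    """Region x motif-class count matrix with row and column totals.

    Columns: mono (MRS), di (DRS), tri (TriRS), tetra (TetRS), a pooled
    penta+hexa "Microsatellite sequences" column, and Total.  The last row
    holds column totals; margins always sum to the number of hits.
    """
    regions: dict[str, dict[str, int]] = {}
    for h in hits:
        row = regions.setdefault(h.region, {c: 0 for c in _CENSUS_COLUMNS})
        row[_CLASS_LABELS[h.motif_length]] += 1
    ordered = sorted(regions, key=lambda r: (r != UNIDENTIFIED_REGION, r))
    rows = []
    for region in ordered:
        counts = regions[region]
        rows.append({"Region": region, **counts, "Total": sum(counts.values())})
    totals = {c: sum(r[c] for r in rows) for c in _CENSUS_COLUMNS}
    rows.append({"Region": "Total", **totals, "Total": sum(totals.values())})
    return pd.DataFrame(rows, columns=["Region", *_CENSUS_COLUMNS, "Total"])


def hits_frame(hits: list[SsrHit]) -> pd.DataFrame:
    """Long-format hit report (motif, repeats, start, end, region)."""
    return pd.DataFrame(
        [
            {"motif": h.motif, "repeats": h.repeats, "start": h.start, "end": h.end, "region": h.region}
            for h in hits
        ],
        columns=["motif", "repeats", "start", "end", "region"],
    )
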