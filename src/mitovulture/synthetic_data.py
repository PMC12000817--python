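"""Seeded generators for every input class the pipeline consumes.

The generators emulate the study system: a circular avian mitogenome
(13 CDS / 22 tRNA / 2 rRNA / 2 control regions on both strands, ~54% AT)
with tunable composition and codon bias, planted perfect microsatellites,
and two clades of protein alignments (5 Old World vs 6 New World vultures
by default) with planted group-conserved substitutions, focal-private
substitutions and within-group noise.  Every generator returns a
:class:`SyntheticTruth` sufficient to predict the exact expected output of
the corresponding analysis stage, so recovery tests can diff stage output
against truth.

Defaults mirror the study conditions: the default gene layout is the
packaged *S. calvus* annotation (17,750 bp), the default AT target is 54.1%,
and the default clade sizes are 5 and 6.  What the generators deliberately do
not emulate: realistic substitution models, indels, rate heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_usage import count_codons
from .genome_profile import GeneticCode, VERTEBRATE_MITO, extract_cds
from .io_formats import (
    AlignmentBlock,
    Feature,
    FeatureTable,
    GenomeRecord,
    GroupPartition,
    packaged_feature_table,
    write_alignment,
    write_fasta,
    write_feature_table,
    write_groups,
)
from .ssr_scan import primitive_motif

__all__ = [
    "SyntheticTruth",
    "generate_mitogenome",
    "plant_ssrs",
    "generate_clade_alignments",
    "default_gene_lengths",
    "write_truth",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """The planted parameters behind a synthetic dataset."""

    seed: int
    at_target: float | None = None
    codon_tallies: dict[str, int] | None = None
    planted_ssrs: list[tuple[str, int, int]] = field(default_factory=list)  # motif, repeats, start
    planted_group_sites: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    planted_focal_sites: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    between_group_divergence: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mitogenome generator
# ---------------------------------------------------------------------------


def _sample_background(rng: np.random.Generator, n: int, at_percent: float) -> np.ndarray:
    """Per-position bases hitting the AT target in expectation.

    Sampling is integer-based (permille threshold) so a fixed seed gives a
    byte-identical genome on any platform.
    """
    is_at = rng.integers(0, 1000, size=n) < round(at_percent * 10)
    pick = rng.integers(0, 2, size=n)
    out = np.where(is_at, np.where(pick == 0, "A", "T"), np.where(pick == 0, "G", "C"))
    return out


def generate_mitogenome(
    layout: FeatureTable | None = None,
    at_percent: float = 54.1,
    codon_bias: dict[str, float] | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
    seed: int = 0,
    identifier: str = "synthetic_mitogenome",
) -> tuple[GenomeRecord, FeatureTable, SyntheticTruth]:
    """Generate a mitogenome realizing a feature layout.

    CDS regions are filled codon by codon: the declared start codon first,
    interior codons drawn from ``codon_bias`` (uniform over the code's sense
    codons by default, stop codons never sampled), the declared stop codon
    last, and — for spans not divisible by 3 — a truncated ``T``/``TA``
    incomplete stop.  Minus-strand genes are written as reverse complements.
    Non-CDS positions are drawn from a nucleotide distribution meeting
    ``at_percent`` in expectation.  CDS written later in table order
    overwrite earlier ones over shared bases (mitogenomes do overlap genes);
    opposite-strand CDS overlaps are rejected as infeasible.  The truth
    object carries the per-codon tallies of the final extracted CDS set.
    """
    if layout is None:
        layout = packaged_feature_table()
    glen = max(f.end for f in layout)
    cds = layout.of_type("CDS")
    for i, a in enumerate(cds):
        for b in cds[i + 1 :]:
            if a.strand != b.strand and a.start <= b.end and b.start <= a.end:
                raise ValueError(
                    f"infeasible layout: opposite-strand CDS overlap "
                    f"{a.label}/{b.label}"
                )
    rng = np.random.default_rng(seed)
    seq = _sample_background(rng, glen, at_percent)

    sense = sorted(c for c in code.codon_map if code.codon_map[c] != "*")
    if codon_bias is None:
        # default bias follows the AT target per base, so the whole genome
        # (coding regions included) meets at_percent in expectation; at 50%
        # this reduces to uniform sense-codon usage
        p_base = {b: (at_percent / 200.0 if b in "AT" else (100.0 - at_percent) / 200.0) for b in "ACGT"}
        w = np.array([p_base[c[0]] * p_base[c[1]] * p_base[c[2]] for c in sense])
        probs = w / w.sum()
    else:
        w = np.array([float(codon_bias.get(c, 0.0)) for c in sense])
        if w.sum() <= 0:
            raise ValueError("codon bias assigns no weight to any sense codon")
        probs = w / w.sum()

    for f in cds:
        n = f.length
        n_codons, rem = divmod(n, 3)
        if n_codons < 2:
            raise ValueError(f"CDS {f.label!r} too short to generate ({n} bp)")
        start_codon = (f.declared_start_codon or "ATG").upper()
        parts = [start_codon]
        n_interior = n_codons - 1
        stop = None
        if rem == 0:
            stop = (f.declared_stop_codon or "TAA").upper()
            if len(stop) != 3 or set(stop) - set("ACGT"):
                stop = "TAA"
            n_interior -= 1
        idx = rng.choice(len(sense), size=n_interior, p=probs)
        parts.extend(sense[i] for i in idx)
        if stop is not None:
            parts.append(stop)
        cds_seq = "".join(parts) + "TA"[:rem]
        assert len(cds_seq) == n
        if f.strand == "-":
            cds_seq = cds_seq.translate(_COMPLEMENT)[::-1]
        seq[f.start - 1 : f.end] = list(cds_seq)

    record = GenomeRecord(identifier=identifier, sequence="".join(seq))
    tallies = count_codons(
        [extract_cds(record, f).sequence for f in cds], include_stops=True, code=code
    )
    truth = SyntheticTruth(seed=seed, at_target=at_percent, codon_tallies=dict(tallies.counts))
    return record, layout, truth


# ---------------------------------------------------------------------------
# Microsatellite planting
# ---------------------------------------------------------------------------


def plant_ssrs(
    genome: GenomeRecord,
    plants: list[tuple[str, int, int]],
    seed: int = 0,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Overwrite the genome with perfect repeats at chosen positions.

    Each plant is ``(motif, repeats, start)`` with a primitive 1–6 bp motif
    and a 1-based start.  The base immediately left of a plant is forced away
    from the motif's last character and the base immediately right away from
    its first character, so no plant extends beyond its declared repeat
    count.  Plants (including their one-base flanks) must not overlap.
    """
    seq = list(genome.sequence)
    n = len(seq)
    rng = np.random.default_rng(seed)
    spans = []
    for motif, repeats, start in plants:
        motif = motif.upper()
        if not (1 <= len(motif) <= 6) or set(motif) - set("ACGT"):
            raise ValueError(f"bad motif {motif!r}")
        if not primitive_motif(motif):
            raise ValueError(f"motif {motif!r} is a power of a shorter motif")
        if repeats < 2:
            raise ValueError("repeats must be >= 2")
        end = start + len(motif) * repeats - 1
        if start < 1 or end > n:
            raise ValueError(f"plant ({motif}, {repeats}, {start}) out of bounds")
        spans.append((start - 1, end + 1))  # flank-inclusive, 1-based
    spans_sorted = sorted(spans)
    for (a1, b1), (a2, b2) in zip(spans_sorted, spans_sorted[1:]):
        if a2 <= b1:
            raise ValueError("planted repeats (with flanks) overlap")

    def _avoid(forbidden: str) -> str:
        options = [b for b in "ACGT" if b != forbidden]
        return options[int(rng.integers(0, len(options)))]

    for motif, repeats, start in plants:
        motif = motif.upper()
        i0 = start - 1
        i1 = i0 + len(motif) * repeats
        seq[i0:i1] = list(motif * repeats)
        if i0 > 0 and seq[i0 - 1] == motif[-1]:
            seq[i0 - 1] = _avoid(motif[-1])
        if i1 < n and seq[i1] == motif[0]:
            seq[i1] = _avoid(motif[0])

    record = GenomeRecord(identifier=genome.identifier, sequence="".join(seq), circular=genome.circular)
    truth = SyntheticTruth(seed=seed, planted_ssrs=[(m.upper(), r, s) for m, r, s in plants])
    return record, truth


# ---------------------------------------------------------------------------
# Clade alignment generator
# ---------------------------------------------------------------------------


def default_gene_lengths() -> dict[str, int]:
    """Protein lengths implied by the packaged layout (codons minus stop)."""
    return {
        f.name: f.length // 3 - 1
        for f in packaged_feature_table().of_type("CDS")
    }


def generate_clade_alignments(
    gene_lengths: dict[str, int] | None = None,
    group_sizes: tuple[int, int] = (5, 6),
    group_labels: tuple[str, str] = ("OWV", "NWV"),
    planted_sites: dict[str, list[tuple[int, str, str]]] | None = None,
    focal_sites: dict[str, list[tuple[int, str]]] | None = None,
    noise_rate: float = 0.01,
    constraint_mode: bool = True,
    between_group_divergence: dict[str, float] | float = 0.0,
    seed: int = 0,
) -> tuple[list[AlignmentBlock], GroupPartition, SyntheticTruth]:
    """Two clades of gapless protein alignments with planted substitutions.

    Per gene, an ancestral sequence is drawn; group A and group B each
    receive one residue of every planted pair ``(column, res_a, res_b)``.
    ``between_group_divergence`` plants additional random differing columns
    so that round(q x length) columns separate the clades per gene — with no
    noise, every cross-clade p-distance then equals 100q exactly.  The focal
    taxon (first member of group A) receives its private residues at
    ``focal_sites`` columns, where the rest of both clades keep the ancestor.

    Within-group noise substitutes residues (uniformly over the 19
    alternatives) at non-planted columns with probability ``noise_rate`` per
    residue.  In constraint mode (the default, used for exact-recovery
    tests) at most one row mutates per column and never the focal row, so
    noise can make a column polymorphic but can never fabricate a spurious
    group-conserved or focal-private site.  All planted truth is returned.
    """
    if gene_lengths is None:
        gene_lengths = default_gene_lengths()
    planted_sites = {g: list(v) for g, v in (planted_sites or {}).items()}
    focal_sites = {g: list(v) for g, v in (focal_sites or {}).items()}
    label_a, label_b = group_labels
    n_a, n_b = group_sizes
    if n_a < 2 or n_b < 1:
        raise ValueError("need >= 2 taxa in group A (for focal analyses) and >= 1 in group B")
    taxa_a = [f"{label_a}_{i + 1}" for i in range(n_a)]
    taxa_b = [f"{label_b}_{i + 1}" for i in range(n_b)]
    focal = taxa_a[0]
    rng = np.random.default_rng(seed)

    if isinstance(between_group_divergence, dict):
        divergence = {g: float(between_group_divergence.get(g, 0.0)) for g in gene_lengths}
    else:
        divergence = {g: float(between_group_divergence) for g in gene_lengths}

    truth = SyntheticTruth(seed=seed, between_group_divergence=divergence)
    blocks: list[AlignmentBlock] = []
    for gene in gene_lengths:
        length = gene_lengths[gene]
        ancestor = [_RESIDUES[i] for i in rng.integers(0, 20, size=length)]
        plants = list(planted_sites.get(gene, []))
        for col, ra, rb in plants:
            if not (1 <= col <= length):
                raise ValueError(f"{gene}: planted column {col} outside 1..{length}")
            if ra == rb:
                raise ValueError(f"{gene} column {col}: planted residues are equal")
        focals = list(focal_sites.get(gene, []))
        taken = {c for c, *_ in plants} | {c for c, _ in focals}
        if len(taken) < len(plants) + len(focals):
            raise ValueError(f"{gene}: planted and focal columns must be distinct")

        # extra between-group divergence columns become planted pairs too
        n_extra = 0
        if divergence[gene] > 0:
            n_extra = max(round(divergence[gene] * length) - len(plants), 0)
        if n_extra > 0:
            free = [c for c in range(1, length + 1) if c not in taken]
            if n_extra > len(free):
                raise ValueError(f"{gene}: not enough free columns for divergence target")
            chosen = rng.choice(len(free), size=n_extra, replace=False)
            for k in sorted(chosen):
                col = free[int(k)]
                ra = ancestor[col - 1]
                rb = _RESIDUES[(_RESIDUES.index(ra) + 1 + int(rng.integers(0, 19))) % 20]
                plants.append((col, ra, rb))
                taken.add(col)
        plants.sort()

        # focal sites: ancestor must differ from the focal residue
        planted_focals: list[tuple[int, str, str]] = []
        for col, rf in focals:
            if not (1 <= col <= length):
                raise ValueError(f"{gene}: focal column {col} outside 1..{length}")
            if ancestor[col - 1] == rf:
                ancestor[col - 1] = _RESIDUES[(_RESIDUES.index(rf) + 1) % 20]
            planted_focals.append((col, ancestor[col - 1], rf))

        rows: dict[str, list[str]] = {}
        for t in taxa_a + taxa_b:
            row = list(ancestor)
            side = 1 if t in taxa_a else 2
            for col, ra, rb in plants:
                row[col - 1] = ra if side == 1 else rb
            if t == focal:
                for col, _, rf in planted_focals:
                    row[col - 1] = rf
            rows[t] = row

        noise_threshold = round(noise_rate * 10_000)
        eligible = [t for t in taxa_a + taxa_b if t != focal] if constraint_mode else taxa_a + taxa_b
        if constraint_mode:
            eligible = [
                t
                for t in eligible
                if (len(taxa_a) if t in taxa_a else len(taxa_b)) >= 2
            ]
        for col in range(1, length + 1):
            if col in taken:
                continue
            mutated_here = False
            for t in eligible:
                if int(rng.integers(0, 10_000)) >= noise_threshold:
                    continue
                if constraint_mode and mutated_here:
                    continue
                current = rows[t][col - 1]
                alt = _RESIDUES[(_RESIDUES.index(current) + 1 + int(rng.integers(0, 19))) % 20]
                rows[t][col - 1] = alt
                mutated_here = True

        blocks.append(AlignmentBlock(gene=gene, rows={t: "".join(r) for t, r in rows.items()}))
        truth.planted_group_sites[gene] = [(c, a, b) for c, a, b in plants]
        truth.planted_focal_sites[gene] = planted_focals

    assignment = {t: label_a for t in taxa_a}
    assignment.update({t: label_b for t in taxa_b})
    partition = GroupPartition(assignment=assignment, focal=focal)
    return blocks, partition, truth


# ---------------------------------------------------------------------------
# Artifact output
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write the truth object as plain TSV files (plus scalar JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_scalars.json", "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "at_target": truth.at_target,
                "between_group_divergence": truth.between_group_divergence,
            },
            fh,
            indent=2,
        )
    if truth.planted_ssrs:
        with open(outdir / "truth_ssrs.tsv", "w") as fh:
            fh.write("motif\trepeats\tstart\n")
            for m, r, s in truth.planted_ssrs:
                fh.write(f"{m}\t{r}\t{s}\n")
    if truth.planted_group_sites:
        with open(outdir / "truth_group_sites.tsv", "w") as fh:
            fh.write("gene\tcolumn\tresidue_a\tresidue_b\n")
            for gene, sites in truth.planted_group_sites.items():
                for c, a, b in sites:
                    fh.write(f"{gene}\t{c}\t{a}\t{b}\n")
    if truth.planted_focal_sites:
        with open(outdir / "truth_focal_sites.tsv", "w") as fh:
            fh.write("gene\tcolumn\tresidue_group\tresidue_focal\n")
            for gene, sites in truth.planted_focal_sites.items():
                for c, a, b in sites:
                    fh.write(f"{gene}\t{c}\t{a}\t{b}\n")
    if truth.codon_tallies:
        with open(outdir / "truth_codon_tallies.tsv", "w") as fh:
            fh.write("codon\tcount\n")
            for codon in sorted(truth.codon_tallies):
                fh.write(f"{codon}\t{truth.codon_tallies[codon]}\n")


def write_dataset(
    outdir: str | Path,
    genome: GenomeRecord | None = None,
    layout: FeatureTable | None = None,
    blocks: list[AlignmentBlock] | None = None,
    partition: GroupPartition | None = None,
    truth: SyntheticTruth | None = None,
) -> None:
    """Write a full synthetic dataset in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genome is not None:
        write_fasta([genome], outdir / "genome.fasta")
    if layout is not None:
        write_feature_table(layout, outdir / "features.tsv")
    if blocks is not None:
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for b in blocks:
            write_alignment(b, aln_dir / f"{b.gene}.fasta")
    if partition is not None:
        write_groups(partition, outdir / "groups.tsv")
    if truth is not None:
        write_truth(truth, outdir)
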