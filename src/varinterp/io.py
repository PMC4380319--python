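"""Readers and writers for the on-disk formats the tool consumes.

Formats: protein FASTA (UniProt-style headers), two labeled-variant table
dialects (a 2-column ``id<TAB>label`` file and a 12-column per-variant
table), aligned-FASTA multiple sequence alignments, Pfam annotation tables
and amino-acid scale tables.  Labels are stored as {0 neutral, 1 disease}
on disk and in memory; conversion to the {-1, +1} convention happens only
inside the classifiers.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Literal

from Bio import SeqIO

from .genetic_code import AMINO_ACIDS, ConfigurationError

NEUTRAL = 0
DISEASE = 1

PFAM_MATCH_TYPES = ("family", "domain", "clan-member")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class VariantRecord:
    """One amino-acid substitution in a protein.

    ``position`` is 1-based into the protein sequence.  ``label`` is 0
    (neutral), 1 (disease-associated) or None (unlabeled).
    """

    protein_id: str
    position: int
    ref_aa: str
    mut_aa: str
    label: int | None = None
    window_seq: str | None = None
    ref_codon: str | None = None
    mut_codon: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"{self.variant_id}: position must be >= 1")
        if self.ref_aa == self.mut_aa:
            raise FormatError(f"{self.variant_id}: synonymous (ref == mut)")
        if self.label is not None and self.label not in (NEUTRAL, DISEASE):
            raise FormatError(f"{self.variant_id}: label must be 0 or 1")

    @property
    def variant_id(self) -> str:
        return f"{self.protein_id}_{self.position}_{self.ref_aa}_{self.mut_aa}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.ref_aa, self.mut_aa)

    def with_label(self, label: int) -> "VariantRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class MsaColumn:
    """Aligned residues at one master-sequence position.

    ``residues`` is the multiset of non-gap amino acids observed in the
    column (query included); ``n_proteins`` the number of sequences in the
    alignment; ``n_residues`` the number of non-gap residues in the column.
    """

    residues: Counter = field(default_factory=Counter)
    n_proteins: int = 0

    @property
    def n_residues(self) -> int:
        return sum(self.residues.values())

    def frequency(self, aa: str) -> float:
        n = self.n_residues
        return self.residues.get(aa, 0) / n if n else 0.0


@dataclass(frozen=True)
class Msa:
    """Per-column view of an alignment, indexed by 1-based master position."""

    query_id: str
    columns: tuple[MsaColumn, ...]

    def __len__(self) -> int:
        return len(self.columns)

    def column(self, position: int) -> MsaColumn:
        if not 1 <= position <= len(self.columns):
            raise IndexError(f"position {position} outside 1..{len(self.columns)}")
        return self.columns[position - 1]


@dataclass(frozen=True)
class PfamAnnotation:
    """A Pfam match span on a protein; ``start``/``end`` 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    match_type: str
    clan_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"{self.protein_id}: Pfam span start > end")
        if self.match_type not in PFAM_MATCH_TYPES:
            raise FormatError(f"unknown Pfam match type {self.match_type!r}")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ScaleSet:
    """K named amino-acid scales, each a complete 20-entry map."""

    names: tuple[str, ...]
    values: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name in self.names:
            table = self.values[name]
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ConfigurationError(
                    f"scale {name!r} missing amino acids {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.names)

    def value(self, name: str, aa: str) -> float:
        try:
            return self.values[name][aa]
        except KeyError as exc:
            raise ConfigurationError(f"scale {name!r} has no value for {aa!r}") from exc


def _accession(header_token: str) -> str:
    # "sp|Q9XYZ1|NAME" -> "Q9XYZ1"; plain ids pass through
    parts = header_token.split("|")
    return parts[1] if len(parts) >= 3 else header_token


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; ids reduced to accessions, sequences upper-cased."""
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = _accession(rec.id)
        if pid in proteins:
            raise FormatError(f"duplicate sequence id {pid!r} in {path}")
        proteins[pid] = str(rec.seq).upper()
    if not proteins:
        warnings.warn(f"no sequences found in {path}")
    return proteins


def write_fasta(proteins: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    """Split ``protein_pos_ref_mut``; parsed from the right so that protein
    ids containing underscores survive."""
    parts = variant_id.rsplit("_", 3)
    if len(parts) != 4:
        raise FormatError(f"malformed variant id {variant_id!r}")
    pid, pos_s, ref, mut = parts
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"malformed position in {variant_id!r}") from exc
    return pid, pos, ref, mut


def read_labeled_variants(
    path: str | Path,
    dialect: Literal["id_label", "twelve_col"] = "id_label",
    fail_fast: bool = False,
) -> tuple[list[VariantRecord], list[str]]:
    """Read a labeled variant table.

    ``id_label``: two tab-separated columns, ``protein_pos_ref_mut<TAB>label``,
    with an optional header line mentioning the label convention.
    ``twelve_col``: twelve tab-separated columns per variant (id, position,
    ref, mut, label, window sequence, window size, nucleotide window, ref
    codon, mut codon, then two structure-mapping columns which are ignored).

    Returns ``(records, errors)``; with ``fail_fast`` the first malformed
    record raises instead of being collected.
    """
    records: list[VariantRecord] = []
    errors: list[str] = []

    def bad(lineno: int, msg: str) -> None:
        full = f"{path}:{lineno}: {msg}"
        if fail_fast:
            raise FormatError(full)
        errors.append(full)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and ("neutral" in line.lower() or line.startswith("#")):
                continue  # tolerated header
            fields = line.split("\t")
            try:
                if dialect == "id_label":
                    if len(fields) != 2:
                        raise FormatError(f"expected 2 columns, got {len(fields)}")
                    pid, pos, ref, mut = parse_variant_id(fields[0])
                    rec = VariantRecord(pid, pos, ref, mut, label=int(fields[1]))
                elif dialect == "twelve_col":
                    if len(fields) != 12:
                        raise FormatError(f"expected 12 columns, got {len(fields)}")
                    rec = VariantRecord(
                        protein_id=fields[0],
                        position=int(fields[1]),
                        ref_aa=fields[2],
                        mut_aa=fields[3],
                        label=int(fields[4]),
                        window_seq=fields[5] or None,
                        ref_codon=fields[8] or None,
                        mut_codon=fields[9] or None,
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (FormatError, ValueError) as exc:
                bad(lineno, str(exc))
                continue
            records.append(rec)
    return records, errors


def write_labeled_variants(
    variants: Iterable[VariantRecord], path: str | Path, header: bool = True
) -> None:
    """Write the 2-column ``id<TAB>label`` dialect."""
    with open(path, "w") as fh:
        if header:
            fh.write("# variant_id\tlabel: neutral (0) and disease (1)\n")
        for v in variants:
            fh.write(f"{v.variant_id}\t{v.label}\n")


_GAP_CHARS = set("-.")


def msa_from_rows(query_id: str, seqs: list[str]) -> Msa:
    """Build an :class:`Msa` from aligned strings; ``seqs[0]`` is the master.

    Columns where the master has a gap are dropped so column ``j`` maps to
    master residue ``j`` (1-based).  Lower-case and gap characters in
    homolog rows count as gaps.
    """
    if not seqs:
        raise FormatError("empty alignment")
    master = seqs[0]
    width = len(master)
    for k, seq in enumerate(seqs[1:], 2):
        if len(seq) != width:
            raise FormatError(
                f"ragged alignment: row {k} has length {len(seq)}, expected {width}"
            )
    n_proteins = len(seqs)
    columns: list[MsaColumn] = []
    for j, master_char in enumerate(master):
        if master_char in _GAP_CHARS:
            continue
        counts: Counter = Counter()
        for seq in seqs:
            ch = seq[j]
            if ch in _GAP_CHARS or ch.islower():
                continue
            counts[ch.upper()] += 1
        columns.append(MsaColumn(residues=counts, n_proteins=n_proteins))
    return Msa(query_id=query_id, columns=tuple(columns))


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA whose first record is the query/master sequence."""
    rows = list(SeqIO.parse(str(path), "fasta"))
    if not rows:
        raise FormatError(f"empty alignment {path}")
    try:
        return msa_from_rows(_accession(rows[0].id), [str(r.seq) for r in rows])
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_pfam_table(path: str | Path) -> list[PfamAnnotation]:
    """Read a Pfam annotation table: protein_id, start, end, match_type[, clan_id]."""
    annotations: list[PfamAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
        clan = fields[4] if len(fields) > 4 and fields[4] not in ("", "None") else None
        try:
            annotations.append(
                PfamAnnotation(fields[0], int(fields[1]), int(fields[2]), fields[3], clan)
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return annotations


def read_scales(source: str | Path | IO[str]) -> ScaleSet:
    """Read a scale table: header of K scale names, then 20 amino-acid rows."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError("empty scale table")
    header = lines[0].split("\t")
    names = tuple(header[1:])
    values: dict[str, dict[str, float]] = {name: {} for name in names}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(names) + 1:
            raise FormatError(f"scale row has {len(fields)} fields, expected {len(names) + 1}")
        aa = fields[0].upper()
        for name, raw in zip(names, fields[1:]):
            values[name][aa] = float(raw)
    return ScaleSet(names=names, values=values)


def write_scales(scales: ScaleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("aa\t" + "\t".join(scales.names) + "\n")
        for aa in AMINO_ACIDS:
            fh.write(aa + "\t" + "\t".join(repr(float(scales.values[n][aa])) for n in scales.names) + "\n")


def write_pfam_table(annotations: Iterable[PfamAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.start}\t{a.end}\t{a.match_type}\t{a.clan_id or 'None'}\n")
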