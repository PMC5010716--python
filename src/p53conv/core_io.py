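"""Input/output and domain extraction for aligned protein sequences.

This module holds the package's basic containers — species metadata, domain
coordinate specifications, and protein alignments — together with the
coordinate machinery that turns "positions on an ungapped reference sequence"
(the protein-biology convention: 1-based, inclusive) into alignment columns,
and the gap-removal rules used to cut per-domain sequence fragments out of a
master alignment.

Alignment computation itself is out of scope: this package consumes
pre-aligned FASTA (e.g. a MAFFT product) and never realigns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity codes retained in sequences but treated as missing sites
#: when computing distances.
AMBIGUOUS_AA = frozenset("XBZ")

GAP_CHARS = frozenset("-")

_ALLOWED_CHARS = STANDARD_AA | AMBIGUOUS_AA | GAP_CHARS

#: Stress-adaptation group labels. ``hypoxic`` species endure acute,
#: fluctuating oxygen deprivation (subterranean and diving mammals);
#: ``metabolic`` species endure other metabolic stresses (hibernation,
#: dehydration, flight, chronic hypoxia); ``non_stress`` species endure
#: neither; ``additional`` species could not be classified.
GROUPS = ("hypoxic", "metabolic", "non_stress", "additional")

#: Default human p53 domain map (1-based inclusive coordinates on the
#: ungapped human p53 sequence, UniProt P04637 numbering). TD/RD ("TDRD")
#: overlaps NLS; overlapping domains are permitted. Override via
#: :func:`read_domain_map` for other references or boundary conventions.
DEFAULT_P53_DOMAINS: dict[str, "DomainSpec"]


class CoreIOError(ValueError):
    """Raised for malformed metadata tables, alignments, or domain maps."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species metadata table."""

    species_id: str
    group: str
    clade: str = ""
    accession: str | None = None
    body_mass: float | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise CoreIOError("species_id must be non-empty")
        if self.group not in GROUPS:
            raise CoreIOError(
                f"unknown group {self.group!r} for species {self.species_id!r}; "
                f"expected one of {GROUPS}"
            )


@dataclass(frozen=True)
class DomainSpec:
    """A named domain given by 1-based inclusive coordinates on an
    ungapped reference sequence."""

    name: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.ref_start <= self.ref_end):
            raise CoreIOError(
                f"domain {self.name!r}: need 1 <= ref_start <= ref_end, "
                f"got {self.ref_start}..{self.ref_end}"
            )

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


DEFAULT_P53_DOMAINS = {
    "TAD1": DomainSpec("TAD1", 1, 40),
    "TAD2": DomainSpec("TAD2", 41, 61),
    "PRD": DomainSpec("PRD", 64, 92),
    "DBD": DomainSpec("DBD", 94, 312),
    "NLS": DomainSpec("NLS", 316, 325),
    "TDRD": DomainSpec("TDRD", 323, 393),
}


class Alignment:
    """An ordered multiple protein alignment.

    Rows are (species_id, gapped sequence) pairs; all rows have equal
    length, ids are unique, and residues are uppercase amino acids,
    ambiguity codes (X/B/Z) or gaps ('-').
    """

    def __init__(self, rows: Iterable[tuple[str, str]]):
        ids: list[str] = []
        seqs: list[str] = []
        for sid, seq in rows:
            ids.append(sid)
            seqs.append(seq.upper().replace(".", "-"))
        if not ids:
            raise CoreIOError("alignment has no sequences")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CoreIOError(f"duplicate sequence ids in alignment: {dup}")
        width = len(seqs[0])
        for sid, seq in zip(ids, seqs):
            if len(seq) != width:
                raise CoreIOError(
                    f"not aligned: sequence {sid!r} has length {len(seq)}, "
                    f"expected {width}"
                )
            bad = set(seq) - _ALLOWED_CHARS
            if bad:
                raise CoreIOError(
                    f"sequence {sid!r} contains non-amino-acid symbols: {sorted(bad)}"
                )
        self._ids: tuple[str, ...] = tuple(ids)
        self._seqs: tuple[str, ...] = tuple(seqs)

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def width(self) -> int:
        return len(self._seqs[0])

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self):
        return iter(zip(self._ids, self._seqs))

    def sequence(self, species_id: str) -> str:
        try:
            return self._seqs[self._ids.index(species_id)]
        except ValueError:
            raise CoreIOError(f"species {species_id!r} not in alignment") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._ids

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self._ids == other._ids
            and self._seqs == other._seqs
        )

    def __repr__(self) -> str:
        return f"Alignment({len(self)} sequences x {self.width} columns)"


@dataclass(frozen=True)
class DomainFragmentSet:
    """Per-species ungapped (or column-filtered) fragments of one domain.

    ``columns`` records the 1-based alignment columns the fragments were cut
    from (before any gap removal), as provenance.
    """

    domain: str
    fragments: Mapping[str, str]
    columns: tuple[int, ...]
    mode: str = "complete_deletion"

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(self.fragments)

    def fragment(self, species_id: str) -> str:
        try:
            return self.fragments[species_id]
        except KeyError:
            raise CoreIOError(
                f"species {species_id!r} missing from domain {self.domain!r}"
            ) from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a TSV species metadata table.

    Requires a header with at least ``species_id`` and ``group``; optional
    columns ``clade``, ``accession`` and ``body_mass`` are carried along.
    Records are returned in file order.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise CoreIOError(f"species table {path} is empty") from None
    for col in ("species_id", "group"):
        if col not in df.columns:
            raise CoreIOError(f"species table {path} lacks required column {col!r}")
    if len(df) == 0:
        raise CoreIOError(f"species table {path} has no rows")
    dup = df["species_id"][df["species_id"].duplicated()].tolist()
    if dup:
        raise CoreIOError(f"duplicate species_id in {path}: {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        mass = row.get("body_mass")
        records.append(
            SpeciesRecord(
                species_id=row["species_id"],
                group=row["group"],
                clade="" if pd.isna(row.get("clade", "")) else str(row.get("clade", "")),
                accession=None if pd.isna(row.get("accession")) else row.get("accession"),
                body_mass=None if mass is None or pd.isna(mass) else float(mass),
            )
        )
    return records


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "group": [r.group for r in records],
            "clade": [r.clade for r in records],
            "accession": [r.accession or "" for r in records],
            "body_mass": ["" if r.body_mass is None else r.body_mass for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def species_by_group(records: Sequence[SpeciesRecord]) -> dict[str, list[str]]:
    """Group -> ordered species_id list."""
    out: dict[str, list[str]] = {g: [] for g in GROUPS}
    for r in records:
        out[r.group].append(r.species_id)
    return out


def read_alignment(path: str | Path | io.TextIOBase) -> Alignment:
    """Read an aligned protein FASTA. Sequences are uppercased and '.'
    gaps normalized to '-'; unequal row lengths raise."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise CoreIOError(f"no FASTA records found in {path}")
    return Alignment((rec.id, str(rec.seq)) for rec in records)


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write FASTA; round-trips sequence content byte-identically modulo
    line wrapping."""
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), wrap):
                fh.write(s[i : i + wrap] + "\n")


def write_fragments(frags: DomainFragmentSet, path: str | Path, wrap: int = 60) -> None:
    """Write a fragment set as FASTA (one record per species)."""
    with open(path, "w") as fh:
        for sid, frag in frags.fragments.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(frag), wrap):
                fh.write(frag[i : i + wrap] + "\n")


def read_domain_map(path: str | Path) -> dict[str, DomainSpec]:
    """Read a flat key-value domain map.

    Format, one domain per line::

        domain.TAD2 = 41-61

    Blank lines and ``#`` comments are ignored. Names must be unique;
    overlapping coordinate ranges are permitted.
    """
    domains: dict[str, DomainSpec] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            key, value = (part.strip() for part in line.split("=", 1))
            prefix, name = key.split(".", 1)
            if prefix != "domain" or not name:
                raise ValueError
            start_s, end_s = value.split("-", 1)
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise CoreIOError(
                f"{path}:{lineno}: cannot parse domain line {raw!r} "
                "(expected 'domain.NAME = START-END')"
            ) from None
        if name in domains:
            raise CoreIOError(f"{path}:{lineno}: duplicate domain {name!r}")
        domains[name] = DomainSpec(name, start, end)
    if not domains:
        raise CoreIOError(f"domain map {path} defines no domains")
    return domains


def write_domain_map(domains: Mapping[str, DomainSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, dom in domains.items():
            fh.write(f"domain.{name} = {dom.ref_start}-{dom.ref_end}\n")


# ---------------------------------------------------------------------------
# coordinate mapping and extraction
# ---------------------------------------------------------------------------

def map_reference_coordinates(
    aln: Alignment, ref_id: str, dom: DomainSpec
) -> list[int]:
    """Map a domain on the ungapped reference to alignment columns.

    Returns the 1-based alignment columns whose reference residue index
    (counting non-gap reference characters) lies in
    ``[dom.ref_start, dom.ref_end]``. Columns where the reference carries a
    gap are included when they fall strictly inside the domain span, i.e.
    insertions relative to the reference between two in-domain reference
    residues belong to the domain.
    """
    ref_seq = aln.sequence(ref_id)
    ungapped_len = sum(1 for c in ref_seq if c not in GAP_CHARS)
    if dom.ref_end > ungapped_len:
        raise CoreIOError(
            f"domain {dom.name!r} ends at {dom.ref_end} but ungapped reference "
            f"{ref_id!r} has only {ungapped_len} residues"
        )
    columns: list[int] = []
    residue_idx = 0  # index of the last reference residue seen
    for col, char in enumerate(ref_seq, start=1):
        if char in GAP_CHARS:
            # insertion relative to the reference: inside the domain iff it
            # sits between residue ref_start..ref_end-1 and the next residue
            if dom.ref_start <= residue_idx < dom.ref_end:
                columns.append(col)
        else:
            residue_idx += 1
            if dom.ref_start <= residue_idx <= dom.ref_end:
                columns.append(col)
    return columns


def extract_domain(
    aln: Alignment,
    columns: Sequence[int],
    mode: str = "complete_deletion",
    domain: str = "domain",
) -> DomainFragmentSet:
    """Cut per-species fragments out of the alignment at the given 1-based
    columns, removing gaps.

    ``complete_deletion`` drops every selected column in which at least one
    sequence has a gap (fragments keep equal length and positional
    correspondence). ``per_sequence_degap`` strips gap characters
    independently per sequence (fragments may differ in length; distance
    computation downstream requires equal lengths, so this mode is meant
    for users who re-align the fragments externally).
    """
    if not columns:
        raise CoreIOError("empty column list")
    if mode not in ("complete_deletion", "per_sequence_degap"):
        raise CoreIOError(f"unknown extraction mode {mode!r}")
    width = aln.width
    for col in columns:
        if not (1 <= col <= width):
            raise CoreIOError(f"column {col} outside alignment width {width}")

    sub = {sid: "".join(seq[c - 1] for c in columns) for sid, seq in aln}
    if mode == "complete_deletion":
        keep = [
            i
            for i in range(len(columns))
            if all(frag[i] not in GAP_CHARS for frag in sub.values())
        ]
        fragments = {
            sid: "".join(frag[i] for i in keep) for sid, frag in sub.items()
        }
    else:
        fragments = {
            sid: "".join(c for c in frag if c not in GAP_CHARS)
            for sid, frag in sub.items()
        }
    return DomainFragmentSet(
        domain=domain, fragments=fragments, columns=tuple(columns), mode=mode
    )


def extract_all_domains(
    aln: Alignment,
    ref_id: str,
    domains: Mapping[str, DomainSpec],
    mode: str = "complete_deletion",
) -> dict[str, DomainFragmentSet]:
    """Map and extract every domain in a domain map."""
    out = {}
    for name, dom in domains.items():
        cols = map_reference_coordinates(aln, ref_id, dom)
        out[name] = extract_domain(aln, cols, mode=mode, domain=name)
    return out
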