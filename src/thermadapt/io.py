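"""Readers and writers for the external formats the pipeline touches.

Aligned protein multi-FASTA (one file per orthogroup), tab-separated
tables with a header row, and a flat key=value run configuration.  No
science lives here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("thermadapt")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: legal alignment alphabet: the 20 standard residues, unknown 'X', gap '-'
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

ROLES = ("foreground", "background", "excluded")


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad vocabulary, ...)."""


@dataclass(frozen=True)
class TaxonLabel:
    """One taxon's identity and its role in the population contrast."""

    taxon_id: str
    species: str
    location: str
    role: str  # foreground | background | excluded

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(
                f"unknown role {self.role!r} for taxon {self.taxon_id!r}; "
                f"allowed roles: {', '.join(ROLES)}"
            )


@dataclass
class AlignedOrthogroup:
    """Aligned protein sequences of one orthogroup.

    Sequences are stored uppercase over the alphabet of the 20 standard
    amino acids plus ``X`` (unknown) and ``-`` (gap); ``.`` gaps are
    rejected.  All sequences have identical length.
    """

    orthogroup_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError(f"orthogroup {self.orthogroup_id!r} has no sequences")
        norm: dict[str, str] = {}
        lengths = set()
        for taxon, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise FormatError(
                    f"orthogroup {self.orthogroup_id!r}, record {taxon!r}: "
                    f"illegal characters {sorted(bad)}"
                )
            norm[taxon] = seq
            lengths.add(len(seq))
        if len(lengths) > 1:
            raise FormatError(
                f"orthogroup {self.orthogroup_id!r}: unequal alignment length "
                f"{sorted(lengths)}"
            )
        if lengths == {0}:
            raise FormatError(f"orthogroup {self.orthogroup_id!r}: empty alignment")
        self.sequences = norm

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def column(self, i: int) -> dict[str, str]:
        """Residues at 0-based column *i*, keyed by taxon."""
        return {t: s[i] for t, s in self.sequences.items()}


def read_msa_fasta(path: str | Path) -> AlignedOrthogroup:
    """Read one aligned orthogroup from a protein multi-FASTA file.

    The taxon identifier is the first whitespace-delimited token of the
    header; the orthogroup id is the file's stem.  Lowercase residues are
    uppercased.  Ragged records raise :class:`FormatError` naming the
    offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: expected >=2 aligned records, got {len(records)}")
    seqs: dict[str, str] = {}
    length = None
    for rec in records:
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate taxon {rec.id!r}")
        if length is not None and len(rec.seq) != length:
            raise FormatError(
                f"{path}: unequal alignment length at record {rec.id!r} "
                f"({len(rec.seq)} vs {length})"
            )
        length = len(rec.seq) if length is None else length
        seqs[rec.id] = str(rec.seq)
    return AlignedOrthogroup(orthogroup_id=path.stem, sequences=seqs)


def write_msa_fasta(aln: AlignedOrthogroup, path: str | Path) -> None:
    """Write an orthogroup alignment as multi-FASTA, preserving order."""
    with open(path, "w", encoding="utf-8") as fh:
        for taxon, seq in aln.sequences.items():
            fh.write(f">{taxon}\n{seq}\n")


def read_taxon_map(path: str | Path) -> dict[str, TaxonLabel]:
    """Read the taxon-to-group mapping TSV.

    Requires header columns ``taxon_id``, ``species``, ``location``,
    ``role`` and at least one foreground and one background entry.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon_id", "species", "location", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    mapping: dict[str, TaxonLabel] = {}
    for row in df.itertuples(index=False):
        if row.taxon_id in mapping:
            raise FormatError(f"{path}: duplicate taxon {row.taxon_id!r}")
        mapping[row.taxon_id] = TaxonLabel(
            taxon_id=row.taxon_id,
            species=row.species,
            location=row.location,
            role=row.role,
        )
    roles = {lbl.role for lbl in mapping.values()}
    if "foreground" not in roles:
        raise FormatError(f"{path}: no foreground taxon defined")
    if "background" not in roles:
        raise FormatError(f"{path}: no background taxon defined")
    return mapping


def _sanitize(value: object) -> object:
    # tabs/newlines inside string fields would break the TSV dialect
    if isinstance(value, str):
        return value.replace("\t", " ").replace("\n", " ")
    return value


def write_table(
    records: Sequence[Mapping] | Sequence[object] | pd.DataFrame,
    path: str | Path,
    digits: int = 6,
) -> None:
    """Write flat records as a header-bearing, newline-terminated TSV.

    Accepts a DataFrame, a sequence of mappings, or a sequence of
    dataclass instances sharing one field set.  Floats are rendered with
    *digits* significant decimals; an empty record list yields a
    header-only file only when a DataFrame (which carries its columns)
    is given.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
                rows.append(dataclasses.asdict(rec))
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].map(_sanitize)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{digits}g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Resolved run parameters, written beside every output for provenance.

    ``gas_constant`` is the universal gas constant in J·mol⁻¹·K⁻¹ and is
    fixed; it is carried here so reports are self-describing.
    """

    trim_max_gap_fraction: float = 0.2
    scenario: int = 3
    max_missing: int = 0
    var_window: int = 5
    var_max_distinct: int = 3
    arrhenius_window: tuple[float, float] = (2.0, 20.0)
    gas_constant: float = 8.314
    digits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_max_gap_fraction <= 1.0:
            raise ValueError("trim_max_gap_fraction must lie in [0, 1]")
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")
        if self.var_window < 1 or self.var_max_distinct < 1:
            raise ValueError("variability-filter parameters must be positive")
        lo, hi = self.arrhenius_window
        if not lo < hi:
            raise ValueError("arrhenius_window must satisfy low < high")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in dataclasses.fields(self):
                val = getattr(self, f.name)
                if isinstance(val, tuple):
                    val = ",".join(str(v) for v in val)
                fh.write(f"{f.name}={val}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        casts = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key not in casts:
                    raise FormatError(f"{path}: unknown config key {key!r}")
                if key == "arrhenius_window":
                    lo, hi = raw.split(",")
                    kwargs[key] = (float(lo), float(hi))
                elif key in ("scenario", "max_missing", "var_window",
                             "var_max_distinct", "digits", "seed"):
                    kwargs[key] = int(raw)
                else:
                    kwargs[key] = float(raw)
        return cls(**kwargs)
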