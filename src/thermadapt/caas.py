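"""Convergent amino acid substitution (CAAS) detection.

A CAAS column is one where the residues carried by the foreground taxa
are mutually exclusive with those of the background taxa.  Detection
runs per orthogroup in three stages: gap-based column trimming, a
sliding-window variability filter that masks hypervariable stretches
(where apparent convergence is more plausibly alignment noise), and the
column scan itself.

Scenario semantics (strictness of the residue-set constraint):

* scenario 1 — both groups fixed for a single residue each;
* scenario 2 — at least one group fixed (the other may segregate);
* scenario 3 — any two disjoint residue sets.

``X`` and ``-`` are both treated as missing data: neither is evidence
of a residue, and a column is only called when the number of missing
taxa does not exceed ``max_missing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from thermadapt.io import AlignedOrthogroup, RunConfig, TaxonLabel

logger = logging.getLogger("thermadapt")

MISSING = {"-", "X"}


@dataclass
class TrimResult:
    """Trimmed alignment plus the map from trimmed to original columns."""

    alignment: AlignedOrthogroup
    column_map: list[int]  # trimmed 0-based -> original 0-based, increasing

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("column_map must be strictly increasing")


@dataclass(frozen=True)
class CAASRecord:
    """One convergent column.  Columns are 1-based in reports."""

    orthogroup_id: str
    column_trimmed: int
    column_original: int
    fg_residues: frozenset[str]
    bg_residues: frozenset[str]
    scenario: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.fg_residues & self.bg_residues:
            raise ValueError("foreground and background residue sets must be disjoint")
        if not self.fg_residues or not self.bg_residues:
            raise ValueError("residue sets must be non-empty")

    def as_row(self) -> dict:
        return {
            "orthogroup_id": self.orthogroup_id,
            "column_trimmed": self.column_trimmed,
            "column_original": self.column_original,
            "fg_residues": "".join(sorted(self.fg_residues)),
            "bg_residues": "".join(sorted(self.bg_residues)),
            "scenario": self.scenario,
            "n_missing": self.n_missing,
        }


def trim_alignment(
    aln: AlignedOrthogroup, max_gap_fraction: float = 0.2
) -> TrimResult:
    """Drop columns whose gap fraction exceeds *max_gap_fraction*.

    A single per-column threshold on the fraction of ``-`` cells stands
    in for gap-heuristic trimmers; the retained-column map allows every
    call to be reported against original coordinates.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    n_taxa = len(aln.sequences)
    seqs = list(aln.sequences.values())
    keep = [
        i
        for i in range(aln.length)
        if sum(s[i] == "-" for s in seqs) / n_taxa <= max_gap_fraction
    ]
    if not keep:
        logger.warning(
            "orthogroup %s: all columns removed by trimming", aln.orthogroup_id
        )
        # represent the empty trim as a zero-column map with the original
        # taxa; callers must check column_map before scanning
        return TrimResult(alignment=aln, column_map=[])
    trimmed = AlignedOrthogroup(
        aln.orthogroup_id,
        {t: "".join(s[i] for i in keep) for t, s in aln.sequences.items()},
    )
    return TrimResult(alignment=trimmed, column_map=keep)


def variability_filter(
    aln: AlignedOrthogroup, window: int = 5, max_distinct: int = 3
) -> set[int]:
    """Mask columns lying in hypervariable sliding windows.

    Every window of *window* consecutive columns whose mean number of
    distinct non-gap residues per column exceeds *max_distinct* has all
    its columns masked (0-based).  Masked columns stay in the alignment
    but are excluded from CAAS calling.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seqs = list(aln.sequences.values())
    distinct = [
        len({s[i] for s in seqs} - {"-"}) for i in range(aln.length)
    ]
    masked: set[int] = set()
    for start in range(0, aln.length - window + 1):
        win = distinct[start : start + window]
        if sum(win) / window > max_distinct:
            masked.update(range(start, start + window))
    return masked


def _split_groups(
    groups: Mapping[str, str] | Mapping[str, TaxonLabel],
) -> tuple[list[str], list[str]]:
    fg, bg = [], []
    for taxon, role in groups.items():
        role = role.role if isinstance(role, TaxonLabel) else role
        if role == "foreground":
            fg.append(taxon)
        elif role == "background":
            bg.append(taxon)
    if not fg or not bg:
        raise ValueError("need >=1 foreground and >=1 background taxon")
    return fg, bg


def _scenario_ok(fg_set: frozenset, bg_set: frozenset, scenario: int) -> bool:
    if scenario == 1:
        return len(fg_set) == 1 and len(bg_set) == 1
    if scenario == 2:
        return min(len(fg_set), len(bg_set)) == 1
    if scenario == 3:
        return True
    raise ValueError(f"unknown scenario {scenario!r}")


def detect_caas(
    aln: AlignedOrthogroup,
    groups: Mapping[str, str] | Mapping[str, TaxonLabel],
    scenario: int = 3,
    max_missing: int = 0,
    masked: Iterable[int] = (),
    column_map: Sequence[int] | None = None,
) -> list[CAASRecord]:
    """Scan every unmasked column of one alignment for convergence.

    A record is emitted for a column iff the foreground and background
    residue sets (gaps and ``X`` removed) are non-empty and disjoint,
    at most *max_missing* foreground/background taxa are missing, and
    the scenario constraint holds.  Taxa absent from *groups* or marked
    ``excluded`` are ignored.  *column_map* translates trimmed to
    original coordinates for reporting (identity when omitted).
    """
    fg, bg = _split_groups(groups)
    missing_in_aln = [t for t in fg + bg if t not in aln.sequences]
    if missing_in_aln:
        raise ValueError(
            f"orthogroup {aln.orthogroup_id!r}: taxa not in alignment: "
            f"{missing_in_aln}"
        )
    masked = set(masked)
    records: list[CAASRecord] = []
    for col in range(aln.length):
        if col in masked:
            continue
        fg_res = [aln.sequences[t][col] for t in fg]
        bg_res = [aln.sequences[t][col] for t in bg]
        n_missing = sum(r in MISSING for r in fg_res + bg_res)
        fg_set = frozenset(r for r in fg_res if r not in MISSING)
        bg_set = frozenset(r for r in bg_res if r not in MISSING)
        if not fg_set or not bg_set:
            continue  # a group vanished at this column; skip, not an error
        if n_missing > max_missing:
            continue
        if fg_set & bg_set:
            continue
        if not _scenario_ok(fg_set, bg_set, scenario):
            continue
        original = column_map[col] if column_map is not None else col
        records.append(
            CAASRecord(
                orthogroup_id=aln.orthogroup_id,
                column_trimmed=col + 1,
                column_original=original + 1,
                fg_residues=fg_set,
                bg_residues=bg_set,
                scenario=scenario,
                n_missing=n_missing,
            )
        )
    return records


def scan_collection(
    orthogroups: Iterable[AlignedOrthogroup],
    groups: Mapping[str, str] | Mapping[str, TaxonLabel],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Trim, filter and scan a collection of orthogroups.

    Returns the concatenated CAAS table sorted by orthogroup id then
    column, with the :class:`CAASRecord` fields as columns (1-based
    coordinates, residue sets as sorted strings).
    """
    config = config or RunConfig()
    all_records: list[CAASRecord] = []
    for aln in orthogroups:
        trim = trim_alignment(aln, config.trim_max_gap_fraction)
        if not trim.column_map:
            logger.info("orthogroup %s: empty after trimming, skipped",
                        aln.orthogroup_id)
            continue
        masked = variability_filter(
            trim.alignment, config.var_window, config.var_max_distinct
        )
        recs = detect_caas(
            trim.alignment,
            groups,
            scenario=config.scenario,
            max_missing=config.max_missing,
            masked=masked,
            column_map=trim.column_map,
        )
        logger.info("orthogroup %s: %d CAAS", aln.orthogroup_id, len(recs))
        all_records.extend(recs)
    all_records.sort(key=lambda r: (r.orthogroup_id, r.column_trimmed))
    columns = [
        "orthogroup_id", "column_trimmed", "column_original",
        "fg_residues", "bg_residues", "scenario", "n_missing",
    ]
    return pd.DataFrame([r.as_row() for r in all_records], columns=columns)


class CAASScan:
    """Convenience wrapper bundling inputs for a scan.

    ``CAASScan(orthogroups, groups, config).run()`` returns a
    :class:`CAASScanResults` holding the record table and per-orthogroup
    counts.
    """

    def __init__(
        self,
        orthogroups: Sequence[AlignedOrthogroup],
        groups: Mapping[str, str] | Mapping[str, TaxonLabel],
        config: RunConfig | None = None,
    ) -> None:
        self.orthogroups = list(orthogroups)
        self.groups = groups
        self.config = config or RunConfig()

    def run(self) -> "CAASScanResults":
        table = scan_collection(self.orthogroups, self.groups, self.config)
        return CAASScanResults(table, n_orthogroups=len(self.orthogroups))


class CAASScanResults:
    def __init__(self, table: pd.DataFrame, n_orthogroups: int) -> None:
        self.table = table
        self.n_orthogroups = n_orthogroups

    @property
    def n_caas(self) -> int:
        return len(self.table)

    def counts_per_orthogroup(self) -> pd.Series:
        return self.table.groupby("orthogroup_id").size()

    def summary(self) -> str:
        lines = [
            f"CAAS scan: {self.n_caas} convergent columns "
            f"across {self.n_orthogroups} orthogroups",
        ]
        for og, n in self.counts_per_orthogroup().items():
            lines.append(f"  {og}: {n}")
        return "\n".join(lines)
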