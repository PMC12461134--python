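"""Characterisation of CAAS tables and sequence composition.

The central statistic is the amino-acid flux D = (C − R)/(C + R),
where C counts the events in which an amino acid was gained (created)
in the foreground population and R the events in which it was lost.
D = +1 means pure gain, −1 pure loss, 0 balance; it is undefined (NaN)
for residues never involved in a substitution.

Also provided: the 20×20 exchange matrix (background residue →
foreground residue, singleton-singleton records only), residue-class
tallies (hydrophilic / hydrophobic / negatively / positively charged),
the arginine/lysine ratio (a classical cold-adaptation indicator:
cold-adapted proteomes tend to favour lysine), average molecular
weight, and functional-category summaries in the COG style.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from thermadapt.io import AMINO_ACIDS
from thermadapt.caas import CAASRecord

#: residue classes; the four sets partition the 20 standard amino acids
RESIDUE_CLASSES = {
    "hydrophilic": frozenset("NQSTY"),
    "hydrophobic": frozenset("ACFGILMPVW"),
    "negative": frozenset("DE"),
    "positive": frozenset("HKR"),
}

#: average (isotope-weighted) residue masses in daltons
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153


def residue_class(aa: str) -> str:
    for name, members in RESIDUE_CLASSES.items():
        if aa in members:
            return name
    raise ValueError(f"not a standard amino acid: {aa!r}")


def flux(c: int, r: int) -> float:
    """Net relative gain D = (C − R)/(C + R); NaN when C + R = 0."""
    if c < 0 or r < 0:
        raise ValueError("counts must be non-negative")
    if c + r == 0:
        return float("nan")
    return (c - r) / (c + r)


def _iter_sets(records) -> Iterable[tuple[frozenset, frozenset]]:
    for rec in records:
        if isinstance(rec, CAASRecord):
            yield rec.fg_residues, rec.bg_residues
        else:  # table row with sorted residue strings
            yield frozenset(rec["fg_residues"]), frozenset(rec["bg_residues"])


def count_gain_loss(
    records: Sequence[CAASRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally gains/losses per amino acid and the exchange matrix.

    Each distinct residue in a record's foreground set contributes one
    gain event, each distinct background residue one loss event (one
    event per residue, not per taxon: a convergent column is one
    substitution event).  Singleton-singleton records additionally
    increment the exchange matrix entry (background → foreground).

    Returns ``(flux_table, exchange_matrix)``: the flux table indexed
    by amino acid with columns gains, losses, flux; the matrix a 20×20
    frame, rows = background (lost) residue, columns = foreground
    (gained) residue.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    aa_list = list(AMINO_ACIDS)
    gains = {a: 0 for a in aa_list}
    losses = {a: 0 for a in aa_list}
    matrix = pd.DataFrame(0, index=aa_list, columns=aa_list, dtype=int)
    for fg_set, bg_set in _iter_sets(records):
        for a in fg_set:
            gains[a] += 1
        for b in bg_set:
            losses[b] += 1
        if len(fg_set) == 1 and len(bg_set) == 1:
            (a,), (b,) = tuple(fg_set), tuple(bg_set)
            matrix.loc[b, a] += 1
    flux_table = pd.DataFrame(
        {
            "amino_acid": aa_list,
            "gains": [gains[a] for a in aa_list],
            "losses": [losses[a] for a in aa_list],
        }
    ).set_index("amino_acid")
    flux_table["flux"] = [
        flux(gains[a], losses[a]) for a in aa_list
    ]
    return flux_table, matrix


def class_tally(
    records: Sequence[CAASRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Residue-class counts and proportions of CAAS residues per group."""
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    counts = {
        (grp, cls): 0
        for grp in ("foreground", "background")
        for cls in RESIDUE_CLASSES
    }
    for fg_set, bg_set in _iter_sets(records):
        for a in fg_set:
            counts[("foreground", residue_class(a))] += 1
        for b in bg_set:
            counts[("background", residue_class(b))] += 1
    rows = []
    for grp in ("foreground", "background"):
        total = sum(counts[(grp, cls)] for cls in RESIDUE_CLASSES)
        for cls in RESIDUE_CLASSES:
            n = counts[(grp, cls)]
            rows.append(
                {
                    "group": grp,
                    "residue_class": cls,
                    "count": n,
                    "proportion": n / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def arg_lys_ratio(sequences: Iterable[str] | str) -> float:
    """Arginine/lysine count ratio over a sequence collection.

    Gaps and unknowns are ignored.  Returns NaN when no lysine is
    present (undefined rather than an error).
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    n_arg = n_lys = 0
    for seq in sequences:
        seq = seq.upper()
        n_arg += seq.count("R")
        n_lys += seq.count("K")
    if n_lys == 0:
        return float("nan")
    return n_arg / n_lys


def molecular_weight(sequence: str) -> float:
    """Average molecular weight of a protein chain in daltons.

    Sum of average residue masses plus one water (18.02 Da).  The empty
    chain degenerately returns the water mass.  Unknown residues raise
    with their 1-based position.
    """
    total = _WATER_MASS
    for pos, aa in enumerate(sequence.upper(), start=1):
        try:
            total += _RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos}"
            ) from None
    return total


def category_summary(
    counts: pd.DataFrame | Sequence[Mapping],
    digits: int = 2,
) -> pd.DataFrame:
    """Functional-category summary with within-category and overall shares.

    Input rows carry ``category``, ``subcategory`` and ``count``
    (pre-tallied, e.g. from a COG annotation).  Adds
    ``pct_within_category`` = 100·count/category_total and
    ``pct_of_all`` = 100·count/grand_total, rounded to *digits*
    decimals; the grand total is the sum over all rows.
    """
    df = pd.DataFrame(counts).copy()
    required = {"category", "subcategory", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    grand_total = df["count"].sum()
    cat_totals = df.groupby("category")["count"].transform("sum")
    df["pct_within_category"] = (100.0 * df["count"] / cat_totals).round(digits)
    df["pct_of_all"] = (100.0 * df["count"] / grand_total).round(digits)
    return df


def tally_annotated_caas(
    caas_table: pd.DataFrame,
    annotation: pd.DataFrame,
    record_id_cols: tuple[str, str] = ("orthogroup_id", "column_original"),
) -> pd.DataFrame:
    """Join CAAS records to (category, subcategory) annotations and tally.

    ``annotation`` carries the record-id columns plus ``category`` and
    ``subcategory``.  Records without an annotation are counted under
    ("Poorly characterized", "Function unknown (S)").  Annotation rows
    referencing unknown records are skipped with a warning.
    """
    import logging

    key = list(record_id_cols)
    known = set(map(tuple, caas_table[key].itertuples(index=False)))
    ann = annotation.copy()
    bad = [
        tuple(row) for row in ann[key].itertuples(index=False)
        if tuple(row) not in known
    ]
    if bad:
        logging.getLogger("thermadapt").warning(
            "%d annotation rows reference unknown CAAS records; skipped",
            len(bad),
        )
        mask = ann[key].apply(tuple, axis=1).isin(known)
        ann = ann[mask]
    merged = caas_table[key].merge(ann, on=key, how="left")
    merged["category"] = merged["category"].fillna("Poorly characterized")
    merged["subcategory"] = merged["subcategory"].fillna("Function unknown (S)")
    tallied = (
        merged.groupby(["category", "subcategory"])
        .size()
        .reset_index(name="count")
    )
    return category_summary(tallied)
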