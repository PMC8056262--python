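"""Public/private classification and fuzzy CDR3 matching to viral clonotypes.

A clonotype is *public* when its CDR3 amino-acid sequence appears in a local
reference of sequences seen in other individuals (a versioned snapshot; no
live database queries), *private* otherwise.

Similarity to virus-specific clonotypes uses unit-cost Levenshtein alignment
with a canonical traceback (diagonal > up > left at equal cost), so that
exactly one edit script is reported among co-optimal alignments. Edit
operations describe how the reference differs from the query, matching the
display convention of epitope databases: a *substitution* replaces a query
residue, an *insertion* is a residue present only in the reference, and a
*deletion* marks a query residue the reference lacks (rendered as a hyphen).

The text annotation renders the reference aligned against the query:
matched residues uppercase, substituted residues lowercase, inserted
residues in square brackets, deletions as ``-``. For example the query
``CASATALNYGYTF`` against reference ``CASASANYGYTF`` renders
``CASAsA-NYGYTF`` (one substitution, one deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

from .repertoire_io import AA_ALPHABET, FormatError
from .clonal_tracking import TopNList


class EditOp(NamedTuple):
    """One edit operation, positioned 1-based on the query.

    For an insertion, ``position`` is the query position before which the
    residue appears and ``from_char`` is empty; for a deletion ``to_char``
    is ``"-"``.
    """

    position: int
    kind: str  # "substitution" | "insertion" | "deletion"
    from_char: str
    to_char: str


@dataclass
class Cdr3Match:
    query: str
    reference: str
    distance: int
    ops: tuple[EditOp, ...]
    annotation: str
    metadata: dict | None = None


@dataclass
class PublicReference:
    """Local snapshot of CDR3 sequences observed across individuals."""

    entries: dict[str, int]  # cdr3_aa -> number of distinct subjects
    source_label: str = ""

    def __post_init__(self) -> None:
        for cdr3, count in self.entries.items():
            if count < 1:
                raise ValueError(f"subject_count for {cdr3} must be >= 1")

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str | None = None) -> "PublicReference":
        df = pd.read_csv(path, sep="\t", dtype={"cdr3_aa": str})
        for col in ("cdr3_aa", "subject_count"):
            if col not in df.columns:
                raise FormatError(f"public reference {path} is missing column {col!r}")
        entries = dict(zip(df["cdr3_aa"].str.upper(), df["subject_count"].astype(int)))
        return cls(entries=entries, source_label=source_label or str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.entries.items()), columns=["cdr3_aa", "subject_count"]
        ).to_csv(path, sep="\t", index=False)


VIRAL_COLUMNS = ["cdr3_aa", "epitope", "antigen", "species", "mhc_allele", "v_call", "j_call"]

# VDJdb export header -> canonical column names
_VDJDB_MAP = {
    "cdr3": "cdr3_aa",
    "antigen.epitope": "epitope",
    "antigen.gene": "antigen",
    "species": "species",
    "mhc.a": "mhc_allele",
    "v.segm": "v_call",
    "j.segm": "j_call",
}


@dataclass
class ViralCdr3Table:
    """Virus-specific CDR3 reference with epitope/antigen/species/MHC metadata."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VIRAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"viral table is missing columns {missing}")
        if (self.df["cdr3_aa"].str.len() == 0).any():
            raise ValueError("viral table contains empty cdr3_aa entries")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ViralCdr3Table":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df = df.rename(columns=_VDJDB_MAP)
        for col in VIRAL_COLUMNS:
            if col not in df.columns:
                if col in ("mhc_allele", "v_call", "j_call"):
                    df[col] = ""
                else:
                    raise FormatError(f"viral table {path} is missing column {col!r}")
        df = df[VIRAL_COLUMNS].copy()
        df["cdr3_aa"] = df["cdr3_aa"].str.upper()
        return cls(df=df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, columns=VIRAL_COLUMNS)

    def __len__(self) -> int:
        return len(self.df)


def _check_alphabet(seq: str, name: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-amino-acid characters {sorted(bad)}")


def edit_align(query: str, reference: str) -> Cdr3Match:
    """Unit-cost Levenshtein alignment of a query CDR3 to a reference CDR3.

    The traceback prefers match/substitution over deletion over insertion
    at equal cost, fixing one canonical edit script; ``distance == len(ops)``
    and applying the ops to the query yields the reference.
    """
    _check_alphabet(query, "query")
    _check_alphabet(reference, "reference")
    m, n = len(query), len(reference)
    dist = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        dist[i][0] = i
    for j in range(1, n + 1):
        dist[0][j] = j
    for i in range(1, m + 1):
        row, prev = dist[i], dist[i - 1]
        qc = query[i - 1]
        for j in range(1, n + 1):
            cost = 0 if qc == reference[j - 1] else 1
            row[j] = min(prev[j - 1] + cost, prev[j] + 1, row[j - 1] + 1)
    # canonical traceback from the end: diagonal > up (deletion) > left (insertion)
    ops_rev: list[EditOp] = []
    rendered_rev: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if query[i - 1] == reference[j - 1] else 1
            if dist[i][j] == dist[i - 1][j - 1] + cost:
                if cost:
                    ops_rev.append(EditOp(i, "substitution", query[i - 1], reference[j - 1]))
                    rendered_rev.append(reference[j - 1].lower())
                else:
                    rendered_rev.append(reference[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and dist[i][j] == dist[i - 1][j] + 1:
            ops_rev.append(EditOp(i, "deletion", query[i - 1], "-"))
            rendered_rev.append("-")
            i -= 1
            continue
        ops_rev.append(EditOp(i + 1, "insertion", "", reference[j - 1]))
        rendered_rev.append(f"[{reference[j - 1]}]")
        j -= 1
    return Cdr3Match(
        query=query,
        reference=reference,
        distance=dist[m][n],
        ops=tuple(reversed(ops_rev)),
        annotation="".join(reversed(rendered_rev)),
    )


def classify_public(
    cdr3_aa: str, reference: PublicReference, min_subjects: int = 1
) -> str:
    """``"public"`` iff the sequence is in the reference with enough subjects."""
    return (
        "public"
        if reference.entries.get(cdr3_aa.upper(), 0) >= min_subjects
        else "private"
    )


def _hla_matches(row_allele: str, hla_filter: set[str]) -> bool:
    allele = row_allele.upper().removeprefix("HLA-")
    for wanted in hla_filter:
        w = wanted.upper().removeprefix("HLA-")
        if allele.startswith(w) or w.startswith(allele):
            return True
    return False


def match_viral(
    query: str,
    table: ViralCdr3Table,
    max_distance: int = 2,
    hla_filter: set[str] | None = None,
) -> list[Cdr3Match]:
    """All viral-reference rows within ``max_distance`` edits of the query.

    Results are sorted by (distance, epitope, reference sequence) for
    determinism. ``hla_filter`` restricts candidate rows to the listed
    MHC alleles before matching.
    """
    if len(table) == 0:
        raise ValueError("viral reference table is empty")
    df = table.df
    if hla_filter:
        df = df[df["mhc_allele"].map(lambda a: _hla_matches(a, hla_filter))]
    hits: list[Cdr3Match] = []
    for row in df.itertuples(index=False):
        # length difference lower-bounds the edit distance
        if abs(len(row.cdr3_aa) - len(query)) > max_distance:
            continue
        match = edit_align(query, row.cdr3_aa)
        if match.distance <= max_distance:
            match.metadata = {
                "epitope": row.epitope,
                "antigen": row.antigen,
                "species": row.species,
                "mhc_allele": row.mhc_allele,
                "v_call": row.v_call,
                "j_call": row.j_call,
            }
            hits.append(match)
    hits.sort(key=lambda h: (h.distance, h.metadata["epitope"], h.reference))
    return hits


def annotate_top_clonotypes(
    top: TopNList,
    reference: PublicReference,
    viral: ViralCdr3Table | None,
    max_distance: int = 2,
    min_subjects: int = 1,
    hla_filter: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label each top-N clonotype public/private with its best viral match.

    Returns the annotated table and a summary holding the public/private
    split and the most abundant public and private clonotype (the layout of
    a per-sample "top public and private clonotypes" report).
    """
    rows = []
    for entry in top.entries.itertuples(index=False):
        publicity = classify_public(entry.cdr3_aa, reference, min_subjects)
        best = None
        if viral is not None and len(viral):
            hits = match_viral(entry.cdr3_aa, viral, max_distance, hla_filter)
            best = hits[0] if hits else None
        rows.append(
            {
                "rank": entry.rank,
                "cdr3_aa": entry.cdr3_aa,
                "templates": entry.templates,
                "frequency": entry.frequency,
                "publicity": publicity,
                "viral_reference": best.reference if best else "",
                "viral_distance": best.distance if best else pd.NA,
                "viral_annotation": best.annotation if best else "",
                "epitope": best.metadata["epitope"] if best else "",
                "antigen": best.metadata["antigen"] if best else "",
                "species": best.metadata["species"] if best else "",
                "mhc_allele": best.metadata["mhc_allele"] if best else "",
            }
        )
    annotated = pd.DataFrame(rows)
    n_public = int((annotated["publicity"] == "public").sum()) if len(annotated) else 0
    summary = {
        "sample_id": top.meta.sample_id,
        "n_top": len(annotated),
        "n_public": n_public,
        "n_private": len(annotated) - n_public,
        "public_fraction": n_public / len(annotated) if len(annotated) else float("nan"),
    }
    for label in ("public", "private"):
        subset = annotated[annotated["publicity"] == label]
        if len(subset):
            lead = subset.iloc[0]  # entries are rank-ordered
            summary[f"top_{label}"] = {
                "cdr3_aa": lead["cdr3_aa"],
                "frequency": float(lead["frequency"]),
                "viral_reference": lead["viral_reference"],
                "viral_distance": None if pd.isna(lead["viral_distance"]) else int(lead["viral_distance"]),
                "epitope": lead["epitope"],
                "species": lead["species"],
            }
        else:
            summary[f"top_{label}"] = None
    return annotated, summary
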