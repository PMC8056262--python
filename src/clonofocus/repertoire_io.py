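"""Reading, curation and aggregation of TCRβ rearrangement data.

Two tab-separated input dialects are supported:

``airr``
    AIRR Community Rearrangement schema columns
    (``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``, ``productive``).
``immunoseq``
    Adaptive immunoSEQ v2 export columns
    (``amino_acid``, ``v_gene``, ``j_gene``, ``templates``, ``frame_type``);
    ``frame_type == "In"`` maps to ``productive=True``.

Curation removes rearrangements that cannot be CDR3 amino-acid clonotypes:
junctions that do not start with the third framework cysteine (IMGT position
104), empty junctions, junctions containing a stop codon (``*``) or an
out-of-frame marker (``_``), and non-productive rearrangements.

Clonotype identity is the CDR3 amino-acid sequence alone; V/J gene calls are
carried as annotation (the call of the highest-count contributing
rearrangement) and never enter the grouping key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: characters tolerated in a raw (pre-curation) junction
PRE_CURATION_ALPHABET = AA_ALPHABET | {"*", "_"}

CLONOTYPE_COLUMNS = ["cdr3_aa", "v_call", "j_call", "templates", "frequency"]

#: curation removal reasons, in the order they are checked
CURATION_REASONS = (
    "empty_junction",
    "stop_codon",
    "out_of_frame",
    "non_productive",
    "no_framework_cysteine",
)


class FormatError(ValueError):
    """A required column is missing or a field cannot be interpreted."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but the operation is undefined on it."""


@dataclass(frozen=True)
class RearrangementRecord:
    """One sequenced TCRβ rearrangement.

    ``templates`` is the number of input DNA molecules supporting the
    rearrangement (a proxy for cell count in immunosequencing assays).
    """

    cdr3_aa: str
    v_call: str = ""
    j_call: str = ""
    templates: int = 1
    productive: bool = True

    def __post_init__(self) -> None:
        if self.templates < 0:
            raise ValueError(f"templates must be >= 0, got {self.templates}")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one repertoire sample within a study."""

    sample_id: str
    subject_id: str = ""
    compartment: str = "brain"
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in ("brain", "blood"):
            raise ValueError(
                f"compartment must be 'brain' or 'blood', got {self.compartment!r}"
            )


@dataclass
class ClonotypeTable:
    """Per-sample aggregation of rearrangements by CDR3 amino-acid sequence.

    ``df`` has columns ``cdr3_aa, v_call, j_call, templates, frequency``,
    one row per unique CDR3, sorted by descending templates then CDR3.
    Frequencies are the P_i of the clonality index and sum to 1.
    """

    meta: SampleMeta
    df: pd.DataFrame

    @property
    def total_templates(self) -> int:
        return int(self.df["templates"].sum())

    @property
    def n_unique(self) -> int:
        return len(self.df)

    @property
    def frequencies(self) -> np.ndarray:
        return self.df["frequency"].to_numpy(dtype=float)

    def cdr3_set(self) -> set[str]:
        return set(self.df["cdr3_aa"])

    def validate(self) -> None:
        if len(self.df) and abs(self.df["frequency"].sum() - 1.0) > 1e-9:
            raise ValueError("clonotype frequencies do not sum to 1")
        if self.df["cdr3_aa"].duplicated().any():
            raise ValueError("duplicate cdr3_aa rows in clonotype table")


_DIALECTS = {
    "airr": {
        "cdr3": "junction_aa",
        "v": "v_call",
        "j": "j_call",
        "count": "duplicate_count",
        "productive": "productive",
    },
    "immunoseq": {
        "cdr3": "amino_acid",
        "v": "v_gene",
        "j": "j_gene",
        "count": "templates",
        "productive": "frame_type",
    },
}

_TRUTHY = {"t", "true", "1", "yes", "y"}


def _parse_productive(value, dialect: str) -> bool:
    if dialect == "immunoseq":
        return str(value).strip().lower() == "in"
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in _TRUTHY


def read_rearrangements(path: str | Path, dialect: str = "airr") -> list[RearrangementRecord]:
    """Read a rearrangement TSV into records.

    Missing template counts default to 1 (with a warning): a sequenced
    rearrangement implies at least one template.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'airr' or 'immunoseq'")
    cols = _DIALECTS[dialect]
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read rearrangement file {path}: {exc}") from exc
    for key in ("cdr3", "v", "j", "count", "productive"):
        if cols[key] not in frame.columns:
            raise FormatError(
                f"{dialect} file {path} is missing required column {cols[key]!r}"
            )
    records: list[RearrangementRecord] = []
    n_defaulted = 0
    for row in frame.itertuples(index=False):
        raw_count = getattr(row, cols["count"])
        if raw_count is None or str(raw_count).strip() in ("", "nan", "null"):
            templates = 1
            n_defaulted += 1
        else:
            templates = int(float(raw_count))
        records.append(
            RearrangementRecord(
                cdr3_aa=str(getattr(row, cols["cdr3"])).strip().upper(),
                v_call=str(getattr(row, cols["v"])).strip(),
                j_call=str(getattr(row, cols["j"])).strip(),
                templates=templates,
                productive=_parse_productive(getattr(row, cols["productive"]), dialect),
            )
        )
    if n_defaulted:
        warnings.warn(
            f"{path}: {n_defaulted} rows had no template count; defaulted to 1",
            stacklevel=2,
        )
    return records


def write_rearrangements(
    records: Iterable[RearrangementRecord], path: str | Path, dialect: str = "airr"
) -> None:
    """Write records as a rearrangement TSV in the given dialect."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    rows = []
    for rec in records:
        if dialect == "airr":
            productive = "T" if rec.productive else "F"
        else:
            productive = "In" if rec.productive else "Out"
        rows.append(
            {
                cols["cdr3"]: rec.cdr3_aa,
                cols["v"]: rec.v_call,
                cols["j"]: rec.j_call,
                cols["count"]: rec.templates,
                cols["productive"]: productive,
            }
        )
    header = [cols["cdr3"], cols["v"], cols["j"], cols["count"], cols["productive"]]
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def _removal_reason(rec: RearrangementRecord) -> str | None:
    if not rec.cdr3_aa:
        return "empty_junction"
    if "*" in rec.cdr3_aa:
        return "stop_codon"
    if "_" in rec.cdr3_aa:
        return "out_of_frame"
    if not rec.productive:
        return "non_productive"
    if not rec.cdr3_aa.startswith("C"):
        return "no_framework_cysteine"
    return None


def curate(
    records: Sequence[RearrangementRecord],
) -> tuple[list[RearrangementRecord], dict[str, int]]:
    """Remove rearrangements that are not valid CDR3 amino-acid clonotypes.

    Returns the kept records and a report counting removals by reason
    (every reason key is present, zeroed when unused, plus ``kept``).
    Each record is tallied under the first matching reason.
    """
    report = {reason: 0 for reason in CURATION_REASONS}
    kept: list[RearrangementRecord] = []
    for rec in records:
        reason = _removal_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            report[reason] += 1
    report["kept"] = len(kept)
    return kept, report


def aggregate_clonotypes(
    records: Sequence[RearrangementRecord],
    meta: SampleMeta,
    weight_by_templates: bool = True,
) -> ClonotypeTable:
    """Aggregate curated records into a per-sample clonotype table.

    Rearrangements sharing a CDR3 amino-acid sequence are pooled; the
    representative V/J calls come from the highest-count contributor
    (ties broken lexicographically on the V call for determinism).
    With ``weight_by_templates=False`` every rearrangement counts once,
    i.e. frequencies weight unique rearrangements rather than templates.
    """
    if not records:
        raise DegenerateInputError("cannot aggregate an empty record list")
    groups: dict[str, dict] = {}
    for rec in records:
        weight = rec.templates if weight_by_templates else 1
        entry = groups.setdefault(
            rec.cdr3_aa,
            {"templates": 0, "best": (-1, ""), "v_call": "", "j_call": ""},
        )
        entry["templates"] += weight
        key = (rec.templates, rec.v_call)
        best_count, best_v = entry["best"]
        if rec.templates > best_count or (
            rec.templates == best_count and rec.v_call < best_v
        ):
            entry["best"] = key
            entry["v_call"] = rec.v_call
            entry["j_call"] = rec.j_call
    total = sum(entry["templates"] for entry in groups.values())
    if total == 0:
        raise DegenerateInputError("total template count is zero after aggregation")
    rows = [
        {
            "cdr3_aa": cdr3,
            "v_call": entry["v_call"],
            "j_call": entry["j_call"],
            "templates": entry["templates"],
            "frequency": entry["templates"] / total,
        }
        for cdr3, entry in groups.items()
    ]
    df = pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)
    df = df.sort_values(
        ["templates", "cdr3_aa"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table = ClonotypeTable(meta=meta, df=df)
    table.validate()
    return table


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, columns=CLONOTYPE_COLUMNS)


def read_clonotype_table(path: str | Path, meta: SampleMeta) -> ClonotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"cdr3_aa": str, "v_call": str, "j_call": str})
    missing = [c for c in CLONOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clonotype table {path} is missing columns {missing}")
    df = df[CLONOTYPE_COLUMNS].copy()
    for col in ("v_call", "j_call"):
        df[col] = df[col].fillna("")
    table = ClonotypeTable(meta=meta, df=df)
    table.validate()
    return table
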