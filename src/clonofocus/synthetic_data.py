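"""Synthetic repertoires, reference databases, and expression matrices.

The generator emulates the statistical structure the analyses assume:

* multi-sample TCRβ repertoires with power-law (Zipf) or lognormal clone
  sizes, a handful of expanded clones carrying a fixed share of the
  repertoire, public sequences shared with a reference pool,
  compartment-specific (brain) enrichment, and longitudinal fold changes;
* public and virus-specific CDR3 reference tables in which a configurable
  subset of rows are 0-2-edit mutations of chosen repertoire clones;
* a cell-type-mixture expression matrix in which marker genes load on a
  per-sample infiltration level, producing separable sample clusters and a
  correlated T-cell/microglia signature.

Every planted effect is returned as ground truth so recovery can be
scored. A single seed drives clone construction; per-sample multinomial
draws use substreams at fixed offsets, so identical parameters produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .repertoire_io import (
    ClonotypeTable,
    RearrangementRecord,
    SampleMeta,
    aggregate_clonotypes,
    curate,
    write_rearrangements,
)
from .cdr3_matching import PublicReference, ViralCdr3Table, VIRAL_COLUMNS
from .immune_signature import ExpressionMatrix, MarkerSet

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: inner residues exclude C so the framework cysteine stays unique-ish
INNER_RESIDUES = np.array(list("ADEFGHIKLMNPQRSTVWY"))

# canonical immunodominant viral epitopes used to label simulated references
VIRAL_EPITOPES = (
    ("KLGGALQAK", "IE1", "HCMV", "HLA-A*03:01"),
    ("NLVPMVATV", "pp65", "HCMV", "HLA-A*02:01"),
    ("GLCTLVAML", "BMLF1", "EBV", "HLA-A*02:01"),
    ("GILGFVFTL", "M", "InfluenzaA", "HLA-A*02:01"),
    ("TPRVTGGGAM", "pp65", "HCMV", "HLA-B*07:02"),
)


@dataclass
class SimParams:
    """Study conditions for one simulated subject.

    ``longitudinal_folds`` maps clone indices (0-based over background then
    expanded clones) to frequency fold changes applied at the second
    timepoint; a non-empty mapping implies two timepoints.
    """

    seed: int = 0
    n_background_clones: int = 10_000
    clone_size_law: tuple = ("zipf", 1.05)  # or ("lognormal", mu, sigma)
    n_expanded: int = 5
    expanded_mass: float = 0.2
    public_pool_size: int = 200
    public_spike_rate: float = 0.1
    brain_enrichment: float = 5.0
    n_brain_enriched: int = 20
    longitudinal_folds: dict[int, float] = field(default_factory=dict)
    n_timepoints: int = 1
    depth: int = 100_000
    cdr3_length_range: tuple[int, int] = (8, 16)

    def __post_init__(self) -> None:
        if not 0.0 <= self.expanded_mass < 1.0:
            raise ValueError("expanded_mass must lie in [0, 1)")
        if not 0.0 <= self.public_spike_rate <= 1.0:
            raise ValueError("public_spike_rate must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.brain_enrichment < 1.0:
            raise ValueError("brain_enrichment must be >= 1")
        if any(f <= 0 for f in self.longitudinal_folds.values()):
            raise ValueError("longitudinal folds must be positive")
        if self.n_expanded > 0 and self.expanded_mass > 0 and self.n_expanded < 1:
            raise ValueError("n_expanded must be >= 1 when expanded_mass > 0")
        lo, hi = self.cdr3_length_range
        if lo < 4 or hi < lo:
            raise ValueError("invalid cdr3_length_range")
        if self.longitudinal_folds and self.n_timepoints < 2:
            self.n_timepoints = 2


@dataclass
class GroundTruth:
    """Planted labels for every generated clone and sample."""

    clones: pd.DataFrame  # cdr3_aa, base_mass, is_public, is_expanded, brain_enriched, longitudinal_fold
    sample_masses: dict[tuple[str, str], np.ndarray]  # (compartment, timepoint) -> frequency vector
    params: SimParams

    def public_set(self) -> set[str]:
        return set(self.clones.loc[self.clones["is_public"], "cdr3_aa"])


def simulate_cdr3(
    rng: np.random.Generator, length_range: tuple[int, int] = (8, 16)
) -> str:
    """One CDR3: framework cysteine + random residues + terminal F.

    Total length is uniform over the configured range; passes curation by
    construction.
    """
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    inner = rng.choice(INNER_RESIDUES, size=length - 2)
    return "C" + "".join(inner) + "F"


def _unique_cdr3s(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    exclude: set[str] | None = None,
) -> list[str]:
    seen: set[str] = set(exclude or ())
    out: list[str] = []
    while len(out) < n:
        cdr3 = simulate_cdr3(rng, length_range)
        if cdr3 not in seen:
            seen.add(cdr3)
            out.append(cdr3)
    return out


def _base_masses(rng: np.random.Generator, params: SimParams) -> np.ndarray:
    law = params.clone_size_law
    n = params.n_background_clones
    if law[0] == "zipf":
        ranks = np.arange(1, n + 1, dtype=float)
        masses = ranks ** (-float(law[1]))
    elif law[0] == "lognormal":
        masses = rng.lognormal(mean=float(law[1]), sigma=float(law[2]), size=n)
    else:
        raise ValueError(f"unknown clone_size_law {law[0]!r}")
    return masses / masses.sum()


@dataclass
class SubjectSim:
    """Simulated repertoires for one subject across compartments/timepoints."""

    records: dict[tuple[str, str], list[RearrangementRecord]]
    truth: GroundTruth
    subject_id: str = "sim"

    def table(self, compartment: str, timepoint: str = "t1") -> ClonotypeTable:
        meta = SampleMeta(
            sample_id=f"{self.subject_id}_{compartment}_{timepoint}",
            subject_id=self.subject_id,
            compartment=compartment,
            timepoint_label=timepoint,
        )
        kept, _ = curate(self.records[(compartment, timepoint)])
        return aggregate_clonotypes(kept, meta)

    def write_airr(self, outdir: str | Path) -> dict[tuple[str, str], Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for (compartment, timepoint), recs in sorted(self.records.items()):
            path = outdir / f"{self.subject_id}_{compartment}_{timepoint}.airr.tsv"
            write_rearrangements(recs, path, dialect="airr")
            paths[(compartment, timepoint)] = path
        return paths


def simulate_subject(params: SimParams, subject_id: str = "sim") -> SubjectSim:
    """Generate paired brain/blood repertoires (1-2 timepoints) with truth.

    Clone masses follow the configured size law; expanded clones share
    ``expanded_mass`` equally; a ``public_spike_rate`` fraction of clones
    take sequences from a shared public pool; the brain compartment
    multiplies ``n_brain_enriched`` clone masses by ``brain_enrichment``
    before renormalization; the second timepoint applies
    ``longitudinal_folds``. Each sample is one multinomial draw of
    ``depth`` templates.
    """
    rng = np.random.default_rng(params.seed)
    n_total = params.n_background_clones + params.n_expanded
    # public pool first so pool membership is independent of clone order
    pool = _unique_cdr3s(rng, params.public_pool_size, params.cdr3_length_range)
    cdr3s = np.array(
        _unique_cdr3s(rng, n_total, params.cdr3_length_range, exclude=set(pool)),
        dtype=object,
    )
    is_public = np.zeros(n_total, dtype=bool)
    n_spiked = min(int(round(params.public_spike_rate * n_total)), len(pool))
    if n_spiked:
        spike_idx = rng.choice(n_total, size=n_spiked, replace=False)
        pool_idx = rng.choice(len(pool), size=n_spiked, replace=False)
        for clone_i, pool_i in zip(spike_idx, pool_idx):
            cdr3s[clone_i] = pool[pool_i]
        is_public[spike_idx] = True

    background = _base_masses(rng, params) * (1.0 - params.expanded_mass)
    is_expanded = np.zeros(n_total, dtype=bool)
    if params.n_expanded:
        expanded = np.full(params.n_expanded, params.expanded_mass / params.n_expanded)
        masses = np.concatenate([background, expanded])
        if params.expanded_mass > 0:
            is_expanded[params.n_background_clones:] = True
    else:
        masses = background
    masses = masses / masses.sum()

    brain_enriched = np.zeros(n_total, dtype=bool)
    if params.n_brain_enriched and params.brain_enrichment > 1.0:
        enriched_idx = rng.choice(n_total, size=min(params.n_brain_enriched, n_total), replace=False)
        brain_enriched[enriched_idx] = True

    folds = np.ones(n_total)
    for idx, fold in params.longitudinal_folds.items():
        folds[idx] = fold

    v_calls = np.array([f"TRBV{v}-1" for v in rng.integers(2, 31, size=n_total)])
    j_calls = np.array([f"TRBJ{j}-{k}" for j, k in zip(rng.integers(1, 3, size=n_total),
                                                       rng.integers(1, 7, size=n_total))])

    timepoints = ["t1", "t2"][: params.n_timepoints]
    records: dict[tuple[str, str], list[RearrangementRecord]] = {}
    sample_masses: dict[tuple[str, str], np.ndarray] = {}
    for t_index, timepoint in enumerate(timepoints):
        for c_index, compartment in enumerate(("brain", "blood")):
            m = masses.copy()
            if compartment == "brain":
                m[brain_enriched] *= params.brain_enrichment
            if t_index == 1:
                m = m * folds
            m = m / m.sum()
            sample_masses[(compartment, timepoint)] = m
            # fixed-offset substream per sample: deterministic, order-independent
            draw_rng = np.random.default_rng(params.seed * 8 + t_index * 2 + c_index + 1)
            counts = draw_rng.multinomial(params.depth, m)
            recs = [
                RearrangementRecord(
                    cdr3_aa=str(cdr3s[i]),
                    v_call=str(v_calls[i]),
                    j_call=str(j_calls[i]),
                    templates=int(counts[i]),
                    productive=True,
                )
                for i in np.flatnonzero(counts)
            ]
            records[(compartment, timepoint)] = recs

    clones = pd.DataFrame(
        {
            "cdr3_aa": cdr3s,
            "base_mass": masses,
            "is_public": is_public,
            "is_expanded": is_expanded,
            "brain_enriched": brain_enriched,
            "longitudinal_fold": folds,
        }
    )
    truth = GroundTruth(clones=clones, sample_masses=sample_masses, params=params)
    return SubjectSim(records=records, truth=truth, subject_id=subject_id)


def _mutate(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """Apply n substitutions at distinct interior positions (edit distance <= n)."""
    chars = list(seq)
    if n_edits == 0:
        return seq
    positions = rng.choice(np.arange(1, len(chars) - 1), size=min(n_edits, len(chars) - 2),
                           replace=False)
    for pos in positions:
        current = chars[pos]
        options = [r for r in INNER_RESIDUES if r != current]
        chars[pos] = str(rng.choice(options))
    return "".join(chars)


def simulate_reference_dbs(
    params: SimParams,
    truth: GroundTruth,
    n_viral: int = 10,
    viral_edits: Sequence[int] = (0, 1, 2),
    n_public_decoys: int = 50,
    n_viral_decoys: int = 20,
) -> tuple[PublicReference, ViralCdr3Table, pd.DataFrame]:
    """Reference databases aligned with a simulated subject.

    The public reference holds exactly the planted public sequences (plus
    decoys absent from the repertoire); the viral table holds rows that
    are 0-2-edit mutations of chosen repertoire clones, with epitope
    metadata, plus unrelated decoy rows. Returns the planted viral pairs
    (clone, reference, edits) as the third element.
    """
    rng = np.random.default_rng(params.seed + 104_729)  # independent substream
    repertoire = set(truth.clones["cdr3_aa"])
    public_seqs = sorted(truth.public_set())
    entries = {s: int(rng.integers(2, 51)) for s in public_seqs}
    for decoy in _unique_cdr3s(rng, n_public_decoys, params.cdr3_length_range, exclude=repertoire):
        entries[decoy] = int(rng.integers(1, 20))
    public_ref = PublicReference(entries=entries, source_label="simulated snapshot")

    candidates = truth.clones.sort_values("base_mass", ascending=False)["cdr3_aa"].tolist()
    chosen = candidates[:n_viral]
    rows, planted = [], []
    for i, clone in enumerate(chosen):
        edits = int(viral_edits[i % len(viral_edits)])
        ref_seq = _mutate(rng, clone, edits)
        epitope, antigen, species, mhc = VIRAL_EPITOPES[i % len(VIRAL_EPITOPES)]
        rows.append(
            {"cdr3_aa": ref_seq, "epitope": epitope, "antigen": antigen,
             "species": species, "mhc_allele": mhc, "v_call": "", "j_call": ""}
        )
        planted.append({"clone": clone, "reference": ref_seq, "edits": edits})
    for i, decoy in enumerate(
        _unique_cdr3s(rng, n_viral_decoys, params.cdr3_length_range, exclude=repertoire)
    ):
        epitope, antigen, species, mhc = VIRAL_EPITOPES[i % len(VIRAL_EPITOPES)]
        rows.append(
            {"cdr3_aa": decoy, "epitope": epitope, "antigen": antigen,
             "species": species, "mhc_allele": mhc, "v_call": "", "j_call": ""}
        )
    viral = ViralCdr3Table(df=pd.DataFrame(rows, columns=VIRAL_COLUMNS))
    return public_ref, viral, pd.DataFrame(planted)


def simulate_expression(
    n_samples: int = 53,
    n_background_genes: int = 400,
    n_markers: dict[str, int] | None = None,
    infiltration_levels: Sequence[float] = (0.0, 2.0, 5.0),
    cluster_fractions: Sequence[float] | None = None,
    class_loads: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, MarkerSet, dict]:
    """Cell-type-mixture expression matrix with planted sample clusters.

    value(g, s) = baseline(g) + load(g) * infiltration(s) + N(0, noise_sd),
    on the log2 scale; load(g) > 0 only for marker genes. Samples are
    grouped into clusters by infiltration level (ascending), so planted
    cluster k is the high-infiltration group. Defaults emulate an immune
    panel profiled across ~50 surgical specimens: 151 marker genes among
    551 total, three infiltration tiers.
    """
    if len(infiltration_levels) < 2:
        raise ValueError("need at least two infiltration levels")
    n_markers = n_markers or {"T cell": 60, "microglia": 60, "macrophage": 31}
    class_loads = class_loads or {"T cell": 1.0, "microglia": 1.0, "macrophage": 1.0}
    rng = np.random.default_rng(seed)

    gene_class: dict[str, str] = {}
    genes: list[str] = []
    for cls_, count in n_markers.items():
        tag = cls_.replace(" ", "").upper()
        for i in range(count):
            name = f"{tag}_{i:03d}"
            genes.append(name)
            gene_class[name] = cls_
    for i in range(n_background_genes):
        name = f"BG_{i:04d}"
        genes.append(name)
        gene_class[name] = "unassigned"

    k = len(infiltration_levels)
    if cluster_fractions is None:
        sizes = [n_samples // k] * k
        for i in range(n_samples - sum(sizes)):
            sizes[i] += 1
    else:
        sizes = [int(round(f * n_samples)) for f in cluster_fractions]
        sizes[-1] = n_samples - sum(sizes[:-1])
    levels_sorted = sorted(infiltration_levels)
    sample_ids, infiltration, cluster_labels = [], [], {}
    for label, (level, size) in enumerate(zip(levels_sorted, sizes), start=1):
        for i in range(size):
            sid = f"S{len(sample_ids):03d}"
            sample_ids.append(sid)
            infiltration.append(level)
            cluster_labels[sid] = label

    baseline = rng.uniform(2.0, 8.0, size=len(genes))
    loads = np.array([class_loads.get(gene_class[g], 0.0) for g in genes])
    infil = np.array(infiltration)
    values = (
        baseline[:, None]
        + loads[:, None] * infil[None, :]
        + rng.normal(0.0, noise_sd, size=(len(genes), len(sample_ids)))
    )
    matrix = ExpressionMatrix(
        df=pd.DataFrame(values, index=genes, columns=sample_ids), scale_flag="log2"
    )
    markers = MarkerSet(classes=gene_class, provenance="simulated")
    truth = {
        "cluster_labels": cluster_labels,
        "infiltration": dict(zip(sample_ids, infiltration)),
        "gene_class": gene_class,
        "loads": dict(zip(genes, loads)),
    }
    return matrix, markers, truth
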