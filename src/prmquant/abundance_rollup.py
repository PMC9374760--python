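"""Replicate aggregation and protein-level rollup.

Per-run peptide fmol values are normalized to fmol per ug of injected
protein, pooled across the technical replicates and spike levels (at most
2 x 3 = 6 values per biological replicate) by geometric mean, pooled across
biological replicates by geometric mean, merged across co-measured peptide
forms, filtered by the catalog discard rules, converted to copies/cell, and
finally rolled up to one geometric-mean value per protein with a
consistency class.  RADM, technical/biological CV and the Tier-2 CV<35%
diagnostic are computed along the way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import PeptideCatalogEntry, strip_modifications
from .prm_quantitation import DISCARDED, GOOD, MAYBE_POOR
from .synthetic_data import AVOGADRO, DEFAULT_PG_PER_CELL

logger = logging.getLogger("prmquant")

__all__ = [
    "PeptideAbundance",
    "ProteinAbundance",
    "RollupResult",
    "geometric_mean",
    "radm",
    "filter_qc_within_bio_rep",
    "aggregate_technical",
    "aggregate_biological",
    "merge_peptide_forms",
    "apply_peptide_discards",
    "copies_per_cell",
    "protein_rollup",
    "cv_and_tier2_summary",
    "rollup",
]

CONSISTENT = "consistent"
SEMI_CONSISTENT = "semi-consistent"
INCONSISTENT = "inconsistent"

DEFAULT_CONSISTENCY_FOLDS = (2.0, 4.0)
TIER2_CV_LIMIT = 0.35


def geometric_mean(values: Sequence[float] | np.ndarray) -> float:
    """exp(mean(log(values))); requires strictly positive inputs."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty set")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def radm(values: Sequence[float] | np.ndarray) -> list[float]:
    """Relative absolute deviation from the (arithmetic) mean, per element."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RADM undefined: arithmetic mean is zero")
    return [float(abs((x - mean) / mean)) for x in arr]


def _cv(values: np.ndarray) -> float:
    if values.size < 2:
        return math.nan
    return float(np.std(values, ddof=1) / np.mean(values))


@dataclass
class PeptideAbundance:
    peptide_key: str
    per_bio_rep: dict[int, float] = field(default_factory=dict)
    radm_values: list[float] = field(default_factory=list)
    technical_cv: float = math.nan
    biological_cv: float = math.nan
    n_replicates_used: int = 0
    fmol_per_ug: float = math.nan
    copies_per_cell: float = math.nan


@dataclass
class ProteinAbundance:
    accession: str
    copies_per_cell: float
    n_peptides_used: int
    consistency: str


@dataclass
class RollupResult:
    peptides: pd.DataFrame
    proteins: pd.DataFrame
    diagnostics: pd.DataFrame


def filter_qc_within_bio_rep(measurements: pd.DataFrame) -> pd.DataFrame:
    """Within one peptide and biological replicate, apply the QC retention rule.

    Discarded rows are never retained; when at least two Good values exist,
    every Maybe Poor value is dropped; otherwise both classes are kept.
    """
    kept = measurements[measurements["qc"] != DISCARDED]
    if (kept["qc"] == GOOD).sum() >= 2:
        kept = kept[kept["qc"] == GOOD]
    return kept


def aggregate_technical(values: Sequence[float]) -> dict:
    """Pool ug-normalized values across technical replicates and spike levels."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no retained values")
    return {
        "value": geometric_mean(arr),
        "radm": radm(arr),
        "technical_cv": _cv(arr),
        "n_used": int(arr.size),
    }


def aggregate_biological(per_bio_values: Sequence[float]) -> dict:
    """Geometric mean across biological replicates, with the biological CV."""
    arr = np.asarray(per_bio_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no biological replicates")
    return {"value": geometric_mean(arr), "biological_cv": _cv(arr)}


def merge_peptide_forms(
    form_abundances: Mapping[str, float],
    catalog: Mapping[str, PeptideCatalogEntry] | None = None,
) -> float:
    """Combine co-measured forms (e.g. unmodified + oxidized) of one peptide.

    Forms flagged ``redundant_lower_form`` in the catalog are dropped; the
    remaining forms are summed.  If every form is flagged, the largest one is
    kept (dropping everything would silently lose the peptide).
    """
    catalog = catalog or {}
    kept = {
        key: value
        for key, value in form_abundances.items()
        if not (key in catalog and catalog[key].redundant_lower_form)
    }
    if not kept:
        key = max(form_abundances, key=form_abundances.__getitem__)
        logger.warning("all forms of %s flagged redundant; keeping the largest", key)
        kept = {key: form_abundances[key]}
    return float(sum(kept.values()))


def apply_peptide_discards(
    abundances: Mapping[str, float],
    catalog: Mapping[str, PeptideCatalogEntry],
) -> tuple[dict[str, float], dict[str, str]]:
    """Drop non-unique, low-confidence, and PTM-confounded peptides.

    Returns (retained, reasons-for-dropped).  Peptides absent from the
    catalog are retained (no evidence against them).
    """
    retained: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for key, value in abundances.items():
        entry = catalog.get(key)
        if entry is None:
            retained[key] = value
            continue
        if not entry.unique_to_target:
            reasons[key] = "not unique to target"
        elif not entry.id_confidence_ok:
            reasons[key] = "low-confidence identification"
        elif entry.ptm_confound:
            reasons[key] = "PTM confounds quantification"
        else:
            retained[key] = value
    for key, reason in reasons.items():
        logger.info("peptide %s discarded: %s", key, reason)
    return retained, reasons


def copies_per_cell(
    fmol_per_injection: float,
    protein_ug_per_injection: float,
    pg_per_cell: float,
) -> float:
    """Convert fmol/injection to copies/cell.

    cells/injection = protein_ug * 1e6 / pg_per_cell;
    copies/cell = fmol * 1e-15 * N_A / cells_per_injection.
    """
    if fmol_per_injection < 0:
        raise ValueError("fmol must be >= 0")
    if protein_ug_per_injection <= 0 or pg_per_cell <= 0:
        raise ValueError("protein load and per-cell mass must be positive")
    cells = protein_ug_per_injection * 1e6 / pg_per_cell
    return fmol_per_injection * 1e-15 * AVOGADRO / cells


def protein_rollup(
    peptide_values: Mapping[str, float],
    consistency_folds: tuple[float, float] = DEFAULT_CONSISTENCY_FOLDS,
) -> tuple[float, str]:
    """Geometric mean across a protein's peptides plus a consistency class.

    The class derives from the maximum pairwise fold difference:
    < folds[0] consistent, <= folds[1] semi-consistent, else inconsistent.
    """
    values = list(peptide_values.values())
    if not values:
        raise ValueError("no peptides")
    value = geometric_mean(values)
    fold = max(values) / min(values)
    if fold < consistency_folds[0]:
        label = CONSISTENT
    elif fold <= consistency_folds[1]:
        label = SEMI_CONSISTENT
    else:
        label = INCONSISTENT
    return value, label


def cv_and_tier2_summary(
    replicate_values: Mapping[str, Sequence[float]],
    cv_limit: float = TIER2_CV_LIMIT,
) -> pd.DataFrame:
    """Per-peptide CV across all replicates plus the CV<limit pass flag.

    The returned frame carries ``pass_fraction`` metadata over peptides with
    a defined CV (>=2 replicates).
    """
    rows = []
    for key in sorted(replicate_values):
        arr = np.asarray(replicate_values[key], dtype=float)
        cv = _cv(arr)
        rows.append(
            {
                "peptide_key": key,
                "n_values": int(arr.size),
                "cv": cv,
                "tier2_pass": bool(cv < cv_limit) if math.isfinite(cv) else None,
            }
        )
    frame = pd.DataFrame(rows, columns=["peptide_key", "n_values", "cv", "tier2_pass"])
    defined = frame["tier2_pass"].notna()
    frame.attrs["pass_fraction"] = (
        float(frame.loc[defined, "tier2_pass"].mean()) if defined.any() else math.nan
    )
    return frame


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def rollup(
    measurements: pd.DataFrame,
    catalog: Iterable[PeptideCatalogEntry] | None = None,
    pg_per_cell: float = DEFAULT_PG_PER_CELL,
    consistency_folds: tuple[float, float] = DEFAULT_CONSISTENCY_FOLDS,
) -> RollupResult:
    """Measurements table (from :func:`prmquant.prm_quantitation.quantify`)
    -> peptide- and protein-level abundance tables.

    Control (spiked standard) peptides are carried through the peptide table
    (their ``fmol_per_ug`` doubles as fmol/injection at a 1 ug load) but are
    excluded from the protein table, whose copies/cell values only make
    sense for endogenous proteins.
    """
    cat: dict[str, PeptideCatalogEntry] = {
        e.peptide_key: e for e in (catalog or [])
    }

    df = measurements[
        (measurements["role"] == "sample")
        & (measurements["level"] > 0)
        & (measurements["qc"] != DISCARDED)
    ].copy()
    nonpositive = df["light_fmol_corrected"] <= 0
    if nonpositive.any():
        for key in df.loc[nonpositive, "peptide_key"].unique():
            logger.info(
                "peptide %s: non-positive corrected fmol discarded before rollup", key
            )
        df = df[~nonpositive]
    df["fmol_per_ug"] = df["light_fmol_corrected"] / df["protein_ug"]

    per_bio_rows = []
    pooled: dict[str, list[float]] = {}
    for (pep, bio), group in df.groupby(["peptide_key", "bio_rep"], sort=True):
        kept = filter_qc_within_bio_rep(group)
        if kept.empty:
            continue
        values = kept["fmol_per_ug"].to_numpy()
        agg = aggregate_technical(values)
        per_bio_rows.append(
            {"peptide_key": pep, "bio_rep": bio, **agg}
        )
        pooled.setdefault(pep, []).extend(values.tolist())
    if not per_bio_rows:
        empty = pd.DataFrame()
        return RollupResult(empty, empty, cv_and_tier2_summary({}))
    per_bio = pd.DataFrame(per_bio_rows)

    peptide_rows = []
    for pep, group in per_bio.groupby("peptide_key", sort=True):
        agg = aggregate_biological(group["value"].to_numpy())
        entry = cat.get(pep)
        peptide_rows.append(
            {
                "peptide_key": pep,
                "base_sequence": entry.base_sequence if entry else strip_modifications(pep),
                "accession": (
                    entry.protein_accessions[0]
                    if entry and entry.protein_accessions
                    else pep
                ),
                "is_control": bool(entry.is_control) if entry else False,
                "fmol_per_ug": agg["value"],
                "biological_cv": agg["biological_cv"],
                "mean_technical_cv": float(np.nanmean(group["technical_cv"]))
                if group["technical_cv"].notna().any()
                else math.nan,
                "max_radm": float(max(max(r) for r in group["radm"])),
                "n_replicates_used": int(group["n_used"].sum()),
                "n_bio_reps": int(group["bio_rep"].nunique()),
            }
        )
    peptides = pd.DataFrame(peptide_rows)

    # merge co-measured forms of the same target peptide, then apply discards
    merged_rows = []
    for (accession, base), group in peptides.groupby(
        ["accession", "base_sequence"], sort=True
    ):
        forms = dict(zip(group["peptide_key"], group["fmol_per_ug"]))
        value = merge_peptide_forms(forms, cat)
        lead = group.loc[group["fmol_per_ug"].idxmax()]
        row = lead.to_dict()
        row["fmol_per_ug"] = value
        row["n_forms"] = len(forms)
        merged_rows.append(row)
    merged = pd.DataFrame(merged_rows)

    retained, reasons = apply_peptide_discards(
        dict(zip(merged["peptide_key"], merged["fmol_per_ug"])), cat
    )
    merged["discard_reason"] = merged["peptide_key"].map(reasons).fillna("")
    merged["retained"] = merged["peptide_key"].isin(retained)
    merged["copies_per_cell"] = [
        copies_per_cell(v, 1.0, pg_per_cell) if v > 0 else 0.0
        for v in merged["fmol_per_ug"]
    ]

    protein_rows = []
    usable = merged[merged["retained"] & ~merged["is_control"]]
    for accession, group in usable.groupby("accession", sort=True):
        values = dict(zip(group["peptide_key"], group["copies_per_cell"]))
        value, label = protein_rollup(values, consistency_folds)
        protein_rows.append(
            {
                "accession": accession,
                "copies_per_cell": value,
                "n_peptides_used": len(values),
                "consistency": label,
            }
        )
    proteins = pd.DataFrame(
        protein_rows,
        columns=["accession", "copies_per_cell", "n_peptides_used", "consistency"],
    )

    diagnostics = cv_and_tier2_summary(pooled)
    return RollupResult(merged.reset_index(drop=True), proteins, diagnostics)
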