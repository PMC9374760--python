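"""Input/output for all external tables.

This module owns the on-disk contract of the pipeline: the transition-level
peak-area report (a Skyline-style CSV export), the sample design table, the
peptide catalog, and the gene-level counts table.  No science lives here —
only parsing, validation, normalization and round-trip serialization.

Column names for the transition CSV follow the Skyline report vocabulary by
default but every column is remappable through :class:`TransitionDialect`,
because upstream exports do not share a fixed schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("prmquant")

__all__ = [
    "TransitionRecord",
    "SampleSpec",
    "PeptideCatalogEntry",
    "TransitionDialect",
    "ReportError",
    "read_transition_report",
    "write_transition_report",
    "read_design_table",
    "write_design_table",
    "read_counts_table",
    "write_counts_table",
    "read_peptide_catalog",
    "write_peptide_catalog",
    "read_fasta",
    "write_fasta",
    "strip_modifications",
    "transitions_to_frame",
    "config_hash",
]

_MOD_TOKEN = re.compile(r"\[[^\]]*\]")

LIGHT = "light"
HEAVY = "heavy"


class ReportError(ValueError):
    """Fatal problem with an input table (missing column, duplicate key...)."""


def strip_modifications(peptide_key: str) -> str:
    """Return the base sequence: any bracketed modification token removed.

    ``"TM[Ox]DAGC[Carbam]K"`` -> ``"TMDAGCK"``.
    """
    return _MOD_TOKEN.sub("", peptide_key)


@dataclass(frozen=True)
class TransitionRecord:
    """One fragment-ion peak area for one peptide/label/replicate."""

    sample_id: str
    tech_rep: int
    peptide_key: str
    precursor_charge: int
    fragment_ion: str
    product_charge: int
    label: str  # "light" | "heavy"
    area: float
    quantitative: bool = True

    def key(self) -> tuple:
        return (
            self.sample_id,
            self.tech_rep,
            self.peptide_key,
            self.precursor_charge,
            self.fragment_ion,
            self.product_charge,
            self.label,
        )


@dataclass(frozen=True)
class SampleSpec:
    """One sample of the quantitation design (one row of the design table)."""

    sample_id: str
    bio_rep: int | None
    protein_ug_per_injection: float
    luciferase_fmol: float
    heavy_std_fmol: float
    n_tech_reps: int
    is_blank: bool

    def __post_init__(self) -> None:
        if self.protein_ug_per_injection < 0:
            raise ReportError(
                f"sample {self.sample_id}: negative protein mass "
                f"{self.protein_ug_per_injection}"
            )
        if self.heavy_std_fmol < 0 or self.luciferase_fmol < 0:
            raise ReportError(f"sample {self.sample_id}: negative standard amount")
        if self.is_blank != (self.protein_ug_per_injection == 0):
            raise ReportError(
                f"sample {self.sample_id}: is_blank must equal (protein_ug == 0)"
            )


@dataclass(frozen=True)
class PeptideCatalogEntry:
    """Per-peptide annotations used by the rollup discard/merge rules."""

    peptide_key: str
    base_sequence: str = ""
    protein_accessions: tuple[str, ...] = ()
    is_phospho: bool = False
    unique_to_target: bool = True
    id_confidence_ok: bool = True
    ptm_confound: bool = False
    redundant_lower_form: bool = False
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.base_sequence:
            object.__setattr__(
                self, "base_sequence", strip_modifications(self.peptide_key)
            )


@dataclass(frozen=True)
class TransitionDialect:
    """Column-name mapping for the transition report CSV.

    Defaults follow Skyline's report vocabulary.
    """

    sample_id: str = "Sample"
    tech_rep: str = "Technical Replicate"
    peptide_key: str = "Peptide Modified Sequence"
    precursor_charge: str = "Precursor Charge"
    fragment_ion: str = "Fragment Ion"
    product_charge: str = "Product Charge"
    label: str = "Isotope Label Type"
    area: str = "Area"
    quantitative: str = "Quantitative"

    @classmethod
    def from_config(cls, mapping: dict | None) -> "TransitionDialect":
        if not mapping:
            return cls()
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ReportError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**mapping)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ReportError(f"{path}: missing required column(s) {missing}")


def _normalize_label(raw: str) -> str:
    value = str(raw).strip().lower()
    if value in (LIGHT, HEAVY):
        return value
    raise ValueError(f"unrecognized isotope label {raw!r}")


_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n", ""}


def _parse_bool(raw, default: bool = True) -> bool:
    if isinstance(raw, bool):
        return raw
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return default
    value = str(raw).strip().lower()
    if value in _TRUTHY:
        return True
    if value in _FALSY:
        return False
    raise ValueError(f"unrecognized boolean {raw!r}")


def read_transition_report(
    path, dialect: TransitionDialect | dict | None = None
) -> list[TransitionRecord]:
    """Parse a transition-level peak-area CSV into :class:`TransitionRecord`s.

    Every row is either parsed or rejected with a line-numbered warning; a
    missing column is a fatal :class:`ReportError`.  Label values are
    case-folded to ``light``/``heavy``.
    """
    if not isinstance(dialect, TransitionDialect):
        dialect = TransitionDialect.from_config(dialect)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        dialect.sample_id,
        dialect.tech_rep,
        dialect.peptide_key,
        dialect.precursor_charge,
        dialect.fragment_ion,
        dialect.product_charge,
        dialect.label,
        dialect.area,
    ]
    _require_columns(frame, required, path)
    has_quant = dialect.quantitative in frame.columns

    records: list[TransitionRecord] = []
    seen: set[tuple] = set()
    n_rejected = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        try:
            area = float(row[dialect.area])
            if area < 0:
                raise ValueError(f"negative area {area}")
            rec = TransitionRecord(
                sample_id=str(row[dialect.sample_id]).strip(),
                tech_rep=int(row[dialect.tech_rep]),
                peptide_key=str(row[dialect.peptide_key]).strip(),
                precursor_charge=int(row[dialect.precursor_charge]),
                fragment_ion=str(row[dialect.fragment_ion]).strip(),
                product_charge=int(row[dialect.product_charge]),
                label=_normalize_label(row[dialect.label]),
                area=area,
                quantitative=_parse_bool(row[dialect.quantitative]) if has_quant else True,
            )
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            logger.warning("%s line %d: row rejected (%s)", path, idx, exc)
            continue
        if rec.key() in seen:
            raise ReportError(f"{path} line {idx}: duplicate transition key {rec.key()}")
        seen.add(rec.key())
        records.append(rec)
    logger.info(
        "%s: %d transitions parsed, %d rejected", path, len(records), n_rejected
    )
    return records


def write_transition_report(
    records: Iterable[TransitionRecord],
    path,
    dialect: TransitionDialect | None = None,
) -> None:
    dialect = dialect or TransitionDialect()
    frame = transitions_to_frame(records)
    frame = frame.rename(
        columns={
            "sample_id": dialect.sample_id,
            "tech_rep": dialect.tech_rep,
            "peptide_key": dialect.peptide_key,
            "precursor_charge": dialect.precursor_charge,
            "fragment_ion": dialect.fragment_ion,
            "product_charge": dialect.product_charge,
            "label": dialect.label,
            "area": dialect.area,
            "quantitative": dialect.quantitative,
        }
    )
    frame.to_csv(path, index=False)


def transitions_to_frame(records: Iterable[TransitionRecord]) -> pd.DataFrame:
    """Tabulate records; the column names are the dataclass field names."""
    cols = [f.name for f in fields(TransitionRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = [
    "sample_id",
    "bio_rep",
    "protein_ug",
    "luciferase_fmol",
    "heavy_std_fmol",
    "n_tech_reps",
]


def read_design_table(path) -> list[SampleSpec]:
    """Read the sample design TSV; ``is_blank`` derives from protein_ug == 0."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, _DESIGN_COLUMNS, path)
    specs: list[SampleSpec] = []
    seen_ids: set[str] = set()
    for idx, row in frame.iterrows():
        sample_id = str(row["sample_id"]).strip()
        if sample_id in seen_ids:
            raise ReportError(f"{path}: duplicate sample_id {sample_id!r}")
        seen_ids.add(sample_id)
        bio_raw = str(row["bio_rep"]).strip()
        bio_rep = None if bio_raw in ("", "-", "NA", "None") else int(bio_raw)
        protein_ug = float(row["protein_ug"])
        specs.append(
            SampleSpec(
                sample_id=sample_id,
                bio_rep=bio_rep,
                protein_ug_per_injection=protein_ug,
                luciferase_fmol=float(row["luciferase_fmol"]),
                heavy_std_fmol=float(row["heavy_std_fmol"]),
                n_tech_reps=int(row["n_tech_reps"]),
                is_blank=protein_ug == 0,
            )
        )
    return specs


def write_design_table(specs: Iterable[SampleSpec], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "bio_rep": "" if s.bio_rep is None else s.bio_rep,
            "protein_ug": s.protein_ug_per_injection,
            "luciferase_fmol": s.luciferase_fmol,
            "heavy_std_fmol": s.heavy_std_fmol,
            "n_tech_reps": s.n_tech_reps,
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=_DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts table
# ---------------------------------------------------------------------------


def read_counts_table(path, mapping_path=None) -> pd.DataFrame:
    """Read a gene-level counts TSV (columns gene, count, effective_length).

    Rows with non-positive length are rejected with a warning.  If a
    two-column mapping table (old_symbol, new_symbol) is supplied, genes are
    renamed and counts of colliding symbols are summed (lengths averaged,
    weighted by counts); without it the table passes through unchanged.
    """
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["gene", "count", "effective_length"], path)
    frame = frame[["gene", "count", "effective_length"]].copy()
    frame["gene"] = frame["gene"].astype(str)
    bad_len = frame["effective_length"] <= 0
    if bad_len.any():
        for gene in frame.loc[bad_len, "gene"]:
            logger.warning("%s: gene %s rejected (non-positive length)", path, gene)
        frame = frame[~bad_len]
    if (frame["count"] < 0).any():
        bad = frame["count"] < 0
        for gene in frame.loc[bad, "gene"]:
            logger.warning("%s: gene %s rejected (negative count)", path, gene)
        frame = frame[~bad]
    if mapping_path is not None:
        mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
        _require_columns(mapping, ["old_symbol", "new_symbol"], mapping_path)
        lut = dict(zip(mapping["old_symbol"], mapping["new_symbol"]))
        renamed = frame["gene"].map(lambda g: lut.get(g, g))
        n_renamed = int((renamed != frame["gene"]).sum())
        if n_renamed:
            logger.info("%s: %d gene symbols updated via mapping", path, n_renamed)
        frame["gene"] = renamed
        if frame["gene"].duplicated().any():
            weight = frame["count"].clip(lower=1)
            frame["_wlen"] = frame["effective_length"] * weight
            frame["_w"] = weight
            grouped = frame.groupby("gene", sort=False).agg(
                count=("count", "sum"), _wlen=("_wlen", "sum"), _w=("_w", "sum")
            )
            grouped["effective_length"] = grouped["_wlen"] / grouped["_w"]
            frame = grouped.reset_index()[["gene", "count", "effective_length"]]
    return frame.reset_index(drop=True)


def write_counts_table(frame: pd.DataFrame, path) -> None:
    frame[["gene", "count", "effective_length"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peptide catalog
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "peptide_key",
    "base_sequence",
    "protein_accessions",
    "is_phospho",
    "unique_to_target",
    "id_confidence_ok",
    "ptm_confound",
    "redundant_lower_form",
    "is_control",
]


def read_peptide_catalog(path) -> list[PeptideCatalogEntry]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, ["peptide_key", "protein_accessions"], path)
    entries = []
    for _, row in frame.iterrows():
        entries.append(
            PeptideCatalogEntry(
                peptide_key=row["peptide_key"],
                base_sequence=row.get("base_sequence", "") or "",
                protein_accessions=tuple(
                    a for a in str(row["protein_accessions"]).split(";") if a
                ),
                is_phospho=_parse_bool(row.get("is_phospho"), default=False),
                unique_to_target=_parse_bool(row.get("unique_to_target"), default=True),
                id_confidence_ok=_parse_bool(row.get("id_confidence_ok"), default=True),
                ptm_confound=_parse_bool(row.get("ptm_confound"), default=False),
                redundant_lower_form=_parse_bool(
                    row.get("redundant_lower_form"), default=False
                ),
                is_control=_parse_bool(row.get("is_control"), default=False),
            )
        )
    return entries


def write_peptide_catalog(entries: Iterable[PeptideCatalogEntry], path) -> None:
    rows = []
    for e in entries:
        row = {c: getattr(e, c) for c in _CATALOG_COLUMNS}
        row["protein_accessions"] = ";".join(e.protein_accessions)
        rows.append(row)
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Protein FASTA -> ordered mapping of accession to sequence."""
    from Bio import SeqIO

    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise ReportError(f"{path}: duplicate FASTA accession {record.id!r}")
        proteome[record.id] = str(record.seq).upper()
    if not proteome:
        raise ReportError(f"{path}: no FASTA records")
    return proteome


def write_fasta(proteome: Mapping[str, str], path) -> None:
    with open(path, "w") as handle:
        for accession, sequence in proteome.items():
            handle.write(f">{accession}\n")
            for i in range(0, len(sequence), 60):
                handle.write(sequence[i : i + 60] + "\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict, for output provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
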