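"""Ground-truthed synthetic inputs for the quantitation pipeline.

The generator builds a dilution-series design (blanks carrying only the
heavy standards, plus biological replicates measured at several heavy-spike
levels), a set of target proteins with log-uniform true abundances, and
transition-level peak areas produced by an explicit forward model:

* per-transition response factors (area per fmol), log-uniform over two
  decades so a few transitions dominate, as in real data;
* multiplicative lognormal technical noise.  One injection-scale factor per
  (peptide, run) is shared by the light and heavy areas, and one ratio-scale
  factor multiplies the endogenous light signal only, so the technical CV of
  the recovered light/heavy ratio equals ``tech_cv`` by construction;
* multiplicative lognormal biological noise per (protein, biological
  replicate);
* heavy-standard bleed-through: a light-channel impurity proportional to the
  heavy spike, shared between blanks and samples so blank-based correction
  is exact when noise is off.

Lognormal factors are parameterized with median 1 (``exp(sigma * Z)``), so
the geometric-mean aggregation downstream is unbiased for the truth.

A spiked control protein (a luciferase stand-in with a known fmol/injection
amount, present in every sample including blanks) is included by default as
a positive control; its peptides are flagged ``is_control`` in the catalog
and are excluded from blank-based bleed-through estimation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    HEAVY,
    LIGHT,
    PeptideCatalogEntry,
    SampleSpec,
    TransitionRecord,
)

__all__ = [
    "AVOGADRO",
    "DEFAULT_PG_PER_CELL",
    "DEFAULT_ABUNDANCE_RANGE",
    "TABLE1_LEVELS",
    "SyntheticTruth",
    "StandardsMassModel",
    "generate_truth",
    "generate_design",
    "simulate_transitions",
    "simulate_rnaseq",
    "infer_standards_masses",
    "predict_total_mass",
    "truth_catalog",
    "write_truth",
    "read_truth",
    "fmol_per_injection",
]

AVOGADRO = 6.02214076e23
DEFAULT_PG_PER_CELL = 230.0
DEFAULT_ABUNDANCE_RANGE = (1.332e3, 2.27e8)
TABLE1_LEVELS = (0.0, 1.0, 10.0, 100.0)
CONTROL_ACCESSION = "SPIKE_LUC"

_RESIDUES = "ACDEFGHILMNQSTVWY"  # no K/R/P: cleavage sites appended explicitly


def _sigma_from_cv(cv: float) -> float:
    """Lognormal sigma such that the distribution's CV equals ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class StandardsMassModel:
    """Linear mass model of a standards-only injection.

    total mass (ug) = luciferase_mass_ug + heavy level (fmol) * per_fmol_each_mass_ug
    """

    luciferase_mass_ug: float
    per_fmol_each_mass_ug: float

    def __post_init__(self) -> None:
        if self.luciferase_mass_ug < -1e-12 or self.per_fmol_each_mass_ug < -1e-12:
            raise ValueError("mass model coefficients must be non-negative")


@dataclass
class SyntheticTruth:
    """Everything the generator decided; the oracle for every downstream test."""

    true_copies_per_cell: dict[str, float]
    peptides: dict[str, str]  # peptide_key -> protein accession
    response_factors: dict[str, dict[str, float]]  # peptide -> fragment -> area/fmol
    bleed_fraction: dict[str, float]
    tech_cv: float = 0.15
    bio_cv: float = 0.10
    rna_slope: float = 1.0
    rna_intercept: float = 4.5
    rna_scatter_sd_log10: float = 0.3
    seed: int = 0
    control_fmol: float = 20.0
    control_peptides: tuple[str, ...] = ()

    @property
    def accessions(self) -> list[str]:
        return list(self.true_copies_per_cell)

    def peptides_of(self, accession: str) -> list[str]:
        return [p for p, a in self.peptides.items() if a == accession]


def fmol_per_injection(
    copies_per_cell: float, protein_ug_per_injection: float, pg_per_cell: float
) -> float:
    """Invert the copies/cell normalization: expected light fmol in one injection."""
    cells = protein_ug_per_injection * 1e6 / pg_per_cell
    return copies_per_cell * cells / (AVOGADRO * 1e-15)


def generate_truth(
    n_proteins: int,
    peptides_per_protein: int = 2,
    abundance_range: tuple[float, float] = DEFAULT_ABUNDANCE_RANGE,
    seed: int = 0,
    n_transitions: int = 5,
    bleed_range: tuple[float, float] = (0.0, 0.01),
    tech_cv: float = 0.15,
    bio_cv: float = 0.10,
    rna_slope: float = 1.0,
    rna_intercept: float = 4.5,
    rna_scatter_sd_log10: float = 0.3,
    include_control: bool = True,
    control_fmol: float = 20.0,
) -> SyntheticTruth:
    """Draw ground truth: log-uniform abundances, peptides, response factors.

    Deterministic given ``seed``.  Response factors are log-uniform over two
    decades (1e5..1e7 area/fmol); bleed-through fractions are uniform over
    ``bleed_range``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = abundance_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid abundance range {abundance_range}")
    if peptides_per_protein < 1:
        raise ValueError("peptides_per_protein must be >= 1")
    rng = np.random.default_rng(seed)

    copies = 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=n_proteins)
    accessions = [f"PROT{i + 1:04d}" for i in range(n_proteins)]
    truth = SyntheticTruth(
        true_copies_per_cell=dict(zip(accessions, copies.tolist())),
        peptides={},
        response_factors={},
        bleed_fraction={},
        tech_cv=tech_cv,
        bio_cv=bio_cv,
        rna_slope=rna_slope,
        rna_intercept=rna_intercept,
        rna_scatter_sd_log10=rna_scatter_sd_log10,
        seed=seed,
        control_fmol=control_fmol,
    )

    seen: set[str] = set()

    def draw_peptide() -> str:
        while True:
            length = int(rng.integers(7, 14))
            body = "".join(rng.choice(list(_RESIDUES), size=length))
            terminal = "K" if rng.random() < 0.5 else "R"
            seq = body + terminal
            if seq not in seen:
                seen.add(seq)
                return seq

    def add_peptide(accession: str, bleed: float) -> str:
        pep = draw_peptide()
        truth.peptides[pep] = accession
        rfs = 10 ** rng.uniform(5.0, 7.0, size=n_transitions)
        truth.response_factors[pep] = {
            f"y{j + 3}": float(rf) for j, rf in enumerate(rfs)
        }
        truth.bleed_fraction[pep] = bleed
        return pep

    for accession in accessions:
        for _ in range(peptides_per_protein):
            add_peptide(accession, float(rng.uniform(*bleed_range)))

    if include_control:
        truth.true_copies_per_cell[CONTROL_ACCESSION] = float("nan")
        controls = [add_peptide(CONTROL_ACCESSION, 0.0) for _ in range(2)]
        truth.control_peptides = tuple(controls)
    return truth


def generate_design(
    levels: Sequence[float] = TABLE1_LEVELS,
    n_tech: int = 2,
    n_bio: int = 2,
    protein_ug: float = 1.0,
    luciferase_fmol: float = 20.0,
) -> list[SampleSpec]:
    """Dilution-series design: standards-only blanks (one run each) at every
    nonzero level, plus one sample per biological replicate per level.

    The defaults reproduce the published topology: levels {0, 1, 10, 100},
    two biological replicates, two technical replicates -> 11 samples and
    3*1 + 8*2 = 19 runs.
    """
    levels = sorted(set(float(v) for v in levels))
    if not levels:
        raise ValueError("levels must be non-empty")
    specs: list[SampleSpec] = []
    nonzero = [v for v in levels if v > 0]
    for i, level in enumerate(nonzero, start=1):
        specs.append(
            SampleSpec(
                sample_id=f"B0-{i}",
                bio_rep=None,
                protein_ug_per_injection=0.0,
                luciferase_fmol=luciferase_fmol,
                heavy_std_fmol=level,
                n_tech_reps=1,
                is_blank=True,
            )
        )
    for bio in range(1, n_bio + 1):
        for j, level in enumerate(levels):
            specs.append(
                SampleSpec(
                    sample_id=f"B{bio}-{j}",
                    bio_rep=bio,
                    protein_ug_per_injection=protein_ug,
                    luciferase_fmol=luciferase_fmol,
                    heavy_std_fmol=level,
                    n_tech_reps=n_tech,
                    is_blank=False,
                )
            )
    return specs


def simulate_transitions(
    truth: SyntheticTruth,
    design: Iterable[SampleSpec],
    pg_per_cell: float = DEFAULT_PG_PER_CELL,
    seed: int | None = None,
) -> list[TransitionRecord]:
    """Run the forward model and emit one record per transition/label/run.

    With all CVs and bleed fractions at zero the recovered light/heavy ratio
    equals true_fmol/heavy_fmol exactly for every peptide and run.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    sigma_t = _sigma_from_cv(truth.tech_cv)
    sigma_b = _sigma_from_cv(truth.bio_cv)

    bio_factor: dict[tuple[str, int], float] = {}
    records: list[TransitionRecord] = []
    control_set = set(truth.control_peptides)

    for spec in design:
        for tech in range(1, spec.n_tech_reps + 1):
            for pep, accession in truth.peptides.items():
                iota = math.exp(sigma_t * rng.standard_normal()) if sigma_t else 1.0
                eta = math.exp(sigma_t * rng.standard_normal()) if sigma_t else 1.0
                if pep in control_set:
                    light_fmol = spec.luciferase_fmol
                elif spec.is_blank:
                    light_fmol = 0.0
                else:
                    key = (accession, spec.bio_rep)
                    if key not in bio_factor:
                        bio_factor[key] = (
                            math.exp(sigma_b * rng.standard_normal()) if sigma_b else 1.0
                        )
                    light_fmol = (
                        fmol_per_injection(
                            truth.true_copies_per_cell[accession],
                            spec.protein_ug_per_injection,
                            pg_per_cell,
                        )
                        * bio_factor[key]
                    )
                heavy_fmol = spec.heavy_std_fmol
                bleed = truth.bleed_fraction[pep]
                for fragment, rf in truth.response_factors[pep].items():
                    light_area = (light_fmol * eta + bleed * heavy_fmol) * rf * iota
                    heavy_area = heavy_fmol * rf * iota
                    for label, area in ((LIGHT, light_area), (HEAVY, heavy_area)):
                        records.append(
                            TransitionRecord(
                                sample_id=spec.sample_id,
                                tech_rep=tech,
                                peptide_key=pep,
                                precursor_charge=2,
                                fragment_ion=fragment,
                                product_charge=1,
                                label=label,
                                area=float(area),
                                quantitative=True,
                            )
                        )
    return records


def simulate_rnaseq(
    truth: SyntheticTruth,
    rna_slope: float | None = None,
    rna_intercept: float | None = None,
    scatter: float | None = None,
    seed: int | None = None,
    n_background: int = 300,
    library_size: float = 5e7,
    integer_counts: bool = True,
) -> pd.DataFrame:
    """Generate a gene-level counts table tied to the protein truth.

    For each target protein, log10(TPM) is set so that
    log10(copies) = slope*log10(TPM) + intercept + Normal(0, scatter).
    Background genes (no protein measurement) absorb the remaining TPM mass
    so that the table's TPMs sum to exactly 1e6; counts are then
    count_g = library_size * TPM_g * length_g / sum(TPM * length).
    """
    slope = truth.rna_slope if rna_slope is None else rna_slope
    intercept = truth.rna_intercept if rna_intercept is None else rna_intercept
    sd = truth.rna_scatter_sd_log10 if scatter is None else scatter
    if sd < 0:
        raise ValueError("scatter must be >= 0")
    if slope == 0:
        raise ValueError("rna_slope must be nonzero")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    targets = [
        a for a in truth.true_copies_per_cell if not math.isnan(truth.true_copies_per_cell[a])
    ]
    log_copies = np.array([math.log10(truth.true_copies_per_cell[a]) for a in targets])
    eps = rng.normal(0.0, sd, size=len(targets)) if sd else np.zeros(len(targets))
    tpm_target = 10 ** ((log_copies - intercept - eps) / slope)

    target_sum = float(tpm_target.sum())
    if target_sum >= 1e6:
        raise ValueError(
            f"target TPM mass {target_sum:.0f} >= 1e6; raise rna_intercept"
        )
    bg_raw = 10 ** rng.uniform(-0.5, 2.5, size=n_background)
    bg_tpm = bg_raw * (1e6 - target_sum) / bg_raw.sum()

    genes = targets + [f"BG{i + 1:05d}" for i in range(n_background)]
    tpm = np.concatenate([tpm_target, bg_tpm])
    lengths = rng.uniform(500, 4000, size=len(genes))
    expected = library_size * tpm * lengths / float((tpm * lengths).sum())
    counts = np.rint(expected) if integer_counts else expected
    return pd.DataFrame(
        {"gene": genes, "count": counts, "effective_length": lengths}
    )


def infer_standards_masses(
    blank_totals: Iterable[tuple[float, float]]
) -> StandardsMassModel:
    """Fit total = L + level*p from standards-only (level, total-ug) pairs.

    Least squares; exact for two points.  Requires >=2 distinct levels.
    """
    pairs = list(blank_totals)
    levels = np.array([p[0] for p in pairs], dtype=float)
    totals = np.array([p[1] for p in pairs], dtype=float)
    if len(set(levels.tolist())) < 2:
        raise ValueError("need >=2 distinct heavy-standard levels")
    coeffs = np.polynomial.polynomial.polyfit(levels, totals, 1)
    intercept, slope = float(coeffs[0]), float(coeffs[1])
    return StandardsMassModel(
        luciferase_mass_ug=intercept, per_fmol_each_mass_ug=slope
    )


def predict_total_mass(spec: SampleSpec, model: StandardsMassModel) -> float:
    """Total injected mass (ug): sample protein + luciferase + heavy standards."""
    return (
        spec.protein_ug_per_injection
        + model.luciferase_mass_ug
        + spec.heavy_std_fmol * model.per_fmol_each_mass_ug
    )


def truth_catalog(truth: SyntheticTruth) -> list[PeptideCatalogEntry]:
    """Catalog entries matching the truth: clean peptides, controls flagged."""
    entries = []
    for pep, accession in truth.peptides.items():
        entries.append(
            PeptideCatalogEntry(
                peptide_key=pep,
                protein_accessions=(accession,),
                is_control=pep in truth.control_peptides,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Truth (de)serialization, for test harnesses and the CLI only
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, peptide_path, params_path) -> None:
    rows = []
    for pep, accession in truth.peptides.items():
        rows.append(
            {
                "peptide_key": pep,
                "protein": accession,
                "true_copies_per_cell": truth.true_copies_per_cell[accession],
                "bleed_fraction": truth.bleed_fraction[pep],
                "is_control": pep in truth.control_peptides,
                "response_factors": json.dumps(truth.response_factors[pep]),
            }
        )
    pd.DataFrame(rows).to_csv(peptide_path, sep="\t", index=False)
    params = {
        "tech_cv": truth.tech_cv,
        "bio_cv": truth.bio_cv,
        "rna_slope": truth.rna_slope,
        "rna_intercept": truth.rna_intercept,
        "rna_scatter_sd_log10": truth.rna_scatter_sd_log10,
        "seed": truth.seed,
        "control_fmol": truth.control_fmol,
    }
    Path(params_path).write_text(json.dumps(params, indent=2))


def read_truth(peptide_path, params_path) -> SyntheticTruth:
    frame = pd.read_csv(peptide_path, sep="\t")
    params = json.loads(Path(params_path).read_text())
    truth = SyntheticTruth(
        true_copies_per_cell={},
        peptides={},
        response_factors={},
        bleed_fraction={},
        **params,
    )
    controls = []
    for _, row in frame.iterrows():
        pep = row["peptide_key"]
        truth.peptides[pep] = row["protein"]
        truth.true_copies_per_cell[row["protein"]] = row["true_copies_per_cell"]
        truth.bleed_fraction[pep] = row["bleed_fraction"]
        truth.response_factors[pep] = json.loads(row["response_factors"])
        if row["is_control"]:
            controls.append(pep)
    truth.control_peptides = tuple(controls)
    return truth
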