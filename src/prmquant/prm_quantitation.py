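"""Transition areas -> per-run peptide fmol.

Implements the stable-isotope-dilution arithmetic: the light/heavy ratio is
the ratio of the summed peak areas of the *common* transitions (fragments
present and flagged quantitative in both labels; precursor/MS1 signals are
never used), the ratio times the heavy spike level gives raw light
fmol/injection, blanks provide a per-peptide bleed-through fraction that is
subtracted, and each measurement gets a rule-based quality class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    HEAVY,
    LIGHT,
    SampleSpec,
    TransitionRecord,
    transitions_to_frame,
)

logger = logging.getLogger("prmquant")

__all__ = [
    "GOOD",
    "MAYBE_POOR",
    "DISCARDED",
    "AREA_FLOOR",
    "EXTREME_RATIO_RULES",
    "PeptideMeasurement",
    "BleedEstimate",
    "common_transitions",
    "light_heavy_ratio",
    "to_fmol",
    "estimate_bleedthrough",
    "correct_bleedthrough",
    "classify_qc",
    "quantify",
]

GOOD = "Good"
MAYBE_POOR = "Maybe Poor"
DISCARDED = "Discarded"

AREA_FLOOR = 10000.0
# (heavy spike level, comparison on raw light fmol, threshold)
EXTREME_RATIO_RULES: tuple[tuple[float, str, float], ...] = (
    (1.0, ">", 10.0),
    (10.0, ">", 500.0),
    (100.0, "<", 2.0),
)
BLEED_DISCARD_FRACTION = 0.20


@dataclass
class PeptideMeasurement:
    """One peptide in one LC-MS run: ratio, fmol, correction, QC."""

    sample_id: str
    tech_rep: int
    peptide_key: str
    n_common_transitions: int = 0
    sum_light_area: float = 0.0
    sum_heavy_area: float = 0.0
    ratio_light_over_heavy: float = math.nan
    heavy_fmol: float = math.nan
    light_fmol_raw: float = math.nan
    bleed_fraction: float = 0.0
    light_fmol_corrected: float = math.nan
    qc: str = ""
    reason: str = ""

    def discard(self, reason: str) -> "PeptideMeasurement":
        self.qc = DISCARDED
        self.reason = reason
        return self


def common_transitions(records: Sequence[TransitionRecord]) -> set[tuple[str, int]]:
    """(fragment, product charge) pairs quantitative in BOTH light and heavy.

    ``records`` must all belong to one peptide in one run.
    """
    by_label: dict[str, set[tuple[str, int]]] = {LIGHT: set(), HEAVY: set()}
    for rec in records:
        if rec.quantitative:
            by_label[rec.label].add((rec.fragment_ion, rec.product_charge))
    return by_label[LIGHT] & by_label[HEAVY]


def light_heavy_ratio(records: Sequence[TransitionRecord]) -> PeptideMeasurement:
    """Sum light and heavy areas over the common transitions; ratio = sums' quotient.

    An empty common set or a zero heavy sum yields a Discarded measurement.
    """
    if not records:
        raise ValueError("no records")
    first = records[0]
    m = PeptideMeasurement(
        sample_id=first.sample_id,
        tech_rep=first.tech_rep,
        peptide_key=first.peptide_key,
    )
    common = common_transitions(records)
    m.n_common_transitions = len(common)
    if not common:
        return m.discard("no common quantitative transitions")
    for rec in records:
        if (rec.fragment_ion, rec.product_charge) in common:
            if rec.label == LIGHT:
                m.sum_light_area += rec.area
            else:
                m.sum_heavy_area += rec.area
    if m.sum_heavy_area <= 0:
        return m.discard("zero heavy signal")
    m.ratio_light_over_heavy = m.sum_light_area / m.sum_heavy_area
    return m


def to_fmol(m: PeptideMeasurement, spec: SampleSpec) -> PeptideMeasurement:
    """Convert the ratio to raw light fmol/injection using the heavy spike level."""
    if m.qc == DISCARDED:
        return m
    if spec.heavy_std_fmol <= 0:
        return m.discard("no heavy standard (level 0)")
    m.heavy_fmol = spec.heavy_std_fmol
    m.light_fmol_raw = m.ratio_light_over_heavy * spec.heavy_std_fmol
    return m


@dataclass
class BleedEstimate:
    """Per-peptide blank light/heavy ratios, by heavy spike level."""

    by_level: dict[float, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        if not self.by_level:
            return 0.0
        return float(np.mean(list(self.by_level.values())))

    def at_level(self, level: float, level_matched: bool = True) -> float:
        if level_matched and level in self.by_level:
            return self.by_level[level]
        return self.mean


def estimate_bleedthrough(
    blank_measurements: Iterable[PeptideMeasurement],
    blank_levels: Mapping[str, float],
) -> dict[str, BleedEstimate]:
    """Bleed-through per peptide from the standards-only blanks.

    The bleed fraction *is* the blank light/heavy ratio.  ``blank_levels``
    maps blank sample_id -> heavy level.  Several blanks at the same level
    are averaged.
    """
    acc: dict[str, dict[float, list[float]]] = {}
    for m in blank_measurements:
        if m.qc == DISCARDED or not math.isfinite(m.ratio_light_over_heavy):
            continue
        level = blank_levels[m.sample_id]
        acc.setdefault(m.peptide_key, {}).setdefault(level, []).append(
            m.ratio_light_over_heavy
        )
    return {
        pep: BleedEstimate(
            by_level={lvl: float(np.mean(vals)) for lvl, vals in levels.items()}
        )
        for pep, levels in acc.items()
    }


def correct_bleedthrough(
    m: PeptideMeasurement, bleed_fraction: float
) -> PeptideMeasurement:
    """Subtract the standard's light impurity; discard if it dominates.

    The bleed contribution is bleed_fraction*heavy_fmol.  If it exceeds 20%
    of the raw light abundance the measurement is discarded, so corrected
    values can never go negative.
    """
    if m.qc == DISCARDED:
        return m
    m.bleed_fraction = bleed_fraction
    contribution = bleed_fraction * m.heavy_fmol
    if contribution > BLEED_DISCARD_FRACTION * m.light_fmol_raw:
        return m.discard("bleed-through >20% of light abundance")
    m.light_fmol_corrected = m.light_fmol_raw - contribution
    return m


def _qc_class(
    n_common: int,
    sum_light: float,
    sum_heavy: float,
    level: float,
    light_fmol_raw: float,
    area_floor: float = AREA_FLOOR,
    extreme_rules: Sequence[tuple[float, str, float]] = EXTREME_RATIO_RULES,
) -> str:
    if n_common <= 2:
        return MAYBE_POOR
    if sum_light < area_floor or sum_heavy < area_floor:
        return MAYBE_POOR
    for rule_level, op, threshold in extreme_rules:
        if level == rule_level:
            if op == ">" and light_fmol_raw > threshold:
                return MAYBE_POOR
            if op == "<" and light_fmol_raw < threshold:
                return MAYBE_POOR
    return GOOD


def classify_qc(
    m: PeptideMeasurement,
    spec: SampleSpec,
    area_floor: float = AREA_FLOOR,
    extreme_rules: Sequence[tuple[float, str, float]] = EXTREME_RATIO_RULES,
) -> str:
    """Quality class of one quantified measurement.

    Maybe Poor when the common-transition count is <=2, either summed label
    area is below the sensitivity floor, or the light/heavy ratio is extreme
    for the sample's nominal spike level; Good otherwise.  The extreme-ratio
    rules key on the nominal level, not the measured heavy amount.
    """
    if m.qc == DISCARDED:
        return DISCARDED
    return _qc_class(
        m.n_common_transitions,
        m.sum_light_area,
        m.sum_heavy_area,
        spec.heavy_std_fmol,
        m.light_fmol_raw,
        area_floor=area_floor,
        extreme_rules=extreme_rules,
    )


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def quantify(
    records: Iterable[TransitionRecord] | pd.DataFrame,
    design: Iterable[SampleSpec],
    control_peptides: Iterable[str] = (),
    level_matched_bleed: bool = True,
    area_floor: float = AREA_FLOOR,
    extreme_rules: Sequence[tuple[float, str, float]] = EXTREME_RATIO_RULES,
) -> pd.DataFrame:
    """Full transition->measurement pass over a report.

    Returns one row per (sample, technical replicate, peptide) with every
    intermediate field and a discard reason where applicable.  Blank runs are
    used to estimate per-peptide bleed-through (level-matched by default,
    mean-pooled otherwise) and appear in the output flagged ``is_blank``.
    Control (spiked standard) peptides are excluded from bleed estimation.
    """
    frame = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else transitions_to_frame(records)
    )
    specs = {s.sample_id: s for s in design}
    unknown = set(frame["sample_id"]) - set(specs)
    if unknown:
        raise ValueError(f"transition report references unknown samples: {sorted(unknown)}")
    control_set = set(control_peptides)

    group_keys = ["sample_id", "tech_rep", "peptide_key"]
    tkey = group_keys + ["precursor_charge", "fragment_ion", "product_charge"]
    wide = frame.set_index(tkey + ["label"])[["area", "quantitative"]].unstack("label")
    area_l = wide.get(("area", LIGHT))
    area_h = wide.get(("area", HEAVY))
    if area_l is None or area_h is None:
        missing = LIGHT if area_l is None else HEAVY
        area_l = area_l if area_l is not None else pd.Series(np.nan, index=wide.index)
        area_h = area_h if area_h is not None else pd.Series(np.nan, index=wide.index)
        logger.warning("report contains no %s transitions at all", missing)
    quant_l = wide.get(("quantitative", LIGHT))
    quant_h = wide.get(("quantitative", HEAVY))
    common = area_l.notna() & area_h.notna()
    if quant_l is not None:
        common &= quant_l.fillna(False).astype(bool)
    if quant_h is not None:
        common &= quant_h.fillna(False).astype(bool)

    summary = pd.DataFrame(
        {
            "n_common": common.groupby(level=group_keys).sum().astype(int),
            "sum_light": area_l.where(common, 0.0).groupby(level=group_keys).sum(),
            "sum_heavy": area_h.where(common, 0.0).groupby(level=group_keys).sum(),
        }
    ).reset_index()

    rows = []
    for r in summary.itertuples(index=False):
        m = PeptideMeasurement(
            sample_id=r.sample_id,
            tech_rep=int(r.tech_rep),
            peptide_key=r.peptide_key,
            n_common_transitions=int(r.n_common),
            sum_light_area=float(r.sum_light),
            sum_heavy_area=float(r.sum_heavy),
        )
        if m.n_common_transitions == 0:
            m.discard("no common quantitative transitions")
        elif m.sum_heavy_area <= 0:
            m.discard("zero heavy signal")
        else:
            m.ratio_light_over_heavy = m.sum_light_area / m.sum_heavy_area
        rows.append(m)

    blank_levels = {s.sample_id: s.heavy_std_fmol for s in design if s.is_blank}
    blanks = [
        m
        for m in rows
        if m.sample_id in blank_levels and m.peptide_key not in control_set
    ]
    bleed = estimate_bleedthrough(blanks, blank_levels)

    out = []
    warned: set[str] = set()
    for m in rows:
        spec = specs[m.sample_id]
        if spec.is_blank:
            role = "blank"
        else:
            role = "sample"
            to_fmol(m, spec)
            if m.qc != DISCARDED:
                if m.peptide_key in control_set:
                    fraction = 0.0
                elif m.peptide_key in bleed:
                    fraction = bleed[m.peptide_key].at_level(
                        spec.heavy_std_fmol, level_matched=level_matched_bleed
                    )
                else:
                    fraction = 0.0
                    if m.peptide_key not in warned:
                        warned.add(m.peptide_key)
                        logger.warning(
                            "peptide %s absent from all blanks; bleed-through 0 assumed",
                            m.peptide_key,
                        )
                correct_bleedthrough(m, fraction)
            if m.qc != DISCARDED:
                m.qc = classify_qc(
                    m, spec, area_floor=area_floor, extreme_rules=extreme_rules
                )
        out.append(
            {
                "sample_id": m.sample_id,
                "tech_rep": m.tech_rep,
                "peptide_key": m.peptide_key,
                "role": role,
                "bio_rep": spec.bio_rep,
                "level": spec.heavy_std_fmol,
                "protein_ug": spec.protein_ug_per_injection,
                "n_common_transitions": m.n_common_transitions,
                "sum_light_area": m.sum_light_area,
                "sum_heavy_area": m.sum_heavy_area,
                "ratio_light_over_heavy": m.ratio_light_over_heavy,
                "heavy_fmol": m.heavy_fmol,
                "light_fmol_raw": m.light_fmol_raw,
                "bleed_fraction": m.bleed_fraction,
                "light_fmol_corrected": m.light_fmol_corrected,
                "qc": m.qc,
                "reason": m.reason,
            }
        )
    return pd.DataFrame(out)
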