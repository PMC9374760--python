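"""Cross-dataset consistency check between two absolute-quantitation runs.

For the proteins quantified in both datasets, per-protein A/B ratios are
formed on copies/cell values; their geometric mean is compared with the
ratio of the two cell types' total protein mass per cell — two independent
routes to the same global scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["ComparisonResult", "per_protein_ratios", "summarize_comparison"]


@dataclass(frozen=True)
class ComparisonResult:
    ratios: dict[str, float]
    geometric_mean_ratio: float
    mass_ratio: float
    log_log_r: float
    n_shared: int

    @property
    def scale_agreement(self) -> float:
        """|log10(gm ratio / mass ratio)| — 0 means perfect agreement."""
        return abs(math.log10(self.geometric_mean_ratio / self.mass_ratio))


def per_protein_ratios(
    dataset_a: Mapping[str, float], dataset_b: Mapping[str, float]
) -> dict[str, float]:
    """A/B copies-per-cell ratios over the shared accessions.

    Raises if the intersection is empty or any shared value is nonpositive.
    """
    shared = sorted(set(dataset_a) & set(dataset_b))
    if not shared:
        raise ValueError("datasets share no protein accessions")
    for accession in shared:
        if dataset_a[accession] <= 0 or dataset_b[accession] <= 0:
            raise ValueError(f"nonpositive abundance for {accession}")
    return {a: dataset_a[a] / dataset_b[a] for a in shared}


def summarize_comparison(
    ratios: Mapping[str, float],
    mass_a_pg: float,
    mass_b_pg: float,
    dataset_a: Mapping[str, float] | None = None,
    dataset_b: Mapping[str, float] | None = None,
) -> ComparisonResult:
    """Geometric-mean fold plus the per-cell protein-mass ratio.

    If the source datasets are provided, the Pearson correlation of the
    log10 abundances over the shared proteins is reported as well (OLS on
    log-log values; an orthogonal fit is deliberately not attempted).
    """
    if mass_a_pg <= 0 or mass_b_pg <= 0:
        raise ValueError("per-cell protein masses must be positive")
    if not ratios:
        raise ValueError("no ratios")
    values = np.array(list(ratios.values()), dtype=float)
    gm = float(np.exp(np.mean(np.log(values))))
    r = math.nan
    if dataset_a is not None and dataset_b is not None:
        shared = sorted(ratios)
        log_a = np.log10([dataset_a[k] for k in shared])
        log_b = np.log10([dataset_b[k] for k in shared])
        if len(shared) >= 3 and np.ptp(log_b) > 0 and np.ptp(log_a) > 0:
            r = float(np.corrcoef(log_b, log_a)[0, 1])
    return ComparisonResult(
        ratios=dict(ratios),
        geometric_mean_ratio=gm,
        mass_ratio=mass_a_pg / mass_b_pg,
        log_log_r=r,
        n_shared=len(ratios),
    )
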