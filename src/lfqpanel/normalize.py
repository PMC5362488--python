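"""Housekeeping-normalizer selection and multiplicative normalization.

Normalizer candidates must be present (non-missing) in every sample,
pass the SR/TR CV gate, and appear in the supplied housekeeping list;
the most abundant by mean linear intensity are retained. Per-sample
normalization factors are the geometric mean of the selected proteins'
intensities, rescaled to unit geometric mean across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix
from .qc import CvTable

log = logging.getLogger(__name__)


@dataclass
class HousekeepingSelection:
    """Ranked normalizer proteins plus per-sample factors."""

    table: pd.DataFrame  # index protein; columns mean_intensity, cv_sr, cv_tr
    factors: pd.Series  # per sample, geometric mean 1 across samples

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)


def read_housekeeping_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _factors(m: IntensityMatrix, proteins: list[str]) -> pd.Series:
    sub = m.intensities.loc[proteins]
    if (sub <= 0).any().any() or sub.isna().any().any():
        raise ValueError("selected proteins must be present and positive in all samples")
    log_factors = np.log(sub).mean(axis=0)
    log_factors = log_factors - log_factors.mean()  # unit geometric mean
    return np.exp(log_factors)


def select_housekeeping(
    m: IntensityMatrix,
    hk_list: set[str],
    cv: CvTable,
    cv_max: float = 20.0,
    top_n: int = 17,
) -> HousekeepingSelection:
    """Pick the top-n most abundant qualifying housekeeping proteins.

    Qualifying = present in every sample, SR and TR CV below *cv_max*,
    and member of *hk_list*. Ranked by mean linear intensity descending.
    """
    if not hk_list:
        raise ValueError("housekeeping list is empty")
    if m.log2:
        raise ValueError("selection operates on the linear-scale matrix")
    present = m.intensities.notna().all(axis=1)
    low_cv = m.proteins.isin(cv.passing(cv_max))
    in_list = m.proteins.isin(hk_list)
    qualify = m.proteins[present & low_cv & in_list]
    if len(qualify) == 0:
        raise ValueError(
            "no housekeeping candidate passes the presence + CV gates; "
            "consider relaxing cv_max or extending the housekeeping list"
        )
    means = m.intensities.loc[qualify].mean(axis=1).sort_values(ascending=False)
    if len(means) > top_n:
        means = means.iloc[:top_n]
    else:
        log.warning("only %d housekeeping candidates qualify (top_n=%d)", len(means), top_n)
    table = pd.DataFrame({"mean_intensity": means})
    table["cv_sr"] = cv.table.loc[table.index, "cv_sr"]
    table["cv_tr"] = cv.table.loc[table.index, "cv_tr"]
    table.index.name = "protein"
    return HousekeepingSelection(table=table, factors=_factors(m, list(table.index)))


def normalize_by_housekeeping(
    m: IntensityMatrix, sel: HousekeepingSelection
) -> IntensityMatrix:
    """Divide each sample by its normalization factor.

    Factors are recomputed from the current matrix state, so the transform
    is idempotent: after one application the geometric mean of the
    selected proteins is identical in every sample.
    """
    if not sel.proteins:
        raise ValueError("empty housekeeping selection")
    factors = _factors(m, sel.proteins)
    if (factors <= 0).any():
        raise ValueError("non-positive normalization factor")
    normalized = m.intensities.div(factors, axis=1)
    return m.with_intensities(normalized)
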