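"""Molecular sexing from qPCR dose ratios and brood sex-ratio tests.

In a WZ/ZZ system a female (WZ) carries one Z copy and a male (ZZ) two,
so the efficiency-corrected relative dose of a Z-linked gene against an
autosomal normalizer, calibrated on ZZ individuals, is ~0.5 for females
and ~1 for males. Two Z-linked genes must agree for a confident call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
)
from .simulate import GENE_EF1A, SEXING_GENES, Z_SEXING_GENES

__all__ = [
    "SexCall",
    "relative_dose",
    "call_sex",
    "call_sex_table",
    "brood_test",
]

DEFAULT_LOW_THRESHOLD = 0.7
DEFAULT_HIGH_THRESHOLD = 0.85


@dataclass(frozen=True)
class SexCall:
    individual_id: str
    doses: dict[str, float]
    call: str  # "female" | "male" | "ambiguous"


def relative_dose(ct_target: float, ct_reference: float,
                  efficiency: float = 1.0,
                  calibrator_dct: float = 0.0) -> float:
    """Efficiency-corrected relative dose of the target gene.

    With dCt = ct_target - ct_reference, the ratio is
    (1 + efficiency) ** (calibrator_dct - dCt): 1.0 when the individual
    matches the (ZZ) calibrator, ~0.5 when one target copy is missing.
    """
    if not 0.0 < efficiency <= 1.0:
        raise InvalidInputError("efficiency must lie in (0, 1]")
    dct = ct_target - ct_reference
    return float((1.0 + efficiency) ** (calibrator_dct - dct))


def call_sex(doses: dict[str, float],
             low: float = DEFAULT_LOW_THRESHOLD,
             high: float = DEFAULT_HIGH_THRESHOLD,
             individual_id: str = "") -> SexCall:
    """Classify one individual from its per-Z-gene dose ratios.

    Both doses below ``low`` -> female (WZ); both above ``high`` -> male
    (ZZ); anything else (including disagreement between the two genes)
    -> ambiguous.
    """
    missing = [g for g in Z_SEXING_GENES if g not in doses]
    if missing:
        raise InsufficientDataError(
            f"missing dose for gene(s): {', '.join(missing)}")
    if any(d <= 0 for d in doses.values()):
        raise InvalidInputError("dose ratios must be > 0")
    values = [doses[g] for g in Z_SEXING_GENES]
    if all(v < low for v in values):
        call = "female"
    elif all(v > high for v in values):
        call = "male"
    else:
        call = "ambiguous"
    return SexCall(individual_id, dict(doses), call)


def call_sex_table(ct_table: pd.DataFrame, efficiency: float = 1.0,
                   calibrator_dct: dict[str, float] | None = None,
                   known_males: list[str] | None = None,
                   low: float = DEFAULT_LOW_THRESHOLD,
                   high: float = DEFAULT_HIGH_THRESHOLD) -> list[SexCall]:
    """Sex every individual in a long-format Ct table.

    The table needs columns individual_id, gene, ct; replicate Ct values
    are averaged. The per-gene calibrator delta-Ct (relative to the
    autosomal normalizer) is taken from ``calibrator_dct``, or estimated
    as the median delta-Ct of ``known_males``, or defaults to 0 (equal
    base Ct across genes).
    """
    required = {"individual_id", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise InvalidInputError(
            f"Ct table needs columns {sorted(required)}")
    mean_ct = (ct_table.groupby(["individual_id", "gene"])["ct"]
               .mean().unstack())
    missing_genes = [g for g in SEXING_GENES if g not in mean_ct.columns]
    if missing_genes:
        raise InsufficientDataError(
            f"Ct table lacks gene(s): {', '.join(missing_genes)}")
    incomplete = mean_ct.index[mean_ct[list(SEXING_GENES)].isna().any(axis=1)]
    if len(incomplete) > 0:
        raise InsufficientDataError(
            f"incomplete measurements for: {', '.join(incomplete[:5])}")

    dct = mean_ct[list(Z_SEXING_GENES)].sub(mean_ct[GENE_EF1A], axis=0)
    if calibrator_dct is None:
        if known_males:
            absent = set(known_males) - set(dct.index)
            if absent:
                raise InvalidInputError(
                    f"unknown calibrator individuals: {sorted(absent)}")
            calibrator_dct = dct.loc[known_males].median().to_dict()
        else:
            calibrator_dct = {g: 0.0 for g in Z_SEXING_GENES}

    calls = []
    for iid, row in dct.iterrows():
        doses = {g: relative_dose(row[g] + mean_ct.loc[iid, GENE_EF1A],
                                  mean_ct.loc[iid, GENE_EF1A],
                                  efficiency, calibrator_dct[g])
                 for g in Z_SEXING_GENES}
        calls.append(call_sex(doses, low, high, individual_id=iid))
    return calls


def brood_test(n_female: int, n_male: int,
               null_proportion: float = 0.5) -> float:
    """Exact two-sided binomial test of a brood's sex ratio: the smaller
    exact tail probability doubled, capped at 1."""
    if n_female < 0 or n_male < 0:
        raise InvalidInputError("counts must be >= 0")
    n = n_female + n_male
    if n == 0:
        raise InvalidInputError("at least one individual required")
    if not 0.0 < null_proportion < 1.0:
        raise InvalidInputError("null proportion must lie in (0, 1)")
    k = n_female
    lower = float(stats.binom.cdf(k, n, null_proportion))
    upper = float(stats.binom.sf(k - 1, n, null_proportion))
    return float(min(1.0, 2.0 * min(lower, upper)))
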