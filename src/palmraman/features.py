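"""The 15 per-sample predictors and their class-level summaries.

From each 4-Lorentzian fit: 4 sub-band peak positions, 4 peak intensities
(fitted Lorentzian heights, not areas), 3 peak-height ratios with the
beta-carotene sub-band nu1b as numerator (nu1b/nu1a, nu1b/nu1c, nu1b/nu1d),
and 4 FWHM.  Class summaries report per-class mean/sd/n per feature and the
two ripening-transition percent changes computed on class means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconv import BAND_ASSIGNMENTS, BandFit
from .errors import UndefinedRatioError, ValidationError
from .io import FEATURE_NAMES, SUB_BANDS, RipenessLabel, validate_feature_table

__all__ = [
    "extract_features",
    "build_feature_table",
    "ClassSummary",
    "summarize_by_class",
    "intensity_ordering",
]

_RATIOS = (("ratio_b_a", "nu1a"), ("ratio_b_c", "nu1c"), ("ratio_b_d", "nu1d"))
#: Transition names, ordered along ripening.
TRANSITIONS = ("under_to_ripe", "ripe_to_over")


def extract_features(fit: BandFit) -> dict[str, float]:
    """The 15 named features of one fitted sample, in canonical order."""
    if len(fit.components) != 4:
        raise ValidationError("a band fit must carry exactly 4 labeled components")
    values: dict[str, float] = {}
    for name, comp in zip(SUB_BANDS, fit.components):
        values[f"pos_{name}"] = comp.position
    for name, comp in zip(SUB_BANDS, fit.components):
        values[f"int_{name}"] = comp.intensity
    numerator = values["int_nu1b"]
    for ratio_name, denom_band in _RATIOS:
        denom = values[f"int_{denom_band}"]
        if denom == 0:
            raise UndefinedRatioError(f"{ratio_name}: zero intensity in {denom_band}")
        values[ratio_name] = numerator / denom
    for name, comp in zip(SUB_BANDS, fit.components):
        values[f"fwhm_{name}"] = comp.fwhm
    return {k: values[k] for k in FEATURE_NAMES}


def build_feature_table(
    fits: dict[str, BandFit], labels: dict[str, RipenessLabel | None]
) -> pd.DataFrame:
    """Assemble per-sample features into the canonical 17-column table."""
    rows = []
    for sid, fit in fits.items():
        row = {"sample_id": sid, "label": labels.get(sid)}
        row.update(extract_features(fit))
        rows.append(row)
    table = pd.DataFrame.from_records(rows, columns=["sample_id", "label", *FEATURE_NAMES])
    return validate_feature_table(table)


@dataclass(frozen=True)
class ClassSummary:
    """Per-class feature statistics and ripening-transition percent changes.

    ``means``/``sds``/``ns`` are indexed by class name with one column per
    feature; ``percent_changes`` is indexed by feature with one column per
    transition, 100 * (mean_after - mean_before) / mean_before.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    ns: pd.Series
    percent_changes: pd.DataFrame


def summarize_by_class(table: pd.DataFrame) -> ClassSummary:
    """Class-wise mean/sd/n per feature plus the two transition percent changes."""
    table = validate_feature_table(table)
    class_names = [lab.name for lab in RipenessLabel]
    groups = {}
    for lab in RipenessLabel:
        sub = table[table["label"] == lab]
        if len(sub) < 2:
            raise ValidationError(f"class {lab.name} needs at least 2 samples")
        groups[lab.name] = sub.loc[:, list(FEATURE_NAMES)].astype(float)
    means = pd.DataFrame({name: g.mean() for name, g in groups.items()}).T.loc[class_names]
    sds = pd.DataFrame({name: g.std(ddof=1) for name, g in groups.items()}).T.loc[class_names]
    ns = pd.Series({name: len(g) for name, g in groups.items()}).loc[class_names]
    changes = {}
    for transition, (before, after) in zip(
        TRANSITIONS, (("UNDER_RIPE", "RIPE"), ("RIPE", "OVER_RIPE"))
    ):
        changes[transition] = 100.0 * (means.loc[after] - means.loc[before]) / means.loc[before]
    percent_changes = pd.DataFrame(changes).loc[list(FEATURE_NAMES)]
    return ClassSummary(means=means, sds=sds, ns=ns, percent_changes=percent_changes)


def intensity_ordering(summary: ClassSummary, label: RipenessLabel) -> list[str]:
    """Molecules sorted by descending class-mean fitted intensity.

    Ties are broken by sub-band index (nu1a first), keeping the ordering
    deterministic.
    """
    means = [summary.means.loc[label.name, f"int_{b}"] for b in SUB_BANDS]
    order = sorted(range(4), key=lambda i: (-means[i], i))
    return [BAND_ASSIGNMENTS[SUB_BANDS[i]][0] for i in order]
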