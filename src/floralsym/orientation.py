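"""Orientation arithmetic and orientation-distribution tests.

Orientations are compass directions in degrees, recorded to the nearest
60 degrees with 0 pointing south and angles increasing clockwise. The
orientation of an organ relative to its flower's outer spathe is the
clockwise angle from the spathe to the organ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SECTORS = (0, 60, 120, 180, 240, 300)

#: Relative orientations of the three falls (and style branches) when the
#: flower sits in the arrangement expected from the floral ground plan,
#: with one fall directly above the outer spathe.
EXPECTED_FALL_SECTORS = frozenset({0, 120, 240})
ROTATED_FALL_SECTORS = frozenset({60, 180, 300})


def _validate_sector(deg, what: str) -> int:
    deg = int(deg)
    if deg % 60 != 0 or not (0 <= deg <= 300):
        raise ValueError(
            f"{what} must be a multiple of 60 in [0, 300], got {deg}"
        )
    return deg


def relative_orientation(organ_compass, spathe_compass) -> int:
    """Clockwise angle from the outer spathe to an organ, in degrees.

    Computed as (organ - spathe) mod 360, i.e. the spathe orientation is
    subtracted from the organ's compass orientation and 360 is added if
    the result is negative. Both inputs must be multiples of 60 in
    [0, 300]; the result is too.
    """
    organ = _validate_sector(organ_compass, "organ compass orientation")
    spathe = _validate_sector(spathe_compass, "spathe orientation")
    return (organ - spathe) % 360


def classify_alignment(fall_relative_orientations) -> str:
    """Classify a flower from its falls' relative orientations.

    Returns ``"expected"`` when the falls sit at relative orientations
    {0, 120, 240} (one fall directly above the outer spathe) and
    ``"rotated60"`` when they sit at {60, 180, 300}.

    Raises
    ------
    ValueError
        If the flower has no falls with known orientation, or its falls'
        orientations mix the two classes.
    """
    sectors = {_validate_sector(o, "relative orientation")
               for o in fall_relative_orientations}
    if not sectors:
        raise ValueError("flower has no falls with known orientation")
    if sectors <= EXPECTED_FALL_SECTORS:
        return "expected"
    if sectors <= ROTATED_FALL_SECTORS:
        return "rotated60"
    raise ValueError(
        f"inconsistent fall orientations {sorted(sectors)}: "
        "mix of expected and rotated60 sectors"
    )


@dataclass
class UniformityTestResult:
    chi_square: float
    df: int
    p_value: float


def orientation_uniformity_test(counts) -> UniformityTestResult:
    """Pearson chi-square test of the six sector counts against uniformity.

    ``counts`` are the observed numbers of flowers per 60-degree sector;
    the expected count is the total divided by six, and df = 5.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (6,):
        raise ValueError(f"expected 6 sector counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("sector counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("total count is zero")
    chi2, p = stats.chisquare(counts)
    return UniformityTestResult(chi_square=float(chi2), df=5, p_value=float(p))


def orientation_summary(organs: pd.DataFrame) -> pd.DataFrame:
    """Tabulate organ counts per compass sector, relative sector and alignment.

    ``organs`` is the annotated per-organ table from
    :func:`floralsym.landmarks.join_metadata`. Returns a tidy table with
    one row per (organ_type, grouping, level).
    """
    rows = []
    for organ_type, sub in organs.groupby("organ_type"):
        for grouping in ("compass_orientation", "relative_orientation"):
            if grouping not in sub.columns:
                continue
            counts = sub[grouping].value_counts()
            for sector in SECTORS:
                rows.append(
                    {"organ_type": organ_type, "grouping": grouping,
                     "level": sector, "n": int(counts.get(sector, 0))}
                )
    if "alignment" in organs.columns:
        flowers = organs.drop_duplicates("flower_id")
        for level, n in flowers["alignment"].value_counts().items():
            rows.append({"organ_type": "flower", "grouping": "alignment",
                         "level": level, "n": int(n)})
    return pd.DataFrame(rows)
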