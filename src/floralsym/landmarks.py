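"""Landmark configurations, bilateral pairing schemes, and file I/O.

Landmark data are exchanged in the tps format commonly produced by
digitizing software (``LM=`` count header, one ``x y`` pair per line,
optional ``SCALE=`` and ``ID=`` fields), with per-organ metadata in a
delimited table. Landmark indices are 1-based in all interfaces, matching
morphometric convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Landmark counts per floral organ type.
LANDMARK_COUNTS: dict[str, int] = {
    "fall": 18,
    "standard": 19,
    "style_branch": 18,
}

ORGAN_TYPES = tuple(LANDMARK_COUNTS)


@dataclass
class LandmarkConfiguration:
    """One floral organ's 2D landmark coordinates plus identity metadata.

    Parameters
    ----------
    organ_id : str
        Unique identifier of the organ record.
    flower_id : str
        Identifier of the flower the organ belongs to.
    organ_type : str
        One of ``fall``, ``standard``, ``style_branch``.
    coords : (k, 2) ndarray
        Landmark coordinates in millimeters, ordered by landmark index.
    compass_orientation : int or None
        Compass orientation of the organ in degrees, a multiple of 60 in
        [0, 300]; 0 degrees points south. ``None`` if not yet annotated.
    """

    organ_id: str
    flower_id: str
    organ_type: str
    coords: np.ndarray
    compass_orientation: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"organ {self.organ_id!r}: coords must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError(f"organ {self.organ_id!r}: non-finite coordinates")
        if self.organ_type not in LANDMARK_COUNTS:
            raise ValueError(
                f"organ {self.organ_id!r}: unknown organ_type {self.organ_type!r}"
            )
        expected = LANDMARK_COUNTS[self.organ_type]
        if len(self.coords) != expected:
            raise ValueError(
                f"organ {self.organ_id!r}: {self.organ_type} requires "
                f"{expected} landmarks, got {len(self.coords)}"
            )
        if self.compass_orientation is not None:
            _check_sector(self.compass_orientation, f"organ {self.organ_id!r}")

    @property
    def k(self) -> int:
        return len(self.coords)


def _check_sector(deg: int, what: str) -> int:
    deg = int(deg)
    if deg % 60 != 0 or not (0 <= deg <= 300):
        raise ValueError(
            f"{what}: orientation must be a multiple of 60 in [0, 300], got {deg}"
        )
    return deg


@dataclass
class PairingScheme:
    """Paired-landmark map defining an organ's internal bilateral symmetry.

    ``pairs`` holds (left, right) 1-based landmark indices; ``midline``
    the indices lying on the symmetry axis. Together they must partition
    {1..k}.
    """

    organ_type: str
    pairs: list[tuple[int, int]]
    midline: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pair in self.pairs:
            left, right = pair
            for idx in (left, right):
                if idx in seen:
                    raise ValueError(f"landmark index {idx} appears twice in pairing")
                seen.add(idx)
        for idx in self.midline:
            if idx in seen:
                raise ValueError(f"landmark index {idx} in both pairs and midline")
            seen.add(idx)
        k = len(seen)
        if seen != set(range(1, k + 1)):
            raise ValueError(
                f"pairs and midline must partition 1..{k}, got indices {sorted(seen)}"
            )

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def permutation(self) -> np.ndarray:
        """0-based index permutation swapping left and right labels."""
        perm = np.arange(self.k)
        for left, right in self.pairs:
            perm[left - 1] = right - 1
            perm[right - 1] = left - 1
        return perm


# ---------------------------------------------------------------------------
# tps files


def write_tps(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    """Write landmark configurations to a tps file (full float precision)."""
    path = Path(path)
    with path.open("w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={cfg.organ_id}\n")


def read_landmarks(
    path: str | Path,
    organ_type: str,
    flower_ids: dict[str, str] | None = None,
) -> list[LandmarkConfiguration]:
    """Read a tps file of landmark configurations of one organ type.

    Applies any ``SCALE=`` factor on read so that coordinates are in
    millimeters. ``flower_ids`` optionally maps organ id to flower id;
    by default the flower id is the part of the organ id before the first
    ``:`` (the convention used by :func:`write_tps` on simulated data).

    Raises
    ------
    ValueError
        If a record has the wrong landmark count or is malformed; the
        offending record is identified in the message.
    """
    if organ_type not in LANDMARK_COUNTS:
        raise ValueError(f"unknown organ_type {organ_type!r}")
    path = Path(path)
    records: list[dict] = []
    current: dict | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                current = {"n": int(line.split("=", 1)[1]), "coords": [],
                           "id": None, "scale": None, "lineno": lineno}
                records.append(current)
            elif current is None:
                raise ValueError(f"{path}:{lineno}: coordinate data before LM= header")
            elif upper.startswith("ID="):
                current["id"] = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                current["scale"] = float(line.split("=", 1)[1])
            elif upper.startswith(("IMAGE=", "COMMENT=", "CURVES=", "POINTS=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed coordinate line {line!r}")
                current["coords"].append((float(parts[0]), float(parts[1])))

    configs = []
    for i, rec in enumerate(records):
        organ_id = rec["id"] if rec["id"] is not None else f"record_{i + 1}"
        if len(rec["coords"]) != rec["n"]:
            raise ValueError(
                f"{path}: record {organ_id!r} declares LM={rec['n']} but has "
                f"{len(rec['coords'])} coordinate lines"
            )
        coords = np.array(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        expected = LANDMARK_COUNTS[organ_type]
        if len(coords) != expected:
            raise ValueError(
                f"{path}: record {organ_id!r}: {organ_type} requires {expected} "
                f"landmarks, found {len(coords)}"
            )
        if flower_ids is not None:
            flower = flower_ids.get(organ_id, "")
        else:
            flower = organ_id.split(":", 1)[0]
        configs.append(
            LandmarkConfiguration(
                organ_id=organ_id, flower_id=flower,
                organ_type=organ_type, coords=coords,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# metadata


def write_metadata(organs: pd.DataFrame, path: str | Path) -> None:
    """Write the per-organ metadata table as CSV."""
    organs.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-organ metadata CSV.

    Required columns: ``organ_id``, ``flower_id``, ``organ_type``,
    ``compass_orientation``, ``spathe_orientation``. Additional columns
    (``plant_id``, ``alignment``) are carried through.
    """
    df = pd.read_csv(path, dtype={"organ_id": str, "flower_id": str})
    required = {"organ_id", "flower_id", "organ_type",
                "compass_orientation", "spathe_orientation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return df


def join_metadata(
    configs: list[LandmarkConfiguration],
    records,
) -> pd.DataFrame:
    """Bind organs to their flower records and derive orientation fields.

    Parameters
    ----------
    configs : list of LandmarkConfiguration
        Organs, each carrying ``flower_id`` and ``compass_orientation``.
    records : list of FlowerRecord or DataFrame
        Flower-level metadata with ``flower_id``, ``spathe_orientation``
        and optionally ``plant_id`` / ``alignment``.

    Returns
    -------
    DataFrame
        One row per organ with compass, spathe and relative orientation.
        Flowers with missing organs are retained and logged.

    Raises
    ------
    KeyError
        If any organ's flower id is absent from the records; all
        offenders are listed.
    """
    from .orientation import relative_orientation

    if isinstance(records, pd.DataFrame):
        flowers = records
    else:
        flowers = pd.DataFrame(
            [{"flower_id": r.flower_id, "plant_id": r.plant_id,
              "spathe_orientation": r.spathe_orientation,
              "alignment": r.alignment} for r in records]
        )
    flowers = flowers.set_index("flower_id")

    orphans = sorted(
        {c.flower_id for c in configs} - set(flowers.index.astype(str))
    )
    if orphans:
        raise KeyError(
            f"{len(orphans)} organ flower_id(s) missing from flower records: {orphans}"
        )

    rows = []
    for cfg in configs:
        fl = flowers.loc[cfg.flower_id]
        row = {
            "organ_id": cfg.organ_id,
            "flower_id": cfg.flower_id,
            "organ_type": cfg.organ_type,
            "compass_orientation": cfg.compass_orientation,
            "spathe_orientation": int(fl["spathe_orientation"]),
        }
        if cfg.compass_orientation is not None:
            row["relative_orientation"] = relative_orientation(
                cfg.compass_orientation, int(fl["spathe_orientation"])
            )
        for extra in ("plant_id", "alignment"):
            if extra in fl.index:
                row[extra] = fl[extra]
        rows.append(row)
    df = pd.DataFrame(rows)

    counts = df.groupby("flower_id")["organ_id"].count()
    incomplete = counts[counts < counts.max()]
    if len(incomplete):
        logger.info(
            "%d flower(s) with missing organs retained: %s",
            len(incomplete), dict(incomplete),
        )
    return df


# ---------------------------------------------------------------------------
# pairing-scheme files


def write_pairing(scheme: PairingScheme, path: str | Path) -> None:
    """Write a pairing scheme as plain text (one pair per line)."""
    with Path(path).open("w") as fh:
        fh.write(f"organ_type {scheme.organ_type}\n")
        fh.write("pairs\n")
        for left, right in scheme.pairs:
            fh.write(f"{left} {right}\n")
        fh.write("midline\n")
        for idx in scheme.midline:
            fh.write(f"{idx}\n")


def read_pairing(path: str | Path) -> PairingScheme:
    """Read a pairing scheme from its plain-text format."""
    organ_type = None
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []
    section = None
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("organ_type"):
                organ_type = line.split()[1]
            elif line == "pairs":
                section = "pairs"
            elif line == "midline":
                section = "midline"
            elif section == "pairs":
                left, right = line.split()
                pairs.append((int(left), int(right)))
            elif section == "midline":
                midline.append(int(line))
            else:
                raise ValueError(f"{path}: unexpected line {line!r}")
    if organ_type is None:
        raise ValueError(f"{path}: missing organ_type line")
    return PairingScheme(organ_type=organ_type, pairs=pairs, midline=midline)
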