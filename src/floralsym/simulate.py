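"""Synthetic flower datasets with known directional-asymmetry structure.

The generator emulates the layered design of the field study: each flower
carries three falls, three standards and three style branches, the outer
spathe points into one of six 60-degree compass sectors, and the perianth
either sits in the arrangement expected from the floral ground plan (one
fall directly above the outer spathe) or is rotated by 60 degrees. On top
of a bilaterally symmetric template shape per organ type, four layered
effects are injected in the organ's own frame before size scaling:

* a compass-linked displacement field (directional asymmetry driven by a
  consistent environmental gradient such as solar irradiance),
* a relative-orientation displacement field (anatomical-position effects),
* a left-right antisymmetric field shared by all organs of a type (the
  "pinwheel" component),
* isotropic fluctuating-asymmetry deviations per organ,

followed by scaling to a drawn centroid size and per-landmark digitizing
noise in millimeters. Every effect amplitude is a free parameter, so each
downstream analysis stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .landmarks import (
    LANDMARK_COUNTS,
    LandmarkConfiguration,
    PairingScheme,
)
from .procrustes import _preshape, centroid_size, reflect_relabel

__all__ = [
    "SimulationParams",
    "FlowerRecord",
    "generate_dataset",
    "default_template",
    "default_pairing",
    "default_compass_fields",
    "default_organ_da",
    "symmetric_field",
    "antisymmetric_field",
    "write_dataset",
    "organs_table",
]

ORGAN_TYPES = ("fall", "standard", "style_branch")

#: Relative orientations of each whorl's organs when the flower is in the
#: expected arrangement; the rotated60 arrangement adds 60 degrees.
WHORL_OFFSETS = {
    "fall": (0, 120, 240),
    "standard": (60, 180, 300),
    "style_branch": (0, 120, 240),
}

# half-outline profiles (y position, half width) for the default templates
_PROFILES = {
    "fall": (
        [0.06, 0.20, 0.36, 0.52, 0.66, 0.78, 0.88, 0.96],
        [0.10, 0.18, 0.24, 0.28, 0.30, 0.28, 0.22, 0.12],
    ),
    "standard": (
        [0.06, 0.20, 0.36, 0.52, 0.66, 0.78, 0.88, 0.96],
        [0.08, 0.20, 0.30, 0.36, 0.38, 0.36, 0.28, 0.16],
    ),
    "style_branch": (
        [0.08, 0.22, 0.38, 0.54, 0.68, 0.80, 0.90, 0.97],
        [0.14, 0.22, 0.27, 0.30, 0.30, 0.27, 0.20, 0.10],
    ),
}


def default_template(organ_type: str) -> np.ndarray:
    """Built-in symmetric polygon template for an organ type.

    A petal-like outline: landmark 1 at the base and landmark 10 at the
    apex on the midline, eight left/right landmark pairs along the
    margins, plus (standards only) landmark 19 on the midline near the
    apex, for the study's landmark counts (falls 18, standards 19, style
    branches 18). Centered, unit centroid size, symmetry axis on the
    y-axis.
    """
    if organ_type not in _PROFILES:
        raise ValueError(f"unknown organ_type {organ_type!r}")
    ys, ws = _PROFILES[organ_type]
    pts = [(0.0, 0.0)]  # 1: base
    pts += [(-w, y) for y, w in zip(ys, ws)]  # 2-9: left margin, base to apex
    pts += [(0.0, 1.0)]  # 10: apex
    pts += [(w, y) for y, w in zip(reversed(ys), reversed(ws))]  # 11-18: right
    if organ_type == "standard":
        pts += [(0.0, 0.80)]  # 19: nerve branching point near the apex
    X = np.array(pts, dtype=float)
    assert len(X) == LANDMARK_COUNTS[organ_type]
    Xc = X - X.mean(axis=0)
    Xc[:, 0] = X[:, 0]  # keep the symmetry axis exactly at x = 0
    Xc[:, 1] = X[:, 1] - X[:, 1].mean()
    return Xc / centroid_size(Xc)


def default_pairing(organ_type: str) -> PairingScheme:
    """Pairing scheme matching :func:`default_template`."""
    pairs = [(2 + i, 18 - i) for i in range(8)]  # (2,18), (3,17), ... (9,11)
    midline = [1, 10] + ([19] if organ_type == "standard" else [])
    return PairingScheme(organ_type=organ_type, pairs=pairs, midline=midline)


def _unit(field: np.ndarray) -> np.ndarray:
    return field / np.linalg.norm(field)


def symmetric_field(template: np.ndarray, kind: str) -> np.ndarray:
    """Unit-norm displacement field invariant under reflect-and-relabel.

    ``"elongation"`` stretches along the midline axis; ``"widening"``
    spreads the margins away from it.
    """
    d = np.zeros_like(template)
    if kind == "elongation":
        d[:, 1] = template[:, 1] - template[:, 1].mean()
    elif kind == "widening":
        d[:, 0] = template[:, 0]
    else:
        raise ValueError(f"unknown symmetric field kind {kind!r}")
    return _unit(d)


def antisymmetric_field(template: np.ndarray, kind: str) -> np.ndarray:
    """Unit-norm displacement field that negates under reflect-and-relabel.

    ``"shear"`` displaces landmarks sideways in proportion to height (the
    pinwheel tilt); ``"tilt"`` raises one margin and lowers the other.
    """
    d = np.zeros_like(template)
    if kind == "shear":
        d[:, 0] = template[:, 1] - template[:, 1].mean()
    elif kind == "tilt":
        d[:, 1] = template[:, 0]
    else:
        raise ValueError(f"unknown antisymmetric field kind {kind!r}")
    return _unit(d)


def default_compass_fields(
    template: np.ndarray,
    amplitude: float = 0.01,
    asym_fraction: float = 0.7,
) -> np.ndarray:
    """Per-sector displacement fields for a compass-linked gradient.

    Sector s at angle theta = 60 s degrees receives
    ``amplitude * (cos(theta) * elongation + sin(theta) * widening)``
    plus an antisymmetric part ``amplitude * asym_fraction * cos(theta) *
    shear``, so the six sector means differ in both the symmetric and the
    asymmetric shape component, as a consistent environmental gradient
    would produce. Returns a (6, k, 2) array.
    """
    e1 = symmetric_field(template, "elongation")
    e2 = symmetric_field(template, "widening")
    a1 = antisymmetric_field(template, "shear")
    out = np.zeros((6,) + template.shape)
    for s in range(6):
        theta = np.deg2rad(60 * s)
        out[s] = amplitude * (
            np.cos(theta) * e1 + np.sin(theta) * e2
            + asym_fraction * np.cos(theta) * a1
        )
    return out


def default_organ_da(template: np.ndarray, amplitude: float = 0.01) -> np.ndarray:
    """Left-right antisymmetric field shared by all organs of a type."""
    return amplitude * antisymmetric_field(template, "shear")


@dataclass
class FlowerRecord:
    """Flower-level metadata: identity, spathe sector and alignment class."""

    flower_id: str
    plant_id: str
    spathe_orientation: int
    alignment: str  # "expected" | "rotated60"

    def __post_init__(self) -> None:
        if self.spathe_orientation % 60 != 0 or not (
            0 <= self.spathe_orientation <= 300
        ):
            raise ValueError(
                f"flower {self.flower_id!r}: spathe orientation must be a "
                f"multiple of 60 in [0, 300], got {self.spathe_orientation}"
            )
        if self.alignment not in ("expected", "rotated60"):
            raise ValueError(f"unknown alignment {self.alignment!r}")


def _default_templates() -> dict[str, np.ndarray]:
    return {t: default_template(t) for t in ORGAN_TYPES}


def _default_sizes() -> dict[str, float]:
    # organ mean centroid sizes (mm), matched to the field study
    return {"fall": 350.0, "standard": 355.0, "style_branch": 217.0}


def _default_size_sds() -> dict[str, float]:
    return {"fall": 42.0, "standard": 44.0, "style_branch": 26.0}


@dataclass
class SimulationParams:
    """Parameters of the synthetic flower generator.

    Displacement fields (``compass_da``, ``relative_da``, ``organ_da``) are
    (6, k, 2) resp. (k, 2) arrays per organ type, applied to the unit-size
    template before scaling; ``fa_sd`` is the per-coordinate SD of the
    isotropic fluctuating-asymmetry deviation in the same units, and
    ``noise_sd`` the per-coordinate digitizing-error SD in millimeters,
    applied after scaling. ``p_expected_alignment`` is the probability
    that a flower sits in the ground-plan arrangement rather than rotated
    by 60 degrees. Defaults reproduce the study conditions: a clear
    compass effect, no relative-orientation effect, and a shared pinwheel
    asymmetry per organ.
    """

    n_flowers: int = 462
    templates: dict = field(default_factory=_default_templates)
    mean_size: dict = field(default_factory=_default_sizes)
    size_sd: dict = field(default_factory=_default_size_sds)
    compass_da: dict = field(default_factory=dict)
    relative_da: dict = field(default_factory=dict)
    organ_da: dict = field(default_factory=dict)
    fa_sd: float = 0.005
    noise_sd: float = 0.5
    p_expected_alignment: float = 315 / 462
    spathe_orientation_weights: np.ndarray = field(
        default_factory=lambda: np.full(6, 1 / 6)
    )
    organ_types: tuple = ORGAN_TYPES
    seed: int | None = None

    @classmethod
    def defaults(
        cls,
        n_flowers: int = 462,
        compass_amplitude: float = 0.01,
        relative_amplitude: float = 0.0,
        organ_da_amplitude: float = 0.01,
        seed: int | None = None,
        **kwargs,
    ) -> "SimulationParams":
        """Study-condition defaults with adjustable effect amplitudes."""
        templates = _default_templates()
        compass = {
            t: default_compass_fields(templates[t], compass_amplitude)
            for t in ORGAN_TYPES
        }
        relative = {
            t: default_compass_fields(templates[t], relative_amplitude)
            for t in ORGAN_TYPES
        }
        organ = {
            t: default_organ_da(templates[t], organ_da_amplitude)
            for t in ORGAN_TYPES
        }
        return cls(
            n_flowers=n_flowers, templates=templates, compass_da=compass,
            relative_da=relative, organ_da=organ, seed=seed, **kwargs,
        )

    def validate(self) -> None:
        if self.n_flowers < 1:
            raise ValueError("n_flowers must be at least 1")
        if not (0.0 <= self.p_expected_alignment <= 1.0):
            raise ValueError("p_expected_alignment must be in [0, 1]")
        w = np.asarray(self.spathe_orientation_weights, dtype=float)
        if w.shape != (6,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                "spathe_orientation_weights must be 6 non-negative "
                "probabilities summing to 1"
            )
        if self.fa_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(self.size_sd.get(t, 0.0) < 0 for t in self.organ_types):
            raise ValueError("size_sd must be non-negative")
        for t in self.organ_types:
            template = self.templates[t]
            if len(template) != LANDMARK_COUNTS[t]:
                raise ValueError(
                    f"template for {t} must have {LANDMARK_COUNTS[t]} landmarks"
                )
            pairing = default_pairing(t)
            mirrored = reflect_relabel(_preshape(template), pairing)
            if np.linalg.norm(mirrored - _preshape(template)) > 1e-8:
                raise ValueError(
                    f"template for {t} is not symmetric under "
                    "reflect-and-relabel"
                )

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        """Write the parameters to a structured text config file."""
        def arr(a):
            return np.asarray(a).tolist()

        doc = {
            "n_flowers": self.n_flowers,
            "templates": {t: arr(v) for t, v in self.templates.items()},
            "mean_size": dict(self.mean_size),
            "size_sd": dict(self.size_sd),
            "compass_da": {t: arr(v) for t, v in self.compass_da.items()},
            "relative_da": {t: arr(v) for t, v in self.relative_da.items()},
            "organ_da": {t: arr(v) for t, v in self.organ_da.items()},
            "fa_sd": self.fa_sd,
            "noise_sd": self.noise_sd,
            "p_expected_alignment": self.p_expected_alignment,
            "spathe_orientation_weights": arr(self.spathe_orientation_weights),
            "organ_types": list(self.organ_types),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        doc = yaml.safe_load(Path(path).read_text())
        for key in ("templates", "compass_da", "relative_da", "organ_da"):
            doc[key] = {t: np.asarray(v) for t, v in doc.get(key, {}).items()}
        doc["spathe_orientation_weights"] = np.asarray(
            doc["spathe_orientation_weights"]
        )
        doc["organ_types"] = tuple(doc["organ_types"])
        return cls(**doc)


def _assign_plants(n_flowers: int) -> list[str]:
    """Plant ids with roughly the field study's two-flowers-per-plant share."""
    n_plants = max(1, round(n_flowers * 314 / 462))
    n_pairs = n_flowers - n_plants
    ids = []
    plant = 0
    for _ in range(n_pairs):
        plant += 1
        ids += [f"P{plant:04d}"] * 2
    while len(ids) < n_flowers:
        plant += 1
        ids.append(f"P{plant:04d}")
    return ids[:n_flowers]


def generate_dataset(
    params: SimulationParams,
) -> tuple[list[FlowerRecord], list[LandmarkConfiguration]]:
    """Simulate a flower dataset.

    Returns flower-level records and one landmark configuration per organ
    (three falls, three standards, three style branches per flower, unless
    ``params.organ_types`` restricts the whorls). Identical parameters and
    seed reproduce the dataset bit for bit. Each organ is written at a
    random position and rotation on its "scanner bed", as digitized data
    would be.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    plant_ids = _assign_plants(params.n_flowers)

    records: list[FlowerRecord] = []
    configs: list[LandmarkConfiguration] = []
    sectors = np.arange(6) * 60
    for i in range(params.n_flowers):
        flower_id = f"F{i + 1:04d}"
        spathe = int(rng.choice(sectors, p=params.spathe_orientation_weights))
        expected = rng.random() < params.p_expected_alignment
        alignment = "expected" if expected else "rotated60"
        records.append(FlowerRecord(flower_id, plant_ids[i], spathe, alignment))

        for organ_type in params.organ_types:
            template = params.templates[organ_type]
            k = len(template)
            compass_da = params.compass_da.get(organ_type)
            relative_da = params.relative_da.get(organ_type)
            organ_da = params.organ_da.get(organ_type)
            for pos, offset in enumerate(WHORL_OFFSETS[organ_type]):
                relative = (offset + (0 if expected else 60)) % 360
                compass = (spathe + relative) % 360
                shape = template.copy()
                if compass_da is not None:
                    shape = shape + compass_da[compass // 60]
                if relative_da is not None:
                    shape = shape + relative_da[relative // 60]
                if organ_da is not None:
                    shape = shape + organ_da
                if params.fa_sd > 0:
                    shape = shape + rng.normal(0.0, params.fa_sd, size=(k, 2))
                size = rng.normal(
                    params.mean_size[organ_type], params.size_sd[organ_type]
                )
                size = abs(size) if size != 0 else params.mean_size[organ_type]
                coords = shape / centroid_size(shape) * size
                # arbitrary digitizing pose: random rotation + offset
                theta = rng.uniform(0.0, 2 * np.pi)
                rot = np.array(
                    [[np.cos(theta), np.sin(theta)],
                     [-np.sin(theta), np.cos(theta)]]
                )
                coords = coords @ rot + rng.uniform(0.0, 1000.0, size=2)
                if params.noise_sd > 0:
                    coords = coords + rng.normal(
                        0.0, params.noise_sd, size=(k, 2)
                    )
                configs.append(
                    LandmarkConfiguration(
                        organ_id=f"{flower_id}:{organ_type}:{pos + 1}",
                        flower_id=flower_id,
                        organ_type=organ_type,
                        coords=coords,
                        compass_orientation=compass,
                    )
                )
    return records, configs


def organs_table(records, configs):
    """Annotated per-organ metadata table for a simulated dataset."""
    from .landmarks import join_metadata

    return join_metadata(configs, records)


def write_dataset(records, configs, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as tps files (one per organ type) plus metadata CSV."""
    from .landmarks import write_metadata, write_tps

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for organ_type in ORGAN_TYPES:
        subset = [c for c in configs if c.organ_type == organ_type]
        if not subset:
            continue
        path = directory / f"{organ_type}.tps"
        write_tps(subset, path)
        paths[organ_type] = path
    meta = organs_table(records, configs)
    meta_path = directory / "metadata.csv"
    write_metadata(meta, meta_path)
    paths["metadata"] = meta_path
    return paths
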