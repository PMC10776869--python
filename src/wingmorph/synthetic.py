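"""Synthetic mosquito-wing landmark datasets.

Generates 17-landmark, 2-D wing configurations with the statistical
structure the downstream morphometric analysis assumes: group-specific
mean-shape offsets concentrated at named landmarks, log-normal centroid
sizes (equal in mean across the *Culex pipiens*-subgroup taxa, distinct
for the outgroups), a weak common allometric shape–size trend, isotropic
Gaussian landmark noise, and nuisance rotation/translation/scale that
superimposition must remove.

The default specification mirrors a six-taxon study design — three
near-indistinguishable *Culex pipiens*-subgroup taxa (PAL, MOL, PIP)
plus three outgroup vector species (SIN, TRI, ALB) — with per-taxon
sample sizes 47/67/17/45/40/35.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .procrustes import centroid_size
from .tps import LandmarkConfiguration, LandmarkDataset

__all__ = ["GroupSpec", "Nuisance", "GeneratorSpec", "default_spec", "generate"]


# Stylized 17-landmark right-wing template (vein junctions/terminations
# along an elongated wing outline, then inner cross-vein points).  The
# exact coordinates are arbitrary plumbing; only their role as a fixed,
# non-degenerate mean shape matters.  Normalized to zero centroid and
# unit centroid size at spec construction.
_RAW_TEMPLATE = np.array(
    [
        (0.00, 0.10),  # LM1  wing base, anterior margin
        (0.25, 0.28),  # LM2
        (0.90, 0.46),  # LM3
        (1.45, 0.42),  # LM4
        (1.80, 0.28),  # LM5
        (1.95, 0.10),  # LM6  wing tip
        (1.75, -0.05),  # LM7
        (1.45, -0.15),  # LM8
        (1.05, -0.22),  # LM9
        (0.65, -0.25),  # LM10
        (0.30, -0.18),  # LM11 posterior margin, toward base
        (0.55, 0.05),  # LM12 inner vein junctions
        (0.85, 0.12),  # LM13
        (1.15, 0.10),  # LM14
        (1.40, 0.02),  # LM15
        (0.95, -0.05),  # LM16
        (0.60, -0.08),  # LM17
    ]
)


def _normalize_template(raw: np.ndarray) -> np.ndarray:
    t = raw - raw.mean(axis=0)
    return t / centroid_size(t)


@dataclass(frozen=True)
class GroupSpec:
    """One taxon's generative parameters.

    ``shape_offset`` is the taxon's mean-shape displacement from the
    template, expressed in the template's tangent space (a (k, 2) array
    of Procrustes-scale coordinates).
    """

    name: str
    n: int
    shape_offset: np.ndarray
    mean_log_cs: float
    sd_log_cs: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"group {self.name}: n must be >= 1")
        if self.sd_log_cs < 0:
            raise ValueError(f"group {self.name}: sd_log_cs must be >= 0")
        object.__setattr__(self, "shape_offset", np.asarray(self.shape_offset, dtype=float))


@dataclass(frozen=True)
class Nuisance:
    """Ranges for the nuisance transform applied after shape generation.

    rotation : bool
        Uniform random rotation over [0, 2π).
    translation : float
        Each axis translated by U(−translation, +translation).
    scale_range : (lo, hi)
        Global scale factor U(lo, hi); the default (1, 1) is the
        identity, so measured centroid sizes equal the drawn sizes.
    """

    rotation: bool = True
    translation: float = 5.0
    scale_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < lo <= hi")
        if self.translation < 0:
            raise ValueError("translation range must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    template: np.ndarray
    groups: tuple[GroupSpec, ...]
    allometric_slope: np.ndarray
    landmark_noise_sd: float
    nuisance: Nuisance = Nuisance()
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.template, dtype=float)
        if abs(centroid_size(t) - 1.0) > 1e-8 or np.linalg.norm(t.mean(axis=0)) > 1e-8:
            raise ValueError("template must have zero centroid and unit centroid size")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        s = np.asarray(self.allometric_slope, dtype=float)
        if s.shape != t.shape:
            raise ValueError("allometric_slope must match the template's shape")
        object.__setattr__(self, "template", t)
        object.__setattr__(self, "allometric_slope", s)
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def k(self) -> int:
        return self.template.shape[0]

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def mean_log_cs(self) -> float:
        """Sample-size-weighted mean log centroid size across groups."""
        n = self.total_n
        return sum(g.n * g.mean_log_cs for g in self.groups) / n

    # -- plain-file serialization --------------------------------------

    def to_json(self) -> str:
        d = {
            "template": self.template.tolist(),
            "groups": [
                {
                    "name": g.name,
                    "n": g.n,
                    "shape_offset": g.shape_offset.tolist(),
                    "mean_log_cs": g.mean_log_cs,
                    "sd_log_cs": g.sd_log_cs,
                }
                for g in self.groups
            ],
            "allometric_slope": self.allometric_slope.tolist(),
            "landmark_noise_sd": self.landmark_noise_sd,
            "nuisance": {
                "rotation": self.nuisance.rotation,
                "translation": self.nuisance.translation,
                "scale_range": list(self.nuisance.scale_range),
            },
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorSpec":
        d = json.loads(text)
        nu = d.get("nuisance", {})
        return cls(
            template=np.asarray(d["template"]),
            groups=tuple(
                GroupSpec(
                    name=g["name"],
                    n=g["n"],
                    shape_offset=np.asarray(g["shape_offset"]),
                    mean_log_cs=g["mean_log_cs"],
                    sd_log_cs=g["sd_log_cs"],
                )
                for g in d["groups"]
            ),
            allometric_slope=np.asarray(d["allometric_slope"]),
            landmark_noise_sd=d["landmark_noise_sd"],
            nuisance=Nuisance(
                rotation=nu.get("rotation", True),
                translation=nu.get("translation", 5.0),
                scale_range=tuple(nu.get("scale_range", (1.0, 1.0))),
            ),
            seed=d.get("seed", 0),
        )


def _tangent_offset(template: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Re-center a raw offset and rescale so template+offset has unit CS.

    This keeps "offset magnitude" interpretable as a Procrustes distance
    from the template.
    """
    o = raw - raw.mean(axis=0)
    shifted = template + o
    shifted = shifted - shifted.mean(axis=0)
    shifted = shifted / centroid_size(shifted)
    return shifted - template


# Within-group landmark noise, per coordinate, in Procrustes (unit-CS)
# units.  Sets the within-group shape dispersion against which the
# subgroup offsets below are a few-sigma signal.
_NOISE_SD = 0.004

# Common allometric magnitude (Procrustes shape change per unit log CS):
# chosen so the expected shape-on-size R² over the default design sits
# in the low single-digit percent range (see docs/methods.md for the
# variance budget).
_SLOPE_MAGNITUDE = 0.046


def _default_offsets(template: np.ndarray) -> dict[str, np.ndarray]:
    k = template.shape[0]
    z = lambda: np.zeros((k, 2))

    sin = z()
    sin[0] = (0.05, 0.02)   # LM1
    sin[1] = (0.04, -0.02)  # LM2
    sin[15] = (-0.03, 0.03)  # LM16
    sin[16] = (-0.03, -0.02)  # LM17

    alb = z()
    alb[0] = (-0.04, 0.03)
    alb[1] = (-0.05, -0.02)
    alb[15] = (0.04, 0.02)
    alb[16] = (0.03, 0.03)

    tri = z()
    for lm in range(11, 17):  # LM12–LM17
        tri[lm] = (0.02, 0.0)

    pal = z()  # subgroup reference

    mol = z()
    mol[15] = (0.010, 0.0)
    mol[16] = (0.0, 0.010)

    pip = z()
    pip[15] = (0.0, 0.009)
    pip[16] = (0.009, 0.0)

    return {"SIN": sin, "PAL": pal, "MOL": mol, "PIP": pip, "TRI": tri, "ALB": alb}


def default_spec(seed: int = 0) -> GeneratorSpec:
    """The six-taxon default design.

    Groups SIN/PAL/MOL/PIP/TRI/ALB with n = 35/47/67/17/45/40 (251
    specimens): equal mean log centroid size across the subgroup taxa
    PAL/MOL/PIP, strictly larger for SIN, strictly smaller for ALB;
    large shape offsets for the outgroups concentrated at landmarks 1–2
    and 16–17 (SIN, ALB) or 12–17 (TRI); small subgroup offsets (a few
    noise sd) at landmarks 16–17; and a weak common allometric trend.

    Offsets are orthogonalized against the between-group size gradient
    so that the allometric R² is controlled by the slope alone, then
    mapped into the template's tangent space.
    """
    template = _normalize_template(_RAW_TEMPLATE)
    raw = _default_offsets(template)

    names = ["SIN", "PAL", "MOL", "PIP", "TRI", "ALB"]
    ns = {"SIN": 35, "PAL": 47, "MOL": 67, "PIP": 17, "TRI": 45, "ALB": 40}
    mean_log_cs = {
        "SIN": float(np.log(3.0)),
        "PAL": float(np.log(2.0)),
        "MOL": float(np.log(2.0)),
        "PIP": float(np.log(2.0)),
        "TRI": float(np.log(2.4)),
        "ALB": float(np.log(1.4)),
    }
    total = sum(ns.values())
    xbar = sum(ns[g] * mean_log_cs[g] for g in names) / total
    dx = {g: mean_log_cs[g] - xbar for g in names}
    sxx = sum(ns[g] * dx[g] ** 2 for g in names)
    # remove the between-group size–offset covariance
    cov = sum(ns[g] * dx[g] * raw[g] for g in names)
    raw = {g: raw[g] - dx[g] * cov / sxx for g in names}

    offsets = {g: _tangent_offset(template, raw[g]) for g in names}

    slope = template * np.array([1.0, -1.0])  # aspect-ratio change with size
    slope = slope / np.linalg.norm(slope) * _SLOPE_MAGNITUDE

    groups = tuple(
        GroupSpec(
            name=g,
            n=ns[g],
            shape_offset=offsets[g],
            mean_log_cs=mean_log_cs[g],
            sd_log_cs=0.06,
        )
        for g in names
    )
    return GeneratorSpec(
        template=template,
        groups=groups,
        allometric_slope=slope,
        landmark_noise_sd=_NOISE_SD,
        nuisance=Nuisance(rotation=True, translation=5.0, scale_range=(1.0, 1.0)),
        seed=seed,
    )


def generate(spec: GeneratorSpec) -> LandmarkDataset:
    """Draw a landmark dataset from a generator specification.

    Per specimen: log centroid size ~ N(mean_log_cs, sd_log_cs²); shape
    = template + group offset + allometric_slope · (log CS − spec-wide
    mean log CS) + iid N(0, landmark_noise_sd²) per coordinate; the
    shape is centered, scaled to exactly CS = exp(log CS), and a random
    rotation, translation and nuisance scale are applied.  Output is
    grouped by taxon in spec order and fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    xbar = spec.mean_log_cs
    nu = spec.nuisance
    configs: list[LandmarkConfiguration] = []
    for g in spec.groups:
        for i in range(g.n):
            logcs = rng.normal(g.mean_log_cs, g.sd_log_cs)
            shape = (
                spec.template
                + g.shape_offset
                + spec.allometric_slope * (logcs - xbar)
                + rng.normal(0.0, spec.landmark_noise_sd, size=(spec.k, 2))
            )
            shape = shape - shape.mean(axis=0)
            shape = shape * (np.exp(logcs) / centroid_size(shape))

            if nu.rotation:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                c, s = np.cos(theta), np.sin(theta)
                shape = shape @ np.array([[c, -s], [s, c]]).T
            shift = rng.uniform(-nu.translation, nu.translation, size=2)
            factor = rng.uniform(nu.scale_range[0], nu.scale_range[1])
            coords = shape * factor + shift
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{g.name}_{i:03d}", landmarks=coords, taxon=g.name
                )
            )
    return LandmarkDataset(configs)
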