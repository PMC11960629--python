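"""Synthetic cloacal phantoms with ground-truth sex labels.

The discriminative anatomy in day-old chicks is the phallus: males carry
three small protruding cones at the cloacal rim, females two.  A phantom is
a parametric cross-section of that anatomy — a gently bowed tissue surface,
a stack of sub-surface layers with decaying backscatter, and two or three
bright cones protruding above the surface.  Phantoms are rasterized onto a
reflectivity grid which the OCT forward model turns into a B-scan.

All geometry is in micrometres.  Every random draw is a pure function of an
integer seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "Cone",
    "Layer",
    "Phantom",
    "PhantomParams",
    "ScanGeometry",
    "ReflectivityMap",
    "CohortSpec",
    "FrameRecord",
    "make_phantom",
    "jitter_phantom",
    "rasterize",
    "make_cohort",
    "cohort_to_json",
    "cohort_from_json",
]

SEXES = ("female", "male", "ambiguous")

#: cones per sex — the ground-truth anatomical rule
CONE_COUNT = {"female": 2, "male": 3, "ambiguous": 0}


@dataclass(frozen=True)
class Cone:
    """One phallic cone: a bright parabolic wedge protruding above the surface."""

    lateral_center_um: float
    apex_depth_um: float   # depth of the cone tip (smaller = closer to the probe)
    width_um: float
    height_um: float
    amplitude: float       # peak reflectivity in [0, 1]


@dataclass(frozen=True)
class Layer:
    """A horizontal tissue layer following the surface contour."""

    depth_um: float        # depth of the layer top at the lateral field center
    thickness_um: float
    reflectivity: float    # base backscatter amplitude in [0, 1]


@dataclass(frozen=True)
class Phantom:
    sex: str
    cone_count: int
    cones: tuple[Cone, ...]
    layers: tuple[Layer, ...]
    attenuation_coeff: float    # per-µm exponential decay below the surface
    speckle_scale: float        # relative multiplicative noise magnitude
    seed: int
    surface_depth_um: float = 700.0
    surface_bow_um: float = 80.0  # parabolic sag of the surface across the field

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex label {self.sex!r}; expected one of {SEXES}")
        if self.cone_count != CONE_COUNT[self.sex]:
            raise ValueError(
                f"cone_count {self.cone_count} inconsistent with sex {self.sex!r}"
            )


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel grid of a B-scan: depth rows × lateral columns at fixed pitches."""

    n_depth: int
    n_lateral: int
    depth_pitch_um: float
    lateral_pitch_um: float

    def __post_init__(self) -> None:
        if self.depth_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise ValueError("pitches must be positive")
        if self.n_depth <= 0 or self.n_lateral <= 0:
            raise ValueError("grid dimensions must be positive")


@dataclass
class ReflectivityMap:
    """Backscatter amplitude grid (depth rows × lateral columns), values in [0, 1]."""

    values: np.ndarray
    depth_pitch_um: float
    lateral_pitch_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("reflectivity map must be 2-D")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("reflectivity values must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomParams:
    """Sampling ranges for phantom geometry.

    The real anatomy's physical dimensions are not tabulated anywhere;
    these ranges are chosen so cones are resolvable at 4 µm/px and still
    visible after a 13× downscale to the classifier's 75×64 input.
    """

    surface_depth_um: tuple[float, float] = (500.0, 900.0)
    surface_bow_um: tuple[float, float] = (20.0, 150.0)
    n_layers: int = 3
    layer_thickness_um: tuple[float, float] = (80.0, 300.0)
    top_layer_reflectivity: tuple[float, float] = (0.35, 0.55)
    layer_decay: float = 0.55            # reflectivity ratio between successive layers
    cone_width_um: tuple[float, float] = (200.0, 600.0)
    cone_height_um: tuple[float, float] = (150.0, 400.0)
    cone_amplitude: tuple[float, float] = (0.65, 0.95)
    cone_spacing_um: tuple[float, float] = (650.0, 900.0)
    attenuation_coeff: tuple[float, float] = (2e-4, 8e-4)
    speckle_scale: tuple[float, float] = (0.10, 0.30)
    lateral_center_um: float = 2000.0    # cones sit around the middle of a 4 mm field
    frame_jitter: float = 0.10           # relative per-frame geometry jitter


#: imaging condition presets --------------------------------------------------
#: Well separated: bright, low-speckle cones — anatomy trivially visible.
#: Used for parameter-recovery checks: a working pipeline must classify it.
WELL_SEPARATED_PARAMS = PhantomParams(
    cone_amplitude=(0.85, 0.95),
    speckle_scale=(0.03, 0.08),
    cone_width_um=(350.0, 550.0),
    cone_height_um=(250.0, 400.0),
    surface_depth_um=(600.0, 780.0),
    surface_bow_um=(20.0, 70.0),
    attenuation_coeff=(2e-4, 4e-4),
)

#: High noise: cone contrast buried far below the speckle floor.  A pipeline
#: that still scores well here would be leaking labels, not measuring signal.
HIGH_NOISE_PARAMS = PhantomParams(
    cone_amplitude=(0.02, 0.06),
    speckle_scale=(1.2, 2.0),
)


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def make_phantom(sex: str, params: PhantomParams | None = None, seed: int = 0) -> Phantom:
    """Draw one phantom of the given sex from the parameter ranges.

    Identical (sex, params, seed) always yields a bit-identical phantom.
    Ambiguous phantoms carry no cones — the anatomy is occluded or out of
    the field of view — and only show the layered tissue background.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}; expected one of {SEXES}")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)

    surface = _uniform(rng, params.surface_depth_um)
    bow = _uniform(rng, params.surface_bow_um)
    atten = _uniform(rng, params.attenuation_coeff)
    speckle = _uniform(rng, params.speckle_scale)

    layers = []
    depth = surface
    refl = _uniform(rng, params.top_layer_reflectivity)
    for _ in range(params.n_layers):
        thick = _uniform(rng, params.layer_thickness_um)
        layers.append(Layer(depth_um=depth, thickness_um=thick, reflectivity=refl))
        depth += thick
        refl *= params.layer_decay

    n_cones = CONE_COUNT[sex]
    cones = []
    if n_cones:
        spacing = _uniform(rng, params.cone_spacing_um)
        offset = params.lateral_center_um - spacing * (n_cones - 1) / 2.0
        for i in range(n_cones):
            width = _uniform(rng, params.cone_width_um)
            height = _uniform(rng, params.cone_height_um)
            amp = _uniform(rng, params.cone_amplitude)
            center = offset + i * spacing + rng.uniform(-0.05, 0.05) * spacing
            cones.append(
                Cone(
                    lateral_center_um=center,
                    apex_depth_um=surface - height,
                    width_um=width,
                    height_um=height,
                    amplitude=amp,
                )
            )

    return Phantom(
        sex=sex,
        cone_count=n_cones,
        cones=tuple(cones),
        layers=tuple(layers),
        attenuation_coeff=atten,
        speckle_scale=speckle,
        seed=seed,
        surface_depth_um=surface,
        surface_bow_um=bow,
    )


def jitter_phantom(base: Phantom, rel: float, seed: int, sex: str | None = None) -> Phantom:
    """Perturb a base phantom's geometry by a relative amount (per-frame variation).

    Each geometric quantity is scaled by an independent uniform factor in
    ``1 ± rel``.  Passing ``sex='ambiguous'`` drops the cones, modelling a
    frame where the anatomy was occluded or outside the field.
    """
    rng = np.random.default_rng(seed)

    def j(x: float) -> float:
        return float(x * rng.uniform(1.0 - rel, 1.0 + rel))

    surface = j(base.surface_depth_um)
    sex = sex or base.sex
    if sex == "ambiguous":
        cones: tuple[Cone, ...] = ()
    else:
        cones = tuple(
            Cone(
                lateral_center_um=j(c.lateral_center_um),
                apex_depth_um=surface - j(c.height_um),
                width_um=j(c.width_um),
                height_um=j(c.height_um),
                amplitude=min(1.0, j(c.amplitude)),
            )
            for c in base.cones
        )
    layers = []
    depth = surface
    for lay in base.layers:
        thick = j(lay.thickness_um)
        layers.append(Layer(depth_um=depth, thickness_um=thick, reflectivity=lay.reflectivity))
        depth += thick
    return Phantom(
        sex=sex,
        cone_count=CONE_COUNT[sex],
        cones=cones,
        layers=tuple(layers),
        attenuation_coeff=base.attenuation_coeff,
        speckle_scale=base.speckle_scale,
        seed=seed,
        surface_depth_um=surface,
        surface_bow_um=j(base.surface_bow_um),
    )


def rasterize(phantom: Phantom, geometry: ScanGeometry) -> ReflectivityMap:
    """Render a phantom onto a reflectivity grid.

    The tissue surface follows a parabolic bow across the field; layers are
    bands of constant base reflectivity below it, attenuated exponentially
    with depth below the surface.  Cones are parabolic wedges protruding
    above the surface (into what would otherwise be clear medium), which
    keeps them topologically separated — one connected bright component per
    cone.  Values are clipped to [0, 1].  A phantom with no structures (or
    all structures out of field) rasterizes to an all-zero map, which is a
    legitimate rendering of an ambiguous frame.
    """
    nz, nx = geometry.n_depth, geometry.n_lateral
    z = np.arange(nz)[:, None] * geometry.depth_pitch_um          # (nz, 1)
    x = np.arange(nx)[None, :] * geometry.lateral_pitch_um        # (1, nx)
    half_fov = max(nx - 1, 1) * geometry.lateral_pitch_um / 2.0
    xc = half_fov

    surf = phantom.surface_depth_um + phantom.surface_bow_um * ((x - xc) / half_fov) ** 2
    below = z - surf                                              # µm below local surface

    values = np.zeros((nz, nx), dtype=np.float64)
    depth_from_top = phantom.layers[0].depth_um if phantom.layers else 0.0
    for lay in phantom.layers:
        top = lay.depth_um - depth_from_top   # offsets relative to the surface
        band = (below >= top) & (below < top + lay.thickness_um)
        values[band] = lay.reflectivity
    values *= np.exp(-phantom.attenuation_coeff * np.clip(below, 0.0, None))
    values[below < 0] = 0.0

    for cone in phantom.cones:
        u = 2.0 * (x - cone.lateral_center_um) / cone.width_um    # (1, nx)
        profile = cone.height_um * np.clip(1.0 - u * u, 0.0, None)
        inside = (below < 0) & (z >= surf - profile) & (profile > 0)
        values = np.where(inside, np.maximum(values, cone.amplitude), values)

    in_field = any(
        0 <= c.lateral_center_um <= 2 * half_fov and c.apex_depth_um < nz * geometry.depth_pitch_um
        for c in phantom.cones
    )
    if phantom.cones and not in_field:
        import warnings

        warnings.warn("all phantom cones fall outside the scan field", stacklevel=2)

    return ReflectivityMap(
        values=np.clip(values, 0.0, 1.0),
        depth_pitch_um=geometry.depth_pitch_um,
        lateral_pitch_um=geometry.lateral_pitch_um,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated imaging session.

    Defaults mirror the study design this generator emulates: 30 chicks
    (half male), 50 frames captured per chick of which 40 survive quality
    selection, giving a 1200-image dataset.
    """

    n_chicks: int = 30
    frames_per_chick: int = 50
    keep_per_chick: int = 40
    sex_balance: float = 0.5
    ambiguous_rate: float = 0.05
    seed: int = 0
    params: PhantomParams = field(default_factory=PhantomParams)

    def __post_init__(self) -> None:
        if self.n_chicks < 2:
            raise ValueError("need at least 2 chicks to form a train/test split")
        if self.keep_per_chick > self.frames_per_chick:
            raise ValueError("keep_per_chick cannot exceed frames_per_chick")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must be in [0, 1]")


@dataclass(frozen=True)
class FrameRecord:
    chick_id: int
    frame_index: int
    chick_sex: str      # true sex of the animal
    label: str          # frame-level label; 'ambiguous' when anatomy is occluded
    phantom: Phantom


def make_cohort(spec: CohortSpec) -> list[FrameRecord]:
    """Generate a full cohort of per-frame phantoms.

    Anatomy is sampled once per chick and jittered per frame, so frames of
    one chick share a base geometry — emulating repeated scans at slightly
    different locations around the cloaca.  A configurable fraction of
    frames is rendered with the cones occluded ('ambiguous').  The result
    is a pure function of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_male = int(round(spec.n_chicks * spec.sex_balance))
    sexes = ["male"] * n_male + ["female"] * (spec.n_chicks - n_male)
    rng.shuffle(sexes)

    # independent, reproducible streams per chick and frame
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        spec.n_chicks * (spec.frames_per_chick + 1)
    ) % (2**31)

    records: list[FrameRecord] = []
    si = 0
    for chick_id, sex in enumerate(sexes):
        base = make_phantom(sex, spec.params, seed=int(seeds[si]))
        si += 1
        n_amb = int(round(spec.ambiguous_rate * spec.frames_per_chick))
        amb_frames = set(
            rng.choice(spec.frames_per_chick, size=n_amb, replace=False).tolist()
        ) if n_amb else set()
        for frame in range(spec.frames_per_chick):
            frame_sex = "ambiguous" if frame in amb_frames else sex
            ph = jitter_phantom(base, spec.params.frame_jitter, int(seeds[si]), sex=frame_sex)
            si += 1
            records.append(
                FrameRecord(
                    chick_id=chick_id,
                    frame_index=frame,
                    chick_sex=sex,
                    label=frame_sex,
                    phantom=ph,
                )
            )
    return records


def cohort_to_json(records: Sequence[FrameRecord], path) -> None:
    """Serialize a cohort, one JSON record per frame."""
    payload = []
    for r in records:
        d = asdict(r)
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=None, separators=(",", ":"))


def cohort_from_json(path) -> list[FrameRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    records = []
    for d in payload:
        ph = d["phantom"]
        phantom = Phantom(
            sex=ph["sex"],
            cone_count=ph["cone_count"],
            cones=tuple(Cone(**c) for c in ph["cones"]),
            layers=tuple(Layer(**lay) for lay in ph["layers"]),
            attenuation_coeff=ph["attenuation_coeff"],
            speckle_scale=ph["speckle_scale"],
            seed=ph["seed"],
            surface_depth_um=ph["surface_depth_um"],
            surface_bow_um=ph["surface_bow_um"],
        )
        records.append(
            FrameRecord(
                chick_id=d["chick_id"],
                frame_index=d["frame_index"],
                chick_sex=d["chick_sex"],
                label=d["label"],
                phantom=phantom,
            )
        )
    return records
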