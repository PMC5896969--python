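"""Reduced lower-limb rigid-body model with hip-spanning muscle fascicles.

The model is a desk-scale stand-in for a full cadaver-based leg: a pelvis root,
a lumped head-arms-trunk (HAT) segment rigidly fused to it, and bilateral
femur/shank/foot chains connected by a spherical hip and revolute knee and
ankle joints.  Seven hip-spanning fascicle groups per leg (anterior/posterior gluteus
medius, gluteus maximus, iliopsoas, adductor group, a rectus-femoris
equivalent and a tensor-fasciae-latae equivalent) make the muscle redundancy
problem at the 3-DOF hip nontrivial while keeping every recruitment solve
small; the TFL group provides the abduction/flexion reserve that lets muscle
forces redistribute gradually as the strength parameter is reduced.

Two hip-joint-width (HJW) modes are supported: ``"CT"`` freezes the hip-center
distance at the CT-measured value during marker-based scaling, ``"C3D"`` leaves
it free for the kinematic optimizer.

Conventions: lab/segment axes are +X anterior, +Y left, +Z up; geometry is in
meters internally (HJW is exposed in mm, PCSA in cm^2); segment frames sit at
the proximal joint center with the long axis pointing down -Z in neutral pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anthro import Anthropometrics

__all__ = [
    "Segment",
    "JointSpec",
    "HillParams",
    "MuscleFascicle",
    "BodyModel",
    "build_reference_model",
    "scale_model",
    "set_hjw",
    "mirror_model",
    "save_model",
    "load_model",
    "REFERENCE_MASS",
    "REFERENCE_HEIGHT",
]

# Anthropometric reference for the cross-section scaling law.
REFERENCE_MASS = 75.0  # kg
REFERENCE_HEIGHT = 1.74  # m

# Segment mass fractions of body mass (HAT lump includes the pelvis).
MASS_FRACTIONS = {"hat": 0.678, "femur": 0.10, "shank": 0.0465, "foot": 0.0145}
# Segment lengths as fractions of body height.
LENGTH_FRACTIONS = {"femur": 0.245, "shank": 0.246, "foot": 0.152, "hat": 0.47}
# COM position along the segment long axis, fraction of length from proximal end.
COM_FRACTIONS = {"femur": 0.433, "shank": 0.433, "foot": 0.5, "hat": 0.45}


@dataclass(frozen=True)
class Segment:
    name: str
    mass: float  # kg
    length: float  # m
    com_offset: np.ndarray  # (3,) m, segment frame
    inertia: np.ndarray  # (3,) principal moments, kg m^2
    frame: np.ndarray  # (3,) m, origin offset in parent frame at neutral pose

    def __post_init__(self):
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if np.any(np.asarray(self.inertia) < 0):
            raise ValueError(f"segment {self.name}: inertia must be >= 0")


@dataclass(frozen=True)
class JointSpec:
    name: str
    kind: str  # "spherical" | "revolute"
    parent: str
    child: str
    axis: np.ndarray | None = None  # unit 3-vector, revolute only

    def __post_init__(self):
        if self.kind not in ("spherical", "revolute"):
            raise ValueError(f"joint {self.name}: unknown kind {self.kind!r}")
        if self.kind == "revolute":
            if self.axis is None or abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
                raise ValueError(f"joint {self.name}: revolute joints need a unit axis")

    @property
    def dof(self) -> int:
        return 3 if self.kind == "spherical" else 1


@dataclass(frozen=True)
class HillParams:
    """Hill-type contractile parameters for one fascicle.

    optimal_fiber_length in m, max_velocity in optimal lengths/s,
    passive_strain_scale is the normalized stretch at which the passive
    element reaches maximal-isometric force, flw is the Gaussian
    force-length width on normalized length.
    """

    optimal_fiber_length: float = 0.10
    max_velocity: float = 10.0
    passive_strain_scale: float = 0.6
    flw: float = 0.45

    def __post_init__(self):
        for name in ("optimal_fiber_length", "max_velocity", "passive_strain_scale", "flw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HillParams.{name} must be > 0")


@dataclass(frozen=True)
class MuscleFascicle:
    name: str
    path: tuple  # ((segment_name, (3,) local point m), ...), >= 2 points
    pcsa: float  # cm^2
    side: str  # "L" | "R"
    hill: HillParams = field(default_factory=HillParams)

    def __post_init__(self):
        if len(self.path) < 2:
            raise ValueError(f"fascicle {self.name}: path needs >= 2 points")
        if self.pcsa <= 0:
            raise ValueError(f"fascicle {self.name}: pcsa must be > 0")


@dataclass(frozen=True)
class BodyModel:
    segments: tuple  # of Segment
    joints: tuple  # of JointSpec
    fascicles: tuple  # of MuscleFascicle
    hjw: float  # mm, distance between hip centers
    hjw_mode: str  # "C3D" (free) | "CT" (frozen)
    length_scales: dict
    cross_section_scale: float  # area factor applied to PCSA
    mass: float  # kg
    height: float  # m

    def __post_init__(self):
        if self.hjw <= 0:
            raise ValueError("hjw must be positive")
        if self.hjw_mode not in ("C3D", "CT"):
            raise ValueError(f"hjw_mode must be 'C3D' or 'CT', got {self.hjw_mode!r}")
        if any(s <= 0 for s in self.length_scales.values()):
            raise ValueError("length scales must be positive")
        if self.cross_section_scale <= 0:
            raise ValueError("cross_section_scale must be positive")

    # -- lookups -----------------------------------------------------------
    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def hip_center_local(self, side: str) -> np.ndarray:
        """Hip joint center in the pelvis frame; +Y is left."""
        s = +1.0 if side == "L" else -1.0
        return np.array([0.0, s * self.hjw / 2000.0, 0.0])

    def fascicles_of(self, side: str) -> list:
        return [f for f in self.fascicles if f.side == side]

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments)


# ---------------------------------------------------------------------------
# Fascicle geometry template.
#
# Pelvic attachment points are stored relative to the hip center of the
# fascicle's side so that changing the HJW moves them consistently; femoral
# points are in the femur frame (origin at the hip center).  Lateral offsets
# carry a sign factor s (+1 left leg, -1 right leg); "medial" is -s*y.
# PCSA values (cm^2) are lumped-group estimates in the physiological range.
_FASCICLE_TEMPLATE = [
    # name, pelvis point rel. hip center (x, s*y, z), femur point (x, s*y, z*Lf-frac), pcsa
    ("glut_med_ant", (0.045, 0.050, 0.090), (0.015, 0.048, -0.025), 22.0),
    ("glut_med_post", (-0.020, 0.045, 0.085), (-0.010, 0.048, -0.040), 20.0),
    ("glut_max", (-0.070, 0.010, 0.075), (-0.015, 0.030, -0.110), 38.0),
    ("iliopsoas", (0.035, -0.010, 0.060), (0.000, -0.020, -0.090), 24.0),
    ("adductor", (-0.030, -0.060, -0.050), (0.000, -0.018, -0.760), 32.0),
    ("rectus_fem", (0.050, 0.005, 0.015), (0.038, 0.000, -0.760), 14.0),
    ("tfl", (0.040, 0.020, 0.005), (0.040, 0.060, -0.070), 18.0),
]

# Optimal "fiber" lengths are effective musculotendon values: with the rigid
# tendon of this model the whole length change is attributed to the fiber, so
# the anatomical fiber lengths are inflated by the tendon compliance they
# would otherwise absorb.
_HILL_DEFAULTS = {
    "glut_med_ant": HillParams(0.12, 10.0, 0.6, 0.45),
    "glut_med_post": HillParams(0.12, 10.0, 0.6, 0.45),
    "glut_max": HillParams(0.22, 10.0, 0.6, 0.45),
    "iliopsoas": HillParams(0.18, 10.0, 0.6, 0.45),
    "adductor": HillParams(0.20, 10.0, 0.6, 0.45),
    "rectus_fem": HillParams(0.17, 10.0, 0.6, 0.45),
    "tfl": HillParams(0.14, 10.0, 0.6, 0.45),
}


# Each muscle group is subdivided into fascicles the way cadaver-based models
# split broad muscles.  Sub-fascicle femoral insertions sit at different
# radial distances from the joint center (factor k on the insertion point),
# which ladders the moment arms: long-levered fascicles are recruited and
# saturate first as the strength parameter is lowered, and load then
# redistributes to progressively shorter-levered (force-costlier) fascicles,
# raising the joint contact force gradually instead of failing abruptly.
# Entries: (pcsa weight, femoral radial factor k, pelvic jitter m).
_SUBDIVISION = 3
_SUB_TAGS = ("a", "b", "c")
_SUBFASCICLE_SPREAD = {
    1: [(1.0, 1.0, 0.0)],
    2: [(0.65, 1.10, 0.003), (0.35, 0.60, -0.003)],
    3: [(0.40, 1.20, 0.004), (0.35, 1.00, 0.0), (0.25, 0.55, -0.004)],
}


def _cross_section_scale(mass: float, height: float) -> float:
    """Area ("fat") scaling factor from body mass and height.

    Defined as sqrt((m/m_ref)/(h/h_ref)): muscle volume tracks body mass,
    length tracks height, so the cross-sectional area grows with their ratio.
    PCSA is multiplied by this factor directly; perpendicular linear segment
    dimensions by its square root.
    """
    return float(np.sqrt((mass / REFERENCE_MASS) / (height / REFERENCE_HEIGHT)))


def _assemble(
    anthro_mass: float,
    anthro_height: float,
    hjw_mm: float,
    hjw_mode: str,
    length_scales: dict,
    n_fascicles: int,
) -> BodyModel:
    m, h = anthro_mass, anthro_height
    if m <= 0 or h <= 0:
        raise ValueError(f"invalid anthropometrics: mass={m}, height={h}")
    if n_fascicles < 1:
        raise ValueError("n_fascicles must be >= 1")
    cross = _cross_section_scale(m, h)
    w = hjw_mm / 1000.0

    def seg_len(name: str) -> float:
        return LENGTH_FRACTIONS[name] * h * length_scales.get(name, 1.0)

    def rod_inertia(mass_, len_) -> np.ndarray:
        i = mass_ * len_**2 / 12.0
        return np.array([i, i, 0.1 * i])

    segments = [
        Segment("pelvis", 0.0, max(w, 1e-3), np.zeros(3), np.zeros(3), np.zeros(3)),
        Segment(
            "hat",
            MASS_FRACTIONS["hat"] * m,
            seg_len("hat"),
            np.array([-0.02, 0.0, COM_FRACTIONS["hat"] * seg_len("hat")]),
            rod_inertia(MASS_FRACTIONS["hat"] * m, seg_len("hat")),
            np.zeros(3),
        ),
    ]
    joints = []
    for side, s in (("L", +1.0), ("R", -1.0)):
        lf, ls, lft = seg_len("femur"), seg_len("shank"), seg_len("foot")
        sfx = side.lower()
        segments += [
            Segment(
                f"femur_{sfx}",
                MASS_FRACTIONS["femur"] * m,
                lf,
                np.array([0.0, 0.0, -COM_FRACTIONS["femur"] * lf]),
                rod_inertia(MASS_FRACTIONS["femur"] * m, lf),
                np.array([0.0, s * w / 2.0, 0.0]),
            ),
            Segment(
                f"shank_{sfx}",
                MASS_FRACTIONS["shank"] * m,
                ls,
                np.array([0.0, 0.0, -COM_FRACTIONS["shank"] * ls]),
                rod_inertia(MASS_FRACTIONS["shank"] * m, ls),
                np.array([0.0, 0.0, -lf]),
            ),
            Segment(
                f"foot_{sfx}",
                MASS_FRACTIONS["foot"] * m,
                lft,
                np.array([0.35 * lft, 0.0, -0.05]),
                rod_inertia(MASS_FRACTIONS["foot"] * m, lft),
                np.array([0.0, 0.0, -ls]),
            ),
        ]
        ey = np.array([0.0, 1.0, 0.0])
        joints += [
            JointSpec(f"hip_{sfx}", "spherical", "pelvis", f"femur_{sfx}"),
            JointSpec(f"knee_{sfx}", "revolute", f"femur_{sfx}", f"shank_{sfx}", ey),
            JointSpec(f"ankle_{sfx}", "revolute", f"shank_{sfx}", f"foot_{sfx}", ey),
        ]

    height_ratio = h / REFERENCE_HEIGHT
    n_groups = min(max((n_fascicles + _SUBDIVISION - 1) // _SUBDIVISION, 1),
                   len(_FASCICLE_TEMPLATE))
    per_group = max(min(n_fascicles // n_groups, _SUBDIVISION), 1)
    fascicles = []
    for side, s in (("L", +1.0), ("R", -1.0)):
        sfx = side.lower()
        lf = seg_len("femur")
        hip = np.array([0.0, s * w / 2.0, 0.0])
        for name, pelv, fem, pcsa in _FASCICLE_TEMPLATE[:n_groups]:
            # pelvic point: relative offsets scale with height, attach rel. hip center
            # femoral point: z stored as fraction of femur length for the two
            # shaft attachments (|z| > 0.2 flags a fraction), else absolute
            fz = fem[2] * lf / 0.42630 if abs(fem[2]) > 0.2 else fem[2] * height_ratio
            for j in range(per_group):
                wj, kj, jit = _SUBFASCICLE_SPREAD[per_group][j]
                p_pel = hip + height_ratio * np.array(
                    [pelv[0] + jit, s * (pelv[1] + jit), pelv[2] + jit]
                )
                p_fem = kj * np.array(
                    [fem[0] * height_ratio, s * fem[1] * height_ratio, fz]
                )
                fascicles.append(
                    MuscleFascicle(
                        name=f"{name}_{_SUB_TAGS[j]}_{sfx}" if per_group > 1
                        else f"{name}_{sfx}",
                        path=((f"pelvis", p_pel), (f"femur_{sfx}", p_fem)),
                        pcsa=pcsa * wj * cross,
                        side=side,
                        hill=_HILL_DEFAULTS.get(name, HillParams()),
                    )
                )

    return BodyModel(
        segments=tuple(segments),
        joints=tuple(joints),
        fascicles=tuple(fascicles),
        hjw=hjw_mm,
        hjw_mode=hjw_mode,
        length_scales=dict(length_scales),
        cross_section_scale=cross,
        mass=m,
        height=h,
    )


def build_reference_model(anthro: Anthropometrics, n_fascicles: int = 21) -> BodyModel:
    """Build the subject-specific reference model.

    Segment masses are fixed fractions of body mass (they always sum to the
    body mass), segment lengths are height fractions, and the hip joint width
    is initialized to the subject's CT-measured value in mode ``"CT"``.
    """
    return _assemble(
        anthro.mass,
        anthro.height,
        anthro.hjw_ct,
        "CT",
        {"femur": 1.0, "shank": 1.0, "foot": 1.0},
        n_fascicles,
    )


def scale_model(model: BodyModel, length_scales: dict, anthro: Anthropometrics) -> BodyModel:
    """Return a copy of ``model`` with per-segment length scales applied.

    Lengths, fascicle attachment points and marker offsets scale with the
    per-segment factors; the PCSA cross-section factor is recomputed from the
    subject's mass and height.
    """
    if any(v <= 0 for v in length_scales.values()):
        raise ValueError("length scales must be positive")
    scales = dict(model.length_scales)
    scales.update(length_scales)
    n_groups = len(model.fascicles_of("L"))
    return _assemble(anthro.mass, anthro.height, model.hjw, model.hjw_mode, scales, n_groups)


def set_hjw(model: BodyModel, hjw_mm: float, mode: str) -> BodyModel:
    """Place the hip centers at +/- hjw_mm/2 about the mid-sagittal plane.

    ``mode="CT"`` marks the width as frozen for the kinematic optimizer,
    ``mode="C3D"`` marks it free.
    """
    if hjw_mm <= 0:
        raise ValueError(f"hjw must be positive, got {hjw_mm}")
    n_groups = len(model.fascicles_of("L"))
    return _assemble(model.mass, model.height, hjw_mm, mode, model.length_scales, n_groups)


# ---------------------------------------------------------------------------
# Mirroring


def _mirror_name(name: str) -> str:
    if name.endswith("_l"):
        return name[:-2] + "_r"
    if name.endswith("_r"):
        return name[:-2] + "_l"
    return name


def mirror_model(model: BodyModel) -> BodyModel:
    """Reflect the model about the mid-sagittal plane and swap side labels.

    Applying the operation twice returns an identical model.
    """
    flip = np.array([1.0, -1.0, 1.0])

    def seg(s: Segment) -> Segment:
        return replace(
            s,
            name=_mirror_name(s.name),
            com_offset=s.com_offset * flip,
            frame=s.frame * flip,
        )

    def jnt(j: JointSpec) -> JointSpec:
        return replace(
            j,
            name=_mirror_name(j.name),
            parent=_mirror_name(j.parent),
            child=_mirror_name(j.child),
        )

    def fas(f: MuscleFascicle) -> MuscleFascicle:
        return replace(
            f,
            name=_mirror_name(f.name),
            side="R" if f.side == "L" else "L",
            path=tuple((_mirror_name(seg_name), pt * flip) for seg_name, pt in f.path),
        )

    key = lambda x: x.name
    return replace(
        model,
        segments=tuple(sorted((seg(s) for s in model.segments), key=key)),
        joints=tuple(sorted((jnt(j) for j in model.joints), key=key)),
        fascicles=tuple(sorted((fas(f) for f in model.fascicles), key=key)),
    )


# ---------------------------------------------------------------------------
# Flat key-value model file (TOML dialect; read back with tomllib)


def _toml_vec(v) -> str:
    return "[" + ", ".join(f"{float(x):.9g}" for x in np.asarray(v).ravel()) + "]"


def save_model(model: BodyModel, path) -> None:
    """Write the model as flat TOML sections (coordinates in mm, PCSA in cm^2)."""
    lines = [
        "[model]",
        f"hjw_mm = {model.hjw:.9g}",
        f'hjw_mode = "{model.hjw_mode}"',
        f"mass_kg = {model.mass:.9g}",
        f"height_m = {model.height:.9g}",
        f"cross_section_scale = {model.cross_section_scale:.9g}",
        "",
        "[length_scales]",
    ]
    lines += [f"{k} = {v:.9g}" for k, v in sorted(model.length_scales.items())]
    for s in model.segments:
        lines += [
            "",
            f"[segments.{s.name}]",
            f"mass_kg = {s.mass:.9g}",
            f"length_mm = {1000 * s.length:.9g}",
            f"com_offset_mm = {_toml_vec(1000 * s.com_offset)}",
            f"inertia_kgm2 = {_toml_vec(s.inertia)}",
            f"frame_mm = {_toml_vec(1000 * s.frame)}",
        ]
    for j in model.joints:
        lines += [
            "",
            f"[joints.{j.name}]",
            f'kind = "{j.kind}"',
            f'parent = "{j.parent}"',
            f'child = "{j.child}"',
        ]
        if j.axis is not None:
            lines.append(f"axis = {_toml_vec(j.axis)}")
    for f in model.fascicles:
        lines += [
            "",
            f"[fascicles.{f.name}]",
            f'side = "{f.side}"',
            f"pcsa_cm2 = {f.pcsa:.9g}",
            "path_segments = [" + ", ".join(f'"{sn}"' for sn, _ in f.path) + "]",
            "path_points_mm = ["
            + ", ".join(_toml_vec(1000 * np.asarray(pt)) for _, pt in f.path)
            + "]",
            f"hill = {_toml_vec([f.hill.optimal_fiber_length, f.hill.max_velocity, f.hill.passive_strain_scale, f.hill.flw])}",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> BodyModel:
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    segs = tuple(
        Segment(
            name,
            d["mass_kg"],
            d["length_mm"] / 1000.0,
            np.asarray(d["com_offset_mm"]) / 1000.0,
            np.asarray(d["inertia_kgm2"], dtype=float),
            np.asarray(d["frame_mm"]) / 1000.0,
        )
        for name, d in doc["segments"].items()
    )
    joints = tuple(
        JointSpec(
            name,
            d["kind"],
            d["parent"],
            d["child"],
            np.asarray(d["axis"], dtype=float) if "axis" in d else None,
        )
        for name, d in doc["joints"].items()
    )
    fascicles = tuple(
        MuscleFascicle(
            name,
            tuple(
                (sn, np.asarray(pt) / 1000.0)
                for sn, pt in zip(d["path_segments"], d["path_points_mm"])
            ),
            d["pcsa_cm2"],
            d["side"],
            HillParams(*d["hill"]),
        )
        for name, d in doc["fascicles"].items()
    )
    m = doc["model"]
    return BodyModel(
        segments=segs,
        joints=joints,
        fascicles=fascicles,
        hjw=m["hjw_mm"],
        hjw_mode=m["hjw_mode"],
        length_scales=dict(doc.get("length_scales", {})),
        cross_section_scale=m["cross_section_scale"],
        mass=m["mass_kg"],
        height=m["height_m"],
    )
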