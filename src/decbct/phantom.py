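"""Digital Catphan-style image-quality phantom.

A 20 cm background cylinder carries two axial modules: a sensitometry module
with nine cylindrical material inserts (air, PMP, LDPE, polystyrene, acrylic,
Delrin, Teflon and two bone-equivalent materials) on a 58.5 mm ring, and a
homogeneous uniformity module.  In-plane coordinates are mm with the origin on
the rotation axis; images are row-major with y increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CoverageError, LookupErrorDecbct, ValidationError
from .materials import get_material, linear_attenuation, material_table
from .reconstruction import ReconGrid

SENSITOMETRY = "sensitometry"
UNIFORMITY = "uniformity"

#: insert order around the ring, top position first, clockwise in image space
_DEFAULT_INSERTS = (
    "air",
    "pmp",
    "ldpe",
    "polystyrene",
    "acrylic",
    "delrin",
    "teflon",
    "bone_20",
    "bone_50",
)


@dataclass(frozen=True)
class InsertSpec:
    name: str
    center: tuple[float, float]  # (x, y) mm
    radius: float  # mm
    material: str
    module: str = SENSITOMETRY

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"insert {self.name}: radius must be positive")
        if self.module not in (SENSITOMETRY, UNIFORMITY):
            raise ValidationError(f"insert {self.name}: unknown module {self.module}")


@dataclass(frozen=True)
class PhantomSpec:
    outer_radius: float = 100.0  # mm
    background_material: str = "epoxy_background"
    inserts: tuple[InsertSpec, ...] = ()
    module_z: dict = field(default_factory=lambda: {SENSITOMETRY: 0.0, UNIFORMITY: 40.0})

    def __post_init__(self) -> None:
        if self.outer_radius <= 0:
            raise ValidationError("outer radius must be positive")
        if self.background_material not in material_table():
            raise LookupErrorDecbct(
                f"background material {self.background_material!r} not in table"
            )
        for ins in self.inserts:
            if ins.material not in material_table():
                raise LookupErrorDecbct(f"insert material {ins.material!r} not in table")
            if math.hypot(*ins.center) + ins.radius > self.outer_radius:
                raise ValidationError(f"insert {ins.name} extends outside the phantom")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                if a.module == b.module and math.dist(a.center, b.center) < a.radius + b.radius:
                    raise ValidationError(f"inserts {a.name} and {b.name} overlap")

    def module_inserts(self, module: str) -> tuple[InsertSpec, ...]:
        return tuple(i for i in self.inserts if i.module == module)


def default_catphan(
    ring_radius: float = 58.5,
    insert_radius: float = 6.35,
    outer_radius: float = 100.0,
    background_material: str = "epoxy_background",
) -> PhantomSpec:
    """Default sensitometry + uniformity phantom with nine material inserts."""
    inserts = []
    for k, mat in enumerate(_DEFAULT_INSERTS):
        theta = math.radians(-90.0 + 40.0 * k)  # top of the image first (y down)
        cx = ring_radius * math.cos(theta)
        cy = ring_radius * math.sin(theta)
        inserts.append(
            InsertSpec(name=mat, center=(cx, cy), radius=insert_radius, material=mat)
        )
    return PhantomSpec(
        outer_radius=outer_radius,
        background_material=background_material,
        inserts=tuple(inserts),
    )


# ---------------------------------------------------------------------------
# ROI layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROI:
    name: str
    cx: float  # mm
    cy: float  # mm
    radius: float  # mm
    material: str | None = None
    module: str = SENSITOMETRY

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"ROI {self.name}: radius must be positive")


@dataclass(frozen=True)
class ROISet:
    insert_rois: tuple[ROI, ...]
    background_roi: ROI
    uniformity_rois: tuple[ROI, ...]  # center first, then 4 peripheral

    def __post_init__(self) -> None:
        if len(self.uniformity_rois) != 5:
            raise ValidationError("uniformity set must have exactly 5 ROIs")

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            (r.name, r.cx, r.cy, r.radius, r.module)
            for r in (*self.insert_rois, self.background_roi, *self.uniformity_rois)
        ]
        pd.DataFrame(rows, columns=["name", "cx_mm", "cy_mm", "r_mm", "module"]).to_csv(
            path, index=False
        )


def default_roiset(
    spec: PhantomSpec,
    insert_fraction: float = 0.6,
    background_gap_deg: float = 20.0,
    uniformity_radius: float = 8.0,
    uniformity_ring_fraction: float = 0.7,
) -> ROISet:
    """ROIs centred on the inserts plus background and uniformity circles.

    Insert ROIs use ``insert_fraction`` of the insert radius to stay clear of
    edge/partial-volume voxels; the background ROI sits on the insert ring at a
    fixed angular gap; the uniformity module gets one central and four
    peripheral ROIs (top/bottom/left/right) at 70% of the outer radius.
    """
    sens = spec.module_inserts(SENSITOMETRY)
    if not sens:
        raise ValidationError("phantom has no sensitometry inserts")
    insert_rois = tuple(
        ROI(i.name, i.center[0], i.center[1], insert_fraction * i.radius, i.material)
        for i in sens
    )
    ring_radius = math.hypot(*sens[0].center)
    theta0 = math.atan2(sens[0].center[1], sens[0].center[0])
    theta_bg = theta0 - math.radians(background_gap_deg)
    bg = ROI(
        "background",
        ring_radius * math.cos(theta_bg),
        ring_radius * math.sin(theta_bg),
        insert_fraction * sens[0].radius,
        spec.background_material,
    )
    ur = uniformity_ring_fraction * spec.outer_radius
    unif = [ROI("center", 0.0, 0.0, uniformity_radius, module=UNIFORMITY)]
    for name, (ux, uy) in (
        ("top", (0.0, -ur)),
        ("bottom", (0.0, ur)),
        ("left", (-ur, 0.0)),
        ("right", (ur, 0.0)),
    ):
        unif.append(ROI(name, ux, uy, uniformity_radius, module=UNIFORMITY))
    return ROISet(insert_rois=insert_rois, background_roi=bg, uniformity_rois=tuple(unif))


# ---------------------------------------------------------------------------
# rasterization and theoretical HU
# ---------------------------------------------------------------------------


def rasterize(spec: PhantomSpec, grid: ReconGrid, module: str = SENSITOMETRY):
    """Material-name image on the grid (pixel-center membership).

    Returns ``(labels, names)`` where ``labels`` is an int image indexing into
    ``names``; index 0 is the surrounding air, 1 the background cylinder.
    """
    if grid.half_extent_mm() < spec.outer_radius:
        raise CoverageError("reconstruction grid does not cover the phantom")
    x, y = grid.pixel_centers()
    names = ["air", spec.background_material]
    labels = np.zeros((grid.ny, grid.nx), dtype=np.int32)
    inside = x**2 + y**2 <= spec.outer_radius**2
    labels[inside] = 1
    for ins in spec.module_inserts(module):
        mask = (x - ins.center[0]) ** 2 + (y - ins.center[1]) ** 2 <= ins.radius**2
        names.append(ins.material)
        labels[mask] = len(names) - 1
    return labels, names


def theoretical_hu(material: str, energy: float) -> float:
    """1000 (mu_m - mu_w) / mu_w at ``energy`` from the embedded tables."""
    mu_m = linear_attenuation(get_material(material), energy)
    mu_w = linear_attenuation(get_material("water"), energy)
    return float(1000.0 * (mu_m - mu_w) / mu_w)


def theoretical_hu_image(
    spec: PhantomSpec, grid: ReconGrid, energy: float, module: str = SENSITOMETRY
) -> np.ndarray:
    """Ground-truth HU image of the rasterized phantom at ``energy``."""
    labels, names = rasterize(spec, grid, module=module)
    hu_by_label = np.array([theoretical_hu(n, energy) for n in names])
    return hu_by_label[labels]
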