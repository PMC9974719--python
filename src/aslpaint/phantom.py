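"""Seeded synthetic brain phantoms for end-to-end testing of the pipeline.

The phantom emulates the imaging situation of a non-enhancing low-grade
glioma study: a spherical head and brain with a white-matter core and a
gray-matter shell, a T2-Flair-like edema region (the GTV) containing a
hyper-perfused core whose CBF exceeds 1.4x the gray-matter reference, the
cranial organs at risk (brain stem, eyeballs, lenses, optic nerves, optic
chiasm), a ground-truth CBF map, and noisy control/label/PD ASL signal
volumes generated by the exact forward model of the quantification equation,
so that noiseless quantification inverts generation bit-for-bit.

Structures are analytic spheres and capsules rasterized by voxel-centre
inclusion, which makes their volumes exact oracles against the closed-form
sphere volume.  Two presets mirror the two clinical scenarios: "unilateral"
(lesion in one hemisphere, 60 Gy baseline prescription) and "midline"
(lesion straddling the mid-sagittal plane, 45-54 Gy baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .asl import ASLParameters, cbf_scale_factor
from .grid import StructureMask, VolumeGrid, centered_origin

__all__ = ["PhantomConfig", "Phantom", "generate_phantom",
           "unilateral_config", "midline_config", "OAR_NAMES"]

OAR_NAMES = (
    "brain_stem",
    "eyeball_l", "eyeball_r",
    "lens_l", "lens_r",
    "optic_nerve_l", "optic_nerve_r",
    "optic_chiasm",
)


def _default_oar_geometry() -> dict[str, dict[str, Any]]:
    """Analytic OAR primitives in phantom coordinates (mm, grid-centred).

    x: left(-) / right(+); y: posterior(-) / anterior(+); z: inferior(-) /
    superior(+).  Eyeballs sit anterior-inferior, the brain stem inferior on
    the midline, the optic nerves run from the eyes back to the chiasm.
    """
    return {
        "brain_stem": {"type": "capsule", "a": (0.0, -30.0, -60.0),
                       "b": (0.0, -30.0, -20.0), "radius": 7.5},
        "eyeball_l": {"type": "sphere", "center": (-28.0, 78.0, -20.0), "radius": 12.0},
        "eyeball_r": {"type": "sphere", "center": (28.0, 78.0, -20.0), "radius": 12.0},
        "lens_l": {"type": "sphere", "center": (-28.0, 87.0, -20.0), "radius": 4.0},
        "lens_r": {"type": "sphere", "center": (28.0, 87.0, -20.0), "radius": 4.0},
        "optic_nerve_l": {"type": "capsule", "a": (-28.0, 70.0, -20.0),
                          "b": (-6.0, 34.0, -20.0), "radius": 2.0},
        "optic_nerve_r": {"type": "capsule", "a": (28.0, 70.0, -20.0),
                          "b": (6.0, 34.0, -20.0), "radius": 2.0},
        "optic_chiasm": {"type": "sphere", "center": (0.0, 30.0, -20.0), "radius": 5.0},
    }


@dataclass
class PhantomConfig:
    """Geometry, tissue CBF levels and noise of the synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm

    body_radius_mm: float = 94.0
    brain_radius_mm: float = 80.0
    wm_radius_mm: float = 55.0

    gtv_center_mm: tuple[float, float, float] = (-48.0, 15.0, 8.0)
    gtv_radius_mm: float = 25.0
    core_radius_mm: float = 12.0  # hyper-perfused core nested in the GTV
    # offset of the core centre from the GTV centre: hyper-perfused cores are
    # typically eccentric within the edema, not concentric
    core_offset_mm: tuple[float, float, float] = (8.0, 0.0, 0.0)

    # Ground-truth CBF levels, ml/100 g/min
    cbf_gm: float = 60.0
    cbf_wm: float = 20.0
    cbf_edema: float = 40.0
    cbf_core: float = 120.0

    # PD-weighted signal levels (arbitrary units) per compartment
    pd_brain: float = 1000.0
    pd_body: float = 600.0

    # Additive Gaussian noise s.d. on control and label signals (same units)
    noise_sd: float = 0.5

    oar_geometry: dict[str, dict[str, Any]] = field(default_factory=_default_oar_geometry)

    scenario: str = "unilateral"  # or "midline"
    # Insula-analog gray-matter reference used in the midline scenario
    insula_center_mm: tuple[float, float, float] = (-60.0, 10.0, -5.0)
    insula_radius_mm: float = 10.0

    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(n) for n in self.grid_shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if self.gtv_radius_mm > 0 and not self.core_radius_mm < self.gtv_radius_mm:
            raise ValueError("core_radius_mm must be strictly smaller than gtv_radius_mm")
        off = float(np.linalg.norm(self.core_offset_mm))
        if self.gtv_radius_mm > 0 and off + self.core_radius_mm >= self.gtv_radius_mm:
            raise ValueError("the core (offset + radius) must lie strictly inside the GTV")
        if self.gtv_radius_mm == 0 and self.core_radius_mm != 0:
            raise ValueError("core_radius_mm must be 0 when gtv_radius_mm is 0")
        for name in ("cbf_gm", "cbf_wm", "cbf_edema", "cbf_core"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pd_brain <= 0 or self.pd_body <= 0:
            raise ValueError("PD signal levels must be positive")
        if self.scenario not in ("unilateral", "midline"):
            raise ValueError(f"unknown scenario '{self.scenario}'")
        self._check_extents()

    def _check_extents(self) -> None:
        half = [(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.voxel_spacing)]

        def inside(center, radius, what):
            for c, h in zip(center, half):
                if abs(c) + radius > h + 1e-9:
                    raise ValueError(f"structure '{what}' exceeds the grid extent")

        inside((0, 0, 0), self.body_radius_mm, "body")
        inside((0, 0, 0), self.brain_radius_mm, "brain")
        if self.gtv_radius_mm > 0:
            inside(self.gtv_center_mm, self.gtv_radius_mm, "GTV")
        for name, spec in self.oar_geometry.items():
            if spec["type"] == "sphere":
                inside(spec["center"], spec["radius"], name)
            elif spec["type"] == "capsule":
                inside(spec["a"], spec["radius"], name)
                inside(spec["b"], spec["radius"], name)
            else:
                raise ValueError(f"unknown primitive type '{spec['type']}' for {name}")


def unilateral_config(seed: int = 0, **overrides: Any) -> PhantomConfig:
    """Lesion confined to the left hemisphere (60 Gy baseline scenario)."""
    return replace(PhantomConfig(scenario="unilateral", seed=seed), **overrides)


def midline_config(seed: int = 0, **overrides: Any) -> PhantomConfig:
    """Lesion straddling the mid-sagittal plane (45-54 Gy baseline scenario).

    The rCBF reference is the insula-analog gray-matter region rather than
    mirrored gray matter.
    """
    cfg = PhantomConfig(scenario="midline", seed=seed,
                        gtv_center_mm=(0.0, 15.0, 8.0))
    return replace(cfg, **overrides)


@dataclass
class Phantom:
    """Ground truth plus simulated acquisition on one shared geometry."""

    config: PhantomConfig
    truth_cbf: VolumeGrid
    tissue_masks: dict[str, StructureMask]     # body, brain, gray_matter, white_matter
    structure_masks: dict[str, StructureMask]  # GTV, hyperperfused core, OARs, midline ref
    asl_control: VolumeGrid
    asl_label: VolumeGrid
    asl_pd: VolumeGrid


def _sphere(grid: VolumeGrid, center, radius) -> np.ndarray:
    if radius <= 0:
        return np.zeros(grid.shape, dtype=bool)
    x, y, z = grid.coordinate_arrays()
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2
            + (z - center[2]) ** 2) <= radius ** 2


def _capsule(grid: VolumeGrid, a, b, radius) -> np.ndarray:
    """Voxels within `radius` mm of the segment a-b (a cylinder with round caps)."""
    x, y, z = grid.coordinate_arrays()
    a = np.asarray(a, float)
    d = np.asarray(b, float) - a
    len2 = float(d @ d)
    px, py, pz = x - a[0], y - a[1], z - a[2]
    t = (px * d[0] + py * d[1] + pz * d[2]) / len2 if len2 > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    return ((px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
            + (pz - t * d[2]) ** 2) <= radius ** 2


def _rasterize_oar(grid: VolumeGrid, spec: Mapping[str, Any]) -> np.ndarray:
    if spec["type"] == "sphere":
        return _sphere(grid, spec["center"], spec["radius"])
    return _capsule(grid, spec["a"], spec["b"], spec["radius"])


def generate_phantom(config: PhantomConfig,
                     asl_params: ASLParameters = ASLParameters()) -> Phantom:
    """Build masks, ground-truth CBF and noisy ASL signals from a config.

    The forward signal model is the exact inverse of the quantification
    closed form: SI_control - SI_label = truth_cbf * SI_PD / scale, so a
    noiseless phantom quantifies back to ``truth_cbf`` to floating-point
    accuracy.  With ``noise_sd > 0``, independent Gaussian noise is added to
    the control and label images (the PD calibration image stays clean).
    """
    config.validate()
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = tuple(float(s) for s in config.voxel_spacing)
    origin = centered_origin(shape, spacing)
    geom = VolumeGrid(np.zeros(shape, dtype=np.float32), spacing, origin)

    body = _sphere(geom, (0, 0, 0), config.body_radius_mm)
    brain = _sphere(geom, (0, 0, 0), config.brain_radius_mm)
    wm_core = _sphere(geom, (0, 0, 0), config.wm_radius_mm)
    gtv = _sphere(geom, config.gtv_center_mm, config.gtv_radius_mm)
    core_center = tuple(c + o for c, o in zip(config.gtv_center_mm,
                                              config.core_offset_mm))
    core = _sphere(geom, core_center, config.core_radius_mm)

    if gtv.any() and not np.all(brain[gtv]):
        raise ValueError("GTV is not fully inside the brain mask")

    oars: dict[str, np.ndarray] = {}
    for name in OAR_NAMES:
        oars[name] = _rasterize_oar(geom, config.oar_geometry[name])
    # Enforce pairwise disjointness by anatomical carving: the lens is cut out
    # of its eyeball; the nerves out of eyes, lenses and chiasm.
    for side in ("l", "r"):
        oars[f"eyeball_{side}"] &= ~oars[f"lens_{side}"]
        oars[f"optic_nerve_{side}"] &= ~(oars[f"eyeball_{side}"] | oars[f"lens_{side}"]
                                         | oars["optic_chiasm"])
    names = list(oars)
    for i, a in enumerate(names):
        if (oars[a] & gtv).any():
            raise ValueError(f"OAR '{a}' overlaps the GTV")
        for b in names[i + 1:]:
            if (oars[a] & oars[b]).any():
                raise ValueError(f"OARs '{a}' and '{b}' overlap")

    oar_union = np.zeros(shape, dtype=bool)
    for m in oars.values():
        oar_union |= m
    gray = brain & ~wm_core & ~gtv & ~oar_union
    white = wm_core & ~gtv & ~oar_union

    truth = np.zeros(shape, dtype=np.float64)
    truth[brain] = config.cbf_gm
    truth[wm_core] = config.cbf_wm
    truth[gtv] = config.cbf_edema
    truth[core] = config.cbf_core

    pd_img = np.zeros(shape, dtype=np.float64)
    pd_img[body] = config.pd_body
    pd_img[brain] = config.pd_brain

    scale = cbf_scale_factor(asl_params)
    diff = truth * pd_img / scale  # control-label difference signal
    control = pd_img.copy()
    label = control - diff

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        control = control + rng.normal(0.0, config.noise_sd, shape)
        label = label + rng.normal(0.0, config.noise_sd, shape)

    def mk(name: str, arr: np.ndarray) -> StructureMask:
        return StructureMask.from_grid(name, arr, geom)

    tissue = {
        "body": mk("body", body),
        "brain": mk("brain", brain),
        "gray_matter": mk("gray_matter", gray),
        "white_matter": mk("white_matter", white),
    }
    structures = {"GTV": mk("GTV", gtv), "hyperperfused_core": mk("hyperperfused_core", core)}
    for name, m in oars.items():
        structures[name] = mk(name, m)
    insula = _sphere(geom, config.insula_center_mm, config.insula_radius_mm) & gray
    structures["insula_reference"] = mk("insula_reference", insula)

    return Phantom(
        config=config,
        truth_cbf=geom.like(truth),
        tissue_masks=tissue,
        structure_masks=structures,
        asl_control=geom.like(control),
        asl_label=geom.like(label),
        asl_pd=geom.like(pd_img),
    )
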