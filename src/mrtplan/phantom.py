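"""Voxelized phantoms: synthetic slabs, a layered mouse head, and CT import.

Arrays are indexed ``[iz, iy, ix]`` with axis 0 the beam/depth axis (the beam
travels toward increasing z).  Voxels are cubic, default 1 mm.  ``origin_mm``
records where voxel ``[0,0,0]``'s near corner sits in the beam frame (source at
the origin, z along the beam axis); it is filled in when a phantom is placed
behind the collimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import get_material, hu_to_material, material_names, material_to_hu


@dataclass
class VoxelPhantom:
    """3D material/density grid.

    ``material_id`` indexes into ``materials`` (a tuple of bundled material
    names); ``density`` is in g/cm^3.  ``roi`` maps ROI tags to boolean masks.
    """

    material_id: np.ndarray  # int16, shape (nz, ny, nx)
    density: np.ndarray  # float64, same shape
    voxel_size_mm: float = 1.0
    origin_mm: tuple[float, float, float] | None = None
    materials: tuple[str, ...] = ()
    roi: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.material_id.shape != self.density.shape:
            raise ValueError("material_id and density shapes differ")
        if self.material_id.ndim != 3:
            raise ValueError("phantom grids must be 3D (nz, ny, nx)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_id.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.shape)

    def material_name(self, idx: int) -> str:
        return self.materials[idx]

    def depth_grid_mm(self) -> np.ndarray:
        """Depth of each slice center from the phantom entrance, in mm."""
        nz = self.shape[0]
        return (np.arange(nz) + 0.5) * self.voxel_size_mm

    def to_hu(self) -> np.ndarray:
        """Inverse HU map (only valid for HU-representable materials)."""
        hu = np.empty(self.shape, dtype=float)
        for idx, name in enumerate(self.materials):
            mask = self.material_id == idx
            if not mask.any():
                continue
            hu[mask] = [material_to_hu(name, d) for d in self.density[mask]]
        return hu


def _dims_to_shape(dims_mm, voxel_mm: float) -> tuple[int, int, int]:
    shape = []
    for d in dims_mm:
        n = d / voxel_mm
        n_round = int(np.ceil(n - 1e-9))
        if abs(n - round(n)) > 1e-9:
            warnings.warn(
                f"dimension {d} mm is not a multiple of voxel {voxel_mm} mm; "
                f"rounded up to {n_round} voxels",
                stacklevel=3,
            )
        shape.append(n_round)
    return tuple(shape)


def make_slab_phantom(
    dims_mm: tuple[float, float, float],
    material: str = "pmma",
    voxel_mm: float = 1.0,
    film_depths_mm: tuple[float, ...] = (),
) -> VoxelPhantom:
    """Homogeneous slab phantom, dims given as (depth, height, width) in mm.

    ``film_depths_mm`` records nominal film-plane positions as metadata only
    (films are assumed thin enough not to perturb transport).
    """
    if any(d <= 0 for d in dims_mm):
        raise ValueError("phantom dimensions must be positive")
    shape = _dims_to_shape(dims_mm, voxel_mm)
    mat = get_material(material)
    mat_id = np.zeros(shape, dtype=np.int16)
    density = np.full(shape, mat.density)
    ph = VoxelPhantom(
        material_id=mat_id,
        density=density,
        voxel_size_mm=voxel_mm,
        materials=(material,),
    )
    ph.roi["film_depths_mm"] = tuple(film_depths_mm)
    return ph


def make_mouse_head_phantom(
    brain_thickness_mm: float = 6.0,
    bed_mm: float = 3.0,
    skin_mm: float = 1.0,
    skull_mm: float = 1.0,
    lateral_mm: float = 20.0,
    voxel_mm: float = 1.0,
    roi_depth_mm: tuple[float, float] = (9.0, 15.0),
) -> VoxelPhantom:
    """Layered mouse-head stand-in: PMMA bed, skin, skull, brain, skull, skin.

    Layers are stacked along the beam axis.  The treatment target is the brain
    tissue between ``roi_depth_mm`` (measured from the phantom entrance, i.e.
    including the bed), tagged as ROI ``"brain"``.
    """
    for v in (brain_thickness_mm, bed_mm, skin_mm, skull_mm):
        if v < 0:
            raise ValueError("layer thicknesses must be non-negative")
    # soft-tissue padding so that the ROI lands at the requested depth
    pre_brain = bed_mm + skin_mm + skull_mm
    pad_mm = max(roi_depth_mm[0] - pre_brain, 0.0)
    layers = [
        ("pmma", bed_mm),
        ("soft_tissue", skin_mm),
        ("bone_cortical", skull_mm),
        ("soft_tissue", pad_mm),  # cranial soft tissue above the target
        ("soft_tissue", brain_thickness_mm),  # target brain slab
        ("bone_cortical", skull_mm),
        ("soft_tissue", skin_mm),
    ]
    total = sum(t for _, t in layers)
    nz = int(np.ceil(total / voxel_mm - 1e-9))
    nxy = int(np.ceil(lateral_mm / voxel_mm - 1e-9))
    names = tuple(material_names())
    name_to_idx = {n: i for i, n in enumerate(names)}
    mat_id = np.zeros((nz, nxy, nxy), dtype=np.int16)
    density = np.zeros((nz, nxy, nxy))
    z = 0.0
    for mat_name, thick in layers:
        if thick <= 0:
            continue
        i0 = int(round(z / voxel_mm))
        i1 = int(round((z + thick) / voxel_mm))
        i1 = min(max(i1, i0 + 1), nz)
        m = get_material(mat_name)
        mat_id[i0:i1] = name_to_idx[mat_name]
        density[i0:i1] = m.density
        z += thick
    ph = VoxelPhantom(
        material_id=mat_id, density=density, voxel_size_mm=voxel_mm, materials=names
    )
    depth = ph.depth_grid_mm()
    roi_mask = np.zeros(ph.shape, dtype=bool)
    in_roi = (depth >= roi_depth_mm[0]) & (depth <= roi_depth_mm[1])
    roi_mask[in_roi] = True
    ph.roi["brain"] = roi_mask
    return ph


def resample_rotated(
    phantom: VoxelPhantom,
    couch_angle_deg: float = 0.0,
    gantry_angle_deg: float = 0.0,
) -> VoxelPhantom:
    """Resample the phantom onto the beam frame for rotated setups.

    The transport engines assume a fixed beam axis, so couch/gantry rotations
    are applied to the phantom instead: couch rotates about the beam axis
    (the y-x plane), gantry tilts the stack (the z-y plane).  Densities are
    interpolated linearly, material labels nearest-neighbor; voxels rotated
    in from outside become air.
    """
    from scipy.ndimage import rotate

    names = tuple(phantom.materials) or tuple(material_names())
    air_idx = names.index("air") if "air" in names else 0
    density = phantom.density
    mat_id = phantom.material_id
    for angle, axes in ((couch_angle_deg, (1, 2)), (gantry_angle_deg, (0, 1))):
        if angle % 360.0 == 0.0:
            continue
        density = rotate(
            density, angle, axes=axes, reshape=False, order=1,
            mode="constant", cval=get_material("air").density,
        )
        mat_id = rotate(
            mat_id, angle, axes=axes, reshape=False, order=0,
            mode="constant", cval=air_idx,
        )
    return VoxelPhantom(
        material_id=mat_id.astype(np.int16),
        density=np.clip(density, 0.0, None),
        voxel_size_mm=phantom.voxel_size_mm,
        origin_mm=phantom.origin_mm,
        materials=names,
        roi=dict(phantom.roi),
    )


def phantom_from_hu(
    hu: np.ndarray, voxel_mm: float = 1.0
) -> VoxelPhantom:
    """Build a phantom from a CT volume in Hounsfield units."""
    names, dens = hu_to_material(hu.ravel())
    all_names = tuple(material_names())
    name_to_idx = {n: i for i, n in enumerate(all_names)}
    mat_id = np.array([name_to_idx[n] for n in names], dtype=np.int16)
    return VoxelPhantom(
        material_id=mat_id.reshape(hu.shape),
        density=dens.reshape(hu.shape),
        voxel_size_mm=voxel_mm,
        materials=all_names,
    )


def load_ct_volume(path, voxel_mm: float | None = None) -> VoxelPhantom:
    """Load a NIfTI (or NRRD via nibabel where supported) HU volume."""
    import nibabel as nib

    img = nib.load(str(path))
    hu = np.asarray(img.get_fdata())
    if voxel_mm is None:
        zooms = img.header.get_zooms()[:3]
        voxel_mm = float(zooms[0])
    return phantom_from_hu(hu, voxel_mm=voxel_mm)


def export_volume(path, array: np.ndarray, voxel_mm: float) -> None:
    """Write a scalar volume as NIfTI with isotropic voxel size."""
    import nibabel as nib

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))
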