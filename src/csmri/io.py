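"""File I/O: HDF5 array containers, NIfTI image export, CSV masks, YAML
protocols."""
from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .acquisition import KSpaceData, ProtocolParams, SamplingMask
from .phantom import CoilSet, Lesion, Phantom


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_phantom(path, phantom: Phantom, coils: CoilSet | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.create_dataset("proton_density", data=phantom.proton_density)
        g.create_dataset("t2_map", data=phantom.t2_map)
        g.create_dataset("phase_map", data=phantom.phase_map)
        g.create_dataset("labels", data=phantom.labels)
        g.attrs["pixel_size"] = phantom.pixel_size
        for i, les in enumerate(phantom.lesion_list):
            lg = g.create_group(f"lesion/{i}")
            lg.attrs.update(
                center=les.center, radius=les.radius,
                tissue_class=les.tissue_class, label=les.label,
            )
        if coils is not None:
            c = f.create_group("coils")
            c.create_dataset("sensitivities", data=coils.sensitivities)
            c.create_dataset("support_mask", data=coils.support_mask)


def load_phantom(path) -> tuple[Phantom, CoilSet | None]:
    with h5py.File(path, "r") as f:
        g = f["phantom"]
        lesions = []
        if "lesion" in g:
            for key in sorted(g["lesion"], key=int):
                a = g[f"lesion/{key}"].attrs
                lesions.append(
                    Lesion(tuple(int(v) for v in a["center"]), float(a["radius"]),
                           str(a["tissue_class"]), int(a["label"]))
                )
        phantom = Phantom(
            proton_density=g["proton_density"][()],
            t2_map=g["t2_map"][()],
            phase_map=g["phase_map"][()],
            labels=g["labels"][()],
            pixel_size=float(g.attrs["pixel_size"]),
            lesion_list=lesions,
        )
        coils = None
        if "coils" in f:
            coils = CoilSet(f["coils/sensitivities"][()], f["coils/support_mask"][()])
    return phantom, coils


def save_kspace(path, ks: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ks.data)
        f.create_dataset("echo_times_ms", data=ks.echo_times_ms)
        f.attrs["noise_sigma"] = ks.noise_sigma
        f.attrs["is_reference"] = ks.is_reference
        m = f.create_group("mask")
        m.create_dataset("sampled_lines", data=ks.mask.sampled_lines)
        m.create_dataset("acs_lines", data=ks.mask.acs_lines)
        m.attrs["n_pe"] = ks.mask.n_pe
        m.attrs["kind"] = ks.mask.kind
        if ks.mask.seed is not None:
            m.attrs["seed"] = ks.mask.seed


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        m = f["mask"]
        mask = SamplingMask(
            n_pe=int(m.attrs["n_pe"]),
            sampled_lines=m["sampled_lines"][()],
            kind=str(m.attrs["kind"]),
            acs_lines=m["acs_lines"][()],
            seed=int(m.attrs["seed"]) if "seed" in m.attrs else None,
        )
        return KSpaceData(
            data=f["data"][()],
            mask=mask,
            echo_times_ms=f["echo_times_ms"][()],
            noise_sigma=float(f.attrs["noise_sigma"]),
            is_reference=bool(f.attrs["is_reference"]),
        )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_nifti(path, image: np.ndarray, pixel_size: float = 1.0) -> None:
    """Magnitude image -> NIfTI volume (single slice, isotropic mm)."""
    data = np.abs(np.asarray(image))[..., None].astype(np.float32)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def export_image_csv(path, image: np.ndarray) -> None:
    np.savetxt(path, np.abs(np.asarray(image)), delimiter=",")


def export_image_png(path, image: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.abs(np.asarray(image)), cmap="gray")


def mask_to_csv(path, mask: SamplingMask) -> None:
    np.savetxt(path, mask.sampled_lines, fmt="%d")


def save_protocol(path, params: ProtocolParams) -> None:
    d = {k: v for k, v in vars(params).items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_protocol(path) -> ProtocolParams:
    d = yaml.safe_load(Path(path).read_text())
    known = set(ProtocolParams.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown protocol keys {sorted(unknown)}")
    return ProtocolParams(**d)
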