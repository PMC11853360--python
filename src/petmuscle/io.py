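"""NIfTI + JSON-sidecar serialization of phantoms.

Each phantom is written as a directory holding four NIfTI volumes sharing one
affine (activity in kBq/mL as float32, the integer label map, and uint8
vessel and blood-pool reference masks) plus ``sidecar.json`` carrying subject
metadata, landmark coordinates and the generator's ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .atlas import Grid, MuscleAtlas
from .phantom import MuscleTruth, PhantomVolume, SubjectParams


def _save(path: Path, data: np.ndarray, affine: np.ndarray, dtype) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), affine), str(path))


def write_phantom(phantom: PhantomVolume, outdir) -> Path:
    """Write one phantom; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = phantom.atlas
    affine = atlas.grid.affine
    _save(out / "activity.nii.gz", phantom.activity, affine, np.float32)
    _save(out / "labels.nii.gz", atlas.labels, affine, np.int16)
    _save(out / "vessel.nii.gz", atlas.vessel_mask, affine, np.uint8)
    _save(out / "reference.nii.gz", atlas.reference_mask, affine, np.uint8)

    sidecar = {
        "subject_id": phantom.subject_id,
        "weight_kg": phantom.subject.weight_kg,
        "dose_MBq": phantom.subject.dose_mbq,
        "group": phantom.subject.group,
        "multiplier": phantom.subject.multiplier,
        "baseline_suv": phantom.subject.baseline_suv,
        "blood_suv": phantom.subject.blood_suv,
        "body_suv": phantom.subject.body_suv,
        "seed": phantom.seed,
        "psf_fwhm_mm": phantom.psf_fwhm_mm,
        "noise_coeff": phantom.noise_coeff,
        "spacing_mm": atlas.grid.spacing,
        "shape": list(atlas.grid.shape),
        "origin_mm": list(atlas.grid.origin),
        "label_codes": {f"{m}_{s}": int(c) for (m, s), c in atlas.label_codes.items()},
        "landmarks_mm": {
            f"{m}_{s}": [list(map(float, p)) for p in pts]
            for (m, s), pts in atlas.landmarks.items()
        },
        "l5s1_mm": list(map(float, atlas.l5s1_point)),
        "muscle_radius_mm": atlas.muscle_radius_mm,
        "ground_truth": {
            f"{m}_{s}": {
                "pattern": t.pattern,
                "n_foci": t.n_foci,
                "focus_centers_mm": np.asarray(t.focus_centers).tolist(),
                "amplitude": t.amplitude,
                "radius_mm": t.radius_mm,
                "baseline_suv": t.baseline_suv,
                "true_max_suv": t.true_max_suv,
            }
            for (m, s), t in phantom.truth.items()
        },
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_phantom(indir) -> PhantomVolume:
    """Read a phantom directory written by :func:`write_phantom`."""
    p = Path(indir)
    sidecar = json.loads((p / "sidecar.json").read_text())
    activity = np.asarray(nib.load(str(p / "activity.nii.gz")).dataobj, dtype=np.float64)
    labels = np.asarray(nib.load(str(p / "labels.nii.gz")).dataobj, dtype=np.int16)
    vessel = np.asarray(nib.load(str(p / "vessel.nii.gz")).dataobj).astype(bool)
    reference = np.asarray(nib.load(str(p / "reference.nii.gz")).dataobj).astype(bool)

    grid = Grid(
        shape=tuple(sidecar["shape"]),
        spacing=float(sidecar["spacing_mm"]),
        origin=tuple(sidecar["origin_mm"]),
    )
    codes = {}
    for key, c in sidecar["label_codes"].items():
        m, s = key.rsplit("_", 1)
        codes[(m, s)] = int(c)
    landmarks = {}
    for key, pts in sidecar["landmarks_mm"].items():
        m, s = key.rsplit("_", 1)
        landmarks[(m, s)] = (np.asarray(pts[0]), np.asarray(pts[1]))
    atlas = MuscleAtlas(
        grid=grid,
        labels=labels,
        label_codes=codes,
        vessel_mask=vessel,
        reference_mask=reference,
        landmarks=landmarks,
        l5s1_point=np.asarray(sidecar["l5s1_mm"]),
        muscle_radius_mm=sidecar["muscle_radius_mm"],
    )
    subject = SubjectParams(
        weight_kg=sidecar["weight_kg"],
        dose_mbq=sidecar["dose_MBq"],
        group=sidecar["group"],
        multiplier=sidecar["multiplier"],
        baseline_suv=sidecar["baseline_suv"],
        blood_suv=sidecar["blood_suv"],
        body_suv=sidecar["body_suv"],
    )
    truth = {}
    for key, t in sidecar["ground_truth"].items():
        m, s = key.rsplit("_", 1)
        truth[(m, s)] = MuscleTruth(
            muscle=m,
            side=s,
            pattern=t["pattern"],
            n_foci=t["n_foci"],
            focus_centers=np.asarray(t["focus_centers_mm"], dtype=float).reshape(-1, 3),
            amplitude=t["amplitude"],
            radius_mm=t["radius_mm"],
            baseline_suv=t["baseline_suv"],
            true_max_suv=t["true_max_suv"],
        )
    return PhantomVolume(
        activity=activity,
        atlas=atlas,
        subject=subject,
        truth=truth,
        psf_fwhm_mm=sidecar["psf_fwhm_mm"],
        noise_coeff=sidecar["noise_coeff"],
        seed=sidecar["seed"],
        subject_id=sidecar["subject_id"],
    )
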