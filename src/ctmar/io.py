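"""Slice I/O and dataset manifests.

Two on-disk forms for a :class:`~ctmar.core.CTSlice`:

* DICOM (``.dcm``) — interchange format; HU round-trips losslessly for
  integer HU in [-1024, 3071] via 16-bit stored values with RescaleSlope 1
  and RescaleIntercept -1024.  Files lacking rescale or spacing metadata
  are rejected, never silently assumed to be HU.
* the toolkit container (``.npy`` + JSON sidecar) — lossless float HU with
  spacing/thickness/id/meta carried in ``<name>.json``.

Dataset manifests are patient-keyed TSV files assigning every patient to
train/test and the training side to one of five folds, so no patient ever
leaks across a split boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CTSlice, PairedSample
from .model.data import holdout_split, kfold_split

__all__ = ["read_ct", "write_ct", "DatasetManifest", "build_manifest",
           "load_manifest_samples"]

_UID_ROOT = "1.2.826.0.1.3680043.8.498."


def _deterministic_uid(tag: str) -> str:
    import hashlib
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:12], "big")
    return _UID_ROOT + str(h)


def write_ct(ct: CTSlice, path) -> Path:
    """Write a slice as DICOM (``.dcm``) or the array container (``.npy``)."""
    path = Path(path)
    if path.suffix == ".dcm":
        _write_dicom(ct, path)
    elif path.suffix == ".npy":
        np.save(path, ct.values)
        sidecar = {"pixel_spacing": ct.pixel_spacing,
                   "thickness": ct.thickness, "id": ct.id, "hu": True,
                   "meta": _jsonable(ct.meta)}
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unsupported slice format {path.suffix!r} "
                         "(use .dcm or .npy)")
    return path


def read_ct(path) -> CTSlice:
    path = Path(path)
    if path.suffix == ".dcm":
        return _read_dicom(path)
    if path.suffix == ".npy":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"container sidecar {sidecar_path.name} is missing")
        sc = json.loads(sidecar_path.read_text())
        return CTSlice(values=np.load(path),
                       pixel_spacing=sc["pixel_spacing"],
                       thickness=sc.get("thickness", 3.0),
                       id=sc.get("id", path.stem), meta=sc.get("meta", {}))
    raise ValueError(f"unsupported slice format {path.suffix!r}")


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, (str, int, float, bool, type(None), list, tuple)):
            out[k] = v
    return out


def _write_dicom(ct: CTSlice, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = _deterministic_uid(ct.id or path.stem)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = ct.id or path.stem
    ds.Rows, ds.Columns = ct.shape
    ds.PixelSpacing = [f"{ct.pixel_spacing:g}", f"{ct.pixel_spacing:g}"]
    ds.SliceThickness = f"{ct.thickness:g}"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    stored = np.clip(np.rint(ct.values), -1024, 3071).astype(np.int64) + 1024
    ds.PixelData = stored.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path) -> CTSlice:
    import pydicom

    ds = pydicom.dcmread(path)
    for attr in ("RescaleSlope", "RescaleIntercept"):
        if not hasattr(ds, attr):
            raise ValueError(
                f"{path.name}: missing {attr}; refusing to assume stored "
                "values are HU")
    if not hasattr(ds, "PixelSpacing"):
        raise ValueError(f"{path.name}: missing PixelSpacing")
    hu = (ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
          + float(ds.RescaleIntercept))
    return CTSlice(values=hu, pixel_spacing=float(ds.PixelSpacing[0]),
                   thickness=float(getattr(ds, "SliceThickness", 3.0)),
                   id=str(getattr(ds, "PatientID", path.stem)))


@dataclass
class DatasetManifest:
    """Patient-keyed sample records with split/fold assignment."""

    records: list = field(default_factory=list)  # dicts
    seed: int = 0
    version: str = "0.1.0"

    COLUMNS = ("patient", "slice", "ref", "art", "cor", "split", "fold",
               "sim_seed")

    def to_tsv(self, path) -> None:
        lines = ["\t".join(self.COLUMNS)]
        for r in sorted(self.records,
                        key=lambda r: (r["patient"], r["slice"])):
            lines.append("\t".join(str(r.get(c, "")) for c in self.COLUMNS))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DatasetManifest":
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0].split("\t")
        recs = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
        return cls(records=recs)

    def patients(self, split: str | None = None) -> list[str]:
        out = []
        for r in self.records:
            if split and r["split"] != split:
                continue
            if r["patient"] not in out:
                out.append(r["patient"])
        return out


def build_manifest(data_dir, test_fraction: float = 0.15, folds: int = 5,
                   seed: int = 0) -> DatasetManifest:
    """Discover ``*_ref.npy`` / ``*_art.npy`` pairs and assign splits.

    The stem before ``_ref``/``_art`` identifies the slice; the part before
    an optional ``_s<k>`` suffix identifies the patient.  Every art file
    must have its ref twin (orphans are an error, listed by name).  The
    85/15 holdout and the five-fold assignment of the training side are
    both at patient level.
    """
    data_dir = Path(data_dir)
    refs = {p.name[:-8]: p for p in sorted(data_dir.glob("*_ref.npy"))}
    arts = {p.name[:-8]: p for p in sorted(data_dir.glob("*_art.npy"))}
    orphans = sorted(set(arts) - set(refs))
    if orphans:
        raise ValueError("artifacted slices without a reference twin: "
                         + ", ".join(orphans))
    if not refs:
        raise ValueError(f"no *_ref.npy slices found in {data_dir}")

    @dataclass
    class _Stub:
        patient_id: str

    def pid(stem: str) -> str:
        return stem.split("_s")[0]

    stems = sorted(set(refs) & set(arts))
    stubs = [_Stub(pid(s)) for s in stems]
    train_stubs, test_stubs = holdout_split(stubs, test_fraction, seed)
    test_pids = {s.patient_id for s in test_stubs}
    fold_of = kfold_split(train_stubs, folds, seed)

    records = []
    for stem in stems:
        p = pid(stem)
        is_test = p in test_pids
        cor = data_dir / f"{stem}_cor.npy"
        records.append({
            "patient": p, "slice": stem,
            "ref": refs[stem].name, "art": arts[stem].name,
            "cor": cor.name if cor.exists() else "",
            "split": "test" if is_test else "train",
            "fold": "" if is_test else f"fold-{fold_of[p] + 1}",
            "sim_seed": ""})
    return DatasetManifest(records=records, seed=seed)


def load_manifest_samples(data_dir, manifest: DatasetManifest,
                          split: str | None = None) -> list[PairedSample]:
    """Materialize paired samples for one split (ref/art and cor if present)."""
    data_dir = Path(data_dir)
    out = []
    for r in manifest.records:
        if split and r["split"] != split:
            continue
        cor = None
        if r.get("cor"):
            cor_path = data_dir / r["cor"]
            if cor_path.exists():
                cor = read_ct(cor_path)
        out.append(PairedSample(ref=read_ct(data_dir / r["ref"]),
                                art=read_ct(data_dir / r["art"]), cor=cor,
                                patient_id=r["patient"],
                                slice_id=r["slice"]))
    return out
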