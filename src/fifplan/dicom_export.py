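"""Minimal DICOM RT Plan / RT Dose export via pydicom (optional extra).

Writes one RT Dose file per beam plus the plan total, and one RT Plan file
carrying beam geometry, jaw and MLC leaf positions.  The files carry the
required identification and grid tags for interchange; they are not intended
to pass a full TPS import validation.
"""

from __future__ import annotations

import datetime
import os

import numpy as np

try:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid, ExplicitVRLittleEndian
except ImportError as exc:  # pragma: no cover - exercised only without extra
    raise ImportError("DICOM export requires the 'dicom' extra (pydicom)") from exc

_RTDOSE = "1.2.840.10008.5.1.4.1.1.481.2"
_RTPLAN = "1.2.840.10008.5.1.4.1.1.481.5"


def _base_dataset(sop_class: str) -> "pydicom.FileDataset":
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "Phantom^Pelvis"
    ds.PatientID = "FIFPLAN"
    ds.Modality = "RTDOSE" if sop_class == _RTDOSE else "RTPLAN"
    now = datetime.datetime(2000, 1, 1)
    ds.StudyDate = ds.SeriesDate = now.strftime("%Y%m%d")
    ds.StudyTime = ds.SeriesTime = now.strftime("%H%M%S")
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    return ds


def _dose_dataset(grid, label: str) -> "pydicom.FileDataset":
    ds = _base_dataset(_RTDOSE)
    arr = np.ascontiguousarray(grid.values)
    scale = float(arr.max()) / 65000.0 if arr.max() > 0 else 1.0
    pixels = np.round(arr / scale).astype(np.uint16)
    # DICOM dose grids are frame-major (z, y, x)
    pixels = np.transpose(pixels, (2, 1, 0))
    ds.SeriesDescription = label
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scale
    ds.NumberOfFrames = pixels.shape[0]
    ds.Rows, ds.Columns = pixels.shape[1], pixels.shape[2]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(pixels.shape[0])]
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    return ds


def _plan_dataset(plan) -> "pydicom.FileDataset":
    ds = _base_dataset(_RTPLAN)
    ds.RTPlanLabel = "FIFPLAN"
    ds.RTPlanGeometry = "PATIENT"
    beams = []
    for k, (beam, w) in enumerate(zip(plan.beams, plan.weights)):
        b = Dataset()
        b.BeamNumber = k + 1
        b.BeamName = beam.id
        b.BeamType = "STATIC"
        b.RadiationType = "PHOTON"
        b.SourceAxisDistance = beam.source_axis_distance
        b.FinalCumulativeMetersetWeight = w
        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.GantryAngle = beam.gantry_angle
        cp.IsocenterPosition = [float(v) for v in beam.isocenter]
        devices = []
        if beam.jaws is not None:
            for dev_type, pos in (("ASYMX", beam.jaws[:2]), ("ASYMY", beam.jaws[2:])):
                d = Dataset()
                d.RTBeamLimitingDeviceType = dev_type
                d.LeafJawPositions = [float(p) for p in pos]
                devices.append(d)
        if beam.mlc_a is not None:
            d = Dataset()
            d.RTBeamLimitingDeviceType = "MLCX"
            d.LeafJawPositions = [float(p) for p in np.concatenate([beam.mlc_a, beam.mlc_b])]
            devices.append(d)
        cp.BeamLimitingDevicePositionSequence = devices
        b.ControlPointSequence = [cp]
        beams.append(b)
    ds.BeamSequence = beams
    return ds


def export_rt_series(plan, total_dose, directory: str) -> list[str]:
    """One RT Dose per beam, one plan-total RT Dose, one RT Plan."""
    written = []
    for bd in plan.compute_beam_doses():
        path = os.path.join(directory, f"RD_beam_{bd.beam_id}.dcm")
        _dose_dataset(bd.dose, f"beam dose {bd.beam_id}").save_as(path, enforce_file_format=True)
        written.append(path)
    path = os.path.join(directory, "RD_plan.dcm")
    _dose_dataset(total_dose, "plan dose").save_as(path, enforce_file_format=True)
    written.append(path)
    path = os.path.join(directory, "RP_plan.dcm")
    _plan_dataset(plan).save_as(path, enforce_file_format=True)
    written.append(path)
    return written
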