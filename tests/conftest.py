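import numpy as np
import pydicom
import pytest
from hypothesis import settings
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from msquant.phantom import PhantomSpec, generate_phantom

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Default noiseless phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture()
def small_spec():
    """A reduced grid for tests that regenerate phantoms repeatedly."""
    return PhantomSpec(seed=0)


def make_dicom(path, patient_name="Doe^Jane", patient_id="P001", seed=0,
               rows=8, cols=8):
    """Write a minimal MR DICOM file with deterministic pixel data."""
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 4096, size=(rows, cols), dtype=np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(path), str(seed)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid(entropy_srcs=["study", patient_id])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=["series", patient_id, str(seed)])
    ds.PatientName = patient_name
    ds.PatientID = patient_id
    ds.PatientBirthDate = "19700101"
    ds.StudyDate = "20200101"
    ds.InstitutionName = "General Hospital"
    ds.Modality = "MR"
    ds.Rows, ds.Columns = rows, cols
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return pixels
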