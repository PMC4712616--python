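"""Dataset intake: DICOM de-identification, sequence inventory, layout.

Patient data arrive from a PACS export.  Before anything touches them the
pipeline (a) anonymizes the DICOM headers under a configurable tag policy,
writing the identity↔pseudonym mapping only to a separate protected file,
(b) checks each patient for the complete required sequence set, emitting a
missing-sequence checklist for every non-conforming patient, and
(c) copies conforming data into a canonical, vendor-independent layout.

Nothing here ever mutates an input directory: anonymization and layout
normalization are copy-based, and anonymization of an already-anonymized
tree is idempotent on header content.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pydicom
from pydicom.uid import UID

__all__ = [
    "TagPolicy", "AnonymizationReport", "InventoryReport",
    "anonymize_dicom_dir", "inventory_check", "normalize_layout",
    "CANONICAL_SEQUENCES",
]

#: canonical sequence names the whole pipeline speaks
CANONICAL_SEQUENCES = ("flair", "t1", "gd_t1", "dwi_b0", "dwi_x", "dwi_y",
                       "dwi_z", "dsc")

#: conservative de-identification defaults: direct identifiers blanked
DEFAULT_REMOVE_TAGS = (
    "PatientName", "PatientBirthDate", "PatientAddress", "PatientTelephoneNumbers",
    "OtherPatientIDs", "OtherPatientNames", "InstitutionName", "InstitutionAddress",
    "ReferringPhysicianName", "PerformingPhysicianName", "OperatorsName",
    "StudyDate", "SeriesDate", "AcquisitionDate", "ContentDate",
)

#: UID tags re-hashed deterministically (per-run salt) instead of blanked
UID_TAGS = ("StudyInstanceUID", "SeriesInstanceUID", "SOPInstanceUID")


@dataclass(frozen=True)
class TagPolicy:
    """Which DICOM header fields to blank, replace or preserve."""

    remove_tags: tuple[str, ...] = DEFAULT_REMOVE_TAGS
    replace_map: dict[str, str] = field(default_factory=dict)
    preserve_tags: tuple[str, ...] = ()
    rehash_uids: bool = True
    salt: str = "msquant"

    def __post_init__(self) -> None:
        clash = set(self.remove_tags) & set(self.preserve_tags)
        if clash:
            raise ValueError(f"tags both removed and preserved: {sorted(clash)}")


@dataclass
class AnonymizationReport:
    files_processed: int = 0
    files_skipped: int = 0
    tags_altered: dict[str, int] = field(default_factory=dict)
    skipped_files: list[str] = field(default_factory=list)
    mapping_file: str | None = None


#: org root marking UIDs this module already pseudonymized (idempotence)
_UID_ROOT = "1.2.826.0.1.3680043.10.424."


def _hashed_uid(uid: str, salt: str) -> UID:
    if uid.startswith(_UID_ROOT):
        return UID(uid)  # already pseudonymized; re-hashing must be a no-op
    digest = hashlib.sha256(f"{salt}:{uid}".encode()).hexdigest()
    # stay within the 64-char UID limit
    return UID(_UID_ROOT + str(int(digest[:28], 16)))


def anonymize_dicom_dir(in_dir: str | Path, out_dir: str | Path,
                        policy: TagPolicy | None = None) -> AnonymizationReport:
    """De-identify every DICOM file of ``in_dir`` into ``out_dir``.

    Pixel data are untouched.  ``remove_tags`` are blanked, ``replace_map``
    values substituted, UIDs re-hashed deterministically under the policy
    salt.  The original-identity → pseudonym mapping is written only to a
    separate ``identity_map.json`` in ``out_dir``, never into any header.
    Unreadable files are logged, skipped and counted.
    """
    policy = policy or TagPolicy()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    if in_dir.resolve() == out_dir.resolve():
        raise ValueError("out_dir must differ from in_dir (copy-before-modify)")
    out_dir.mkdir(parents=True, exist_ok=True)
    report = AnonymizationReport()
    identity_map: dict[str, dict[str, str]] = {}

    for path in sorted(p for p in in_dir.rglob("*") if p.is_file()):
        try:
            ds = pydicom.dcmread(str(path))
        except Exception:
            report.files_skipped += 1
            report.skipped_files.append(str(path))
            continue
        original = {"PatientName": str(ds.get("PatientName", "")),
                    "PatientID": str(ds.get("PatientID", ""))}
        for tag in policy.remove_tags:
            if tag in policy.preserve_tags:
                continue
            if hasattr(ds, tag) and str(getattr(ds, tag)) != "":
                setattr(ds, tag, "")
                report.tags_altered[tag] = report.tags_altered.get(tag, 0) + 1
        for tag, value in policy.replace_map.items():
            if str(ds.get(tag, None)) != value:
                setattr(ds, tag, value)
                report.tags_altered[tag] = report.tags_altered.get(tag, 0) + 1
        if policy.rehash_uids:
            for tag in UID_TAGS:
                if hasattr(ds, tag):
                    setattr(ds, tag, _hashed_uid(str(getattr(ds, tag)), policy.salt))
            if hasattr(ds, "file_meta") and hasattr(ds.file_meta, "MediaStorageSOPInstanceUID"):
                ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        rel = path.relative_to(in_dir)
        dest = out_dir / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        ds.save_as(str(dest), enforce_file_format=False)
        pseudonym = str(ds.get("PatientID", ""))
        if original["PatientName"] or original["PatientID"]:
            identity_map[str(rel)] = {**original, "pseudonym": pseudonym}
        report.files_processed += 1

    if report.files_processed:
        mapping_path = out_dir / "identity_map.json"
        mapping_path.write_text(json.dumps(identity_map, indent=2))
        try:
            mapping_path.chmod(0o600)  # protected file
        except OSError:
            pass
        report.mapping_file = str(mapping_path)
    return report


@dataclass
class InventoryReport:
    """Per-patient sequence availability and the conforming run list."""

    checklist: dict[str, dict[str, bool]] = field(default_factory=dict)
    conforming: dict[str, bool] = field(default_factory=dict)

    @property
    def run_list(self) -> list[str]:
        return [p for p, ok in self.conforming.items() if ok]


def _sequence_present(patient_dir: Path, name: str) -> bool:
    for suffix in (".nii.gz", ".nii"):
        if (patient_dir / f"{name}{suffix}").exists():
            return True
    return False


def inventory_check(patient_dirs: list[str | Path],
                    required: list[str] = list(CANONICAL_SEQUENCES),
                    report_dir: str | Path | None = None) -> InventoryReport:
    """Check each patient directory for the full required sequence set.

    Non-conforming patients are excluded from the run list; for each one a
    JSON checklist of the missing sequences is written under ``report_dir``
    (when given), mirroring the exclusion reports a study coordinator needs.
    """
    if not required:
        raise ValueError("required sequence list must be non-empty")
    report = InventoryReport()
    for pdir in patient_dirs:
        pdir = Path(pdir)
        checklist = {name: _sequence_present(pdir, name) for name in required}
        conforming = all(checklist.values())
        report.checklist[pdir.name] = checklist
        report.conforming[pdir.name] = conforming
        if not conforming and report_dir is not None:
            rdir = Path(report_dir)
            rdir.mkdir(parents=True, exist_ok=True)
            (rdir / f"{pdir.name}_missing_sequences.json").write_text(json.dumps(
                {"patient": pdir.name,
                 "missing": [n for n, ok in checklist.items() if not ok]},
                indent=2))
    return report


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def normalize_layout(raw_dir: str | Path, out_dir: str | Path,
                     naming: dict[str, str]) -> Path:
    """Copy a patient's files into the canonical vendor-independent layout.

    ``naming`` maps vendor file stems (e.g. ``AX_FLAIR_3mm``) to canonical
    sequence names.  Files are copied, never moved, byte-identical; unmapped
    extra sequences land untouched under ``extra/``.  Two sources mapping to
    one canonical name is an error naming both.  Re-running is idempotent.
    """
    raw_dir, out_dir = Path(raw_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    claimed: dict[str, Path] = {}
    for path in sorted(p for p in raw_dir.iterdir() if p.is_file()):
        stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
        ext = path.name[len(stem):] or path.suffix
        canonical = naming.get(stem)
        if canonical is None:
            dest = out_dir / "extra" / path.name
        else:
            if canonical in claimed and claimed[canonical] != path:
                raise ValueError(
                    f"name collision on {canonical!r}: {claimed[canonical]} and {path}")
            claimed[canonical] = path
            dest = out_dir / f"{canonical}{ext}"
        dest.parent.mkdir(parents=True, exist_ok=True)
        if dest.exists() and _checksum(dest) == _checksum(path):
            continue  # idempotent rerun
        shutil.copy2(path, dest)
    return out_dir
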