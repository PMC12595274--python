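"""Tab-separated table and model-document I/O.

Formats are deliberately plain: spectra and manifests are TSV with
mandatory headers, the trained classifier is a versioned YAML document.
Readers attach line numbers to parse errors and warn (rather than fail) on
markers absent from a supplied panel.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .scoring import ClassifierModel, MarkerEvidenceModel, MSIScoreResult
from .types import AlleleSpectrum, MarkerDef, SampleProfile, SampleType

logger = logging.getLogger("msiscreen")

SPECTRA_COLUMNS = ["sample_id", "marker_id", "allele_offset", "read_count"]
MANIFEST_COLUMNS = [
    "sample_id",
    "subject_id",
    "sample_type",
    "collection_day",
    "true_tumour_fraction",
]
MODEL_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed input row; message carries the file and line number."""


def write_spectra_table(profiles: Sequence[SampleProfile], path) -> None:
    """Write long-format spectra TSV (one row per sample/marker/offset)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SPECTRA_COLUMNS)
        for profile in profiles:
            for marker_id in profile.marker_ids:
                spec = profile.spectra[marker_id]
                for offset in sorted(spec.counts):
                    w.writerow(
                        [profile.sample_id, marker_id, offset, spec.counts[offset]]
                    )


def write_manifest(profiles: Sequence[SampleProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for p in profiles:
            tf = "" if p.true_tumour_fraction is None else p.true_tumour_fraction
            w.writerow(
                [p.sample_id, p.subject_id, p.sample_type.value, p.collection_day, tf]
            )


def read_spectra_table(
    path,
    panel: Optional[Sequence[MarkerDef]] = None,
    manifest: Optional[dict[str, dict]] = None,
) -> list[SampleProfile]:
    """Assemble SampleProfiles from a spectra TSV.

    Unknown markers (when a panel is given) are ignored with a warning.
    Sample metadata defaults to a urine sample at day 0 unless a manifest
    mapping ``sample_id -> fields`` is supplied.
    """
    known = None if panel is None else {m.marker_id for m in panel}
    per_sample: dict[str, dict[str, dict[int, int]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            warnings.warn(f"{path}: empty spectra table", stacklevel=2)
            return []
        if header != SPECTRA_COLUMNS:
            raise ParseError(
                f"{path}:1: expected header {SPECTRA_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            sample_id, marker_id = row[0], row[1]
            try:
                offset = int(row[2])
                count = int(row[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative read count {count}")
            if known is not None and marker_id not in known:
                warnings.warn(
                    f"{path}:{lineno}: marker {marker_id!r} not in panel; ignored",
                    stacklevel=2,
                )
                logger.warning("ignored unknown marker %s at line %d", marker_id, lineno)
                continue
            if sample_id not in per_sample:
                per_sample[sample_id] = {}
                order.append(sample_id)
            per_sample[sample_id].setdefault(marker_id, {})
            per_sample[sample_id][marker_id][offset] = (
                per_sample[sample_id][marker_id].get(offset, 0) + count
            )
    profiles = []
    for sample_id in order:
        meta = (manifest or {}).get(sample_id, {})
        tf = meta.get("true_tumour_fraction")
        profiles.append(
            SampleProfile(
                sample_id=sample_id,
                subject_id=meta.get("subject_id", sample_id),
                sample_type=SampleType(meta.get("sample_type", "urine")),
                collection_day=int(meta.get("collection_day", 0)),
                spectra={
                    m: AlleleSpectrum(marker_id=m, counts=counts)
                    for m, counts in per_sample[sample_id].items()
                },
                true_tumour_fraction=None if tf in (None, "") else float(tf),
            )
        )
    return profiles


def read_manifest(path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            if row.get("sample_id") in (None, ""):
                raise ParseError(f"{path}:{lineno}: missing sample_id")
            out[row["sample_id"]] = row
    return out


def write_model(model: ClassifierModel, path, *, seed: Optional[int] = None) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "seed": seed,
        "score_scale": model.score_scale,
        "qc_min_depth": model.qc_min_depth,
        "qc_min_markers": model.qc_min_markers,
        "markers": {
            mid: {
                "msih_alpha": m.msih_alpha,
                "msih_beta": m.msih_beta,
                "mss_alpha": m.mss_alpha,
                "mss_beta": m.mss_beta,
                "pseudocount": m.pseudocount,
            }
            for mid, m in sorted(model.markers.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path) -> ClassifierModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ParseError(
            f"{path}: unsupported model schema {doc.get('schema_version')!r}"
        )
    markers = {
        mid: MarkerEvidenceModel(marker_id=mid, **params)
        for mid, params in doc["markers"].items()
    }
    return ClassifierModel(
        markers=markers,
        score_scale=doc["score_scale"],
        qc_min_depth=doc["qc_min_depth"],
        qc_min_markers=doc["qc_min_markers"],
    )


def write_score_table(results: Sequence[MSIScoreResult], path, *, seed=None) -> None:
    """Per-sample score summary TSV (plus provenance comment lines)."""
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_id", "msi_score", "call", "borderline", "qc_pass", "markers_used"]
        )
        for r in results:
            w.writerow(
                [
                    r.sample_id,
                    "" if r.msi_score is None else f"{r.msi_score:.4f}",
                    "" if r.call is None else r.call.value,
                    int(r.borderline),
                    int(r.qc_pass),
                    r.markers_used,
                ]
            )


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
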