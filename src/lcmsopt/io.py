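"""Readers and writers: mzML (centroided MS1), the peak-table CSV dialect, JSON.

The mzML support is deliberately narrow: centroided MS1 spectra with
uncompressed or zlib-compressed 32/64-bit float arrays, which covers the
files this package writes and the common msconvert output for MS1-only data.
Profile-mode spectra are rejected, since every downstream step assumes
centroid sticks.
"""
from __future__ import annotations

import base64
import json
import zlib
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from lxml import etree

from .model import (
    CentroidScan,
    EmptyInputError,
    FormatError,
    Peak,
    Run,
    RunSet,
    SchemaError,
)

__all__ = [
    "read_mzml",
    "write_mzml",
    "write_runset_mzml",
    "read_peaks_csv",
    "write_peaks_csv",
    "read_peaklists_csv",
    "write_groups_csv",
    "to_json",
]

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS accessions we interpret
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cvparams(elem) -> dict[str, str]:
    out = {}
    for cv in elem.iter(f"{{{_NS}}}cvParam"):
        out[cv.get("accession")] = cv
    return out


def _decode_binary(bda) -> np.ndarray:
    params = _cvparams(bda)
    text_elem = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(text_elem.text or "")
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    if _ACC_F64 in params:
        return np.frombuffer(raw, dtype="<f8").astype(float)
    if _ACC_F32 in params:
        return np.frombuffer(raw, dtype="<f4").astype(float)
    raise FormatError("binary array with unsupported value encoding (need 32- or 64-bit float)")


def read_mzml(path: str | Path) -> Run:
    """Read a centroided MS1 mzML file into a :class:`Run`.

    Scans are re-sorted by retention time if stored out of order; retention
    times are converted to seconds.  Profile-mode spectra raise
    :class:`FormatError`; a file without MS1 spectra raises
    :class:`EmptyInputError`.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"{path}: not a readable mzML file ({exc})") from exc
    root = tree.getroot()
    if etree.QName(root).localname == "indexedmzML":
        inner = root.find(f"{{{_NS}}}mzML")
        if inner is None:
            raise FormatError(f"{path}: indexedmzML without inner mzML element")
        root = inner
    if etree.QName(root).localname != "mzML":
        raise FormatError(f"{path}: root element is not mzML")

    run_elem = root.find(f"{{{_NS}}}run")
    run_id = run_elem.get("id") if run_elem is not None else path.stem

    scans: list[CentroidScan] = []
    for spec in root.iter(f"{{{_NS}}}spectrum"):
        params = _cvparams(spec)
        level = params.get(_ACC_MS_LEVEL)
        if level is not None and level.get("value") not in ("1", ""):
            continue
        if _ACC_PROFILE in params:
            raise FormatError(f"{path}: spectrum {spec.get('id')!r} is profile mode; centroided data required")

        rt = None
        for scan_el in spec.iter(f"{{{_NS}}}scan"):
            p = _cvparams(scan_el)
            if _ACC_SCAN_START in p:
                cv = p[_ACC_SCAN_START]
                rt = float(cv.get("value"))
                if (cv.get("unitName") or "").lower().startswith("minute"):
                    rt *= 60.0
                break
        if rt is None:
            raise FormatError(f"{path}: spectrum {spec.get('id')!r} lacks a scan start time")

        mz = inten = None
        for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
            p = _cvparams(bda)
            if _ACC_MZ_ARRAY in p:
                mz = _decode_binary(bda)
            elif _ACC_INT_ARRAY in p:
                inten = _decode_binary(bda)
        if mz is None or inten is None:
            raise FormatError(f"{path}: spectrum {spec.get('id')!r} lacks m/z or intensity array")
        order = np.argsort(mz, kind="stable")
        scans.append(CentroidScan(rt=rt, mz_values=mz[order], intensities=inten[order]))

    if not scans:
        raise EmptyInputError(f"{path}: no MS1 spectra found")
    scans.sort(key=lambda s: s.rt)
    return Run(run_id=run_id or path.stem, scans=scans)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a :class:`Run` as a minimal centroided-MS1 mzML file."""
    path = Path(path)
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<mzML xmlns="{_NS}" version="1.1.0">\n'
        '  <cvList count="2">\n'
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '    <cv id="UO" fullName="Unit Ontology" '
        'URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>\n'
        "  </cvList>\n"
        f'  <run id="{run.run_id}">\n'
        f'    <spectrumList count="{run.n_scans}">\n'
    ]
    for i, scan in enumerate(run.scans):
        bmz, bint = _b64(scan.mz_values), _b64(scan.intensities)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.n_centroids}">\n'
            f'        <cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="1"/>\n'
            f'        <cvParam cvRef="MS" accession="{_ACC_CENTROID}" name="centroid spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
            '        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(bmz)}">\n'
            f'            <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="{_ACC_NOCOMP}" name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="{_ACC_MZ_ARRAY}" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f"            <binary>{bmz}</binary>\n"
            "          </binaryDataArray>\n"
            f'          <binaryDataArray encodedLength="{len(bint)}">\n'
            f'            <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="{_ACC_NOCOMP}" name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="{_ACC_INT_ARRAY}" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
            f"            <binary>{bint}</binary>\n"
            "          </binaryDataArray>\n"
            "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts))


def write_runset_mzml(runset: RunSet, directory: str | Path) -> list[Path]:
    """Write every run of a run set as ``<run_id>.mzML`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runset:
        p = directory / f"{run.run_id}.mzML"
        write_mzml(run, p)
        paths.append(p)
    return paths


PEAK_COLUMNS = ["run_id", "mz", "mzmin", "mzmax", "rt", "rtmin", "rtmax", "intensity"]


def write_peaks_csv(peaks: Iterable[Peak], path: str | Path) -> None:
    rows = [
        [p.run_id, p.mz, p.mzmin, p.mzmax, p.rt, p.rtmin, p.rtmax, p.intensity] for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_peaks_csv(path: str | Path) -> list[Peak]:
    """Read the package's peak-table CSV dialect; validates every row."""
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        peak = Peak(
            run_id=str(row.run_id),
            mz=float(row.mz),
            mzmin=float(row.mzmin),
            mzmax=float(row.mzmax),
            rt=float(row.rt),
            rtmin=float(row.rtmin),
            rtmax=float(row.rtmax),
            intensity=float(row.intensity),
        )
        peak.validate(where=f"{path} row {i}")
        peaks.append(peak)
    return peaks


def read_peaklists_csv(path: str | Path) -> dict[str, list[Peak]]:
    """Read a peak CSV and split it into per-run peak lists (insertion order)."""
    peaklists: dict[str, list[Peak]] = {}
    for p in read_peaks_csv(path):
        peaklists.setdefault(p.run_id, []).append(p)
    return peaklists


def write_groups_csv(groups, path: str | Path) -> None:
    """Write feature groups: one row per member peak, keyed by group_id."""
    rows = []
    for gid, g in enumerate(groups):
        for p in g.member_peaks:
            rows.append(
                [gid, g.mz_center, g.median_rt, p.run_id, p.mz, p.rt, p.rtmin, p.rtmax, p.intensity]
            )
    cols = ["group_id", "mz_center", "median_rt", "run_id", "mz", "rt", "rtmin", "rtmax", "intensity"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.10g")


def _json_default(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def to_json(obj, path: str | Path | None = None, **kwargs) -> str:
    """Serialize result objects (dataclasses, arrays) to JSON text or a file."""
    text = json.dumps(obj, default=_json_default, indent=2, sort_keys=True, **kwargs)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
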