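"""Minimal mzML 1.1.0 serialization for centroided positive-mode runs.

The writer emits a plain (non-indexed) mzML document with one MS1 centroid
spectrum per scan, retention time in minutes, and uncompressed base64
little-endian float64 m/z and intensity arrays.  The reader parses the
same subset with the standard library's ElementTree, so a written file
round-trips bit-faithfully; files are also readable by standard mzML
tooling (Bioconductor's mzR serves as an independent cross-reader in the
test-suite).
"""

from __future__ import annotations

import base64
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SyntheticRun

__all__ = ["write_mzml", "read_mzml"]

_NS = "http://psi.hupo.org/ms/mzml"

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="{ns}" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="argentms" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="argentms"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="argentms">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


def _spectrum_xml(index: int, rt_min: float, mz: np.ndarray, inten: np.ndarray) -> str:
    n = len(mz)
    mz_b64, int_b64 = _b64(mz), _b64(inten)
    return f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def write_mzml(run: "SyntheticRun", path: str | Path) -> Path:
    """Serialize a run to mzML; returns the written path."""
    path = Path(path)
    run_id = str(run.metadata.get("run_id", "synthetic_run"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(ns=_NS, run_id=run_id, count=len(run.scans)))
        for i, scan in enumerate(run.scans):
            fh.write(_spectrum_xml(i, float(scan.rt), scan.mz, scan.intensity))
        fh.write(_FOOTER)
    return path


def read_mzml(path: str | Path) -> "SyntheticRun":
    """Parse centroid MS1 spectra from mzML into a run object.

    Retention times are converted to minutes regardless of the stored unit.
    """
    from .simulate import Scan, SyntheticRun

    tree = ET.parse(str(path))
    root = tree.getroot()
    ns = {"m": _NS}
    scans = []
    for spec in root.iterfind(".//m:spectrum", ns):
        rt = None
        for cv in spec.iterfind(".//m:scan/m:cvParam", ns):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iterfind(".//m:binaryDataArray", ns):
            name = None
            for cv in bda.iterfind("m:cvParam", ns):
                if cv.get("accession") in ("MS:1000514", "MS:1000515"):
                    name = cv.get("name")
                if cv.get("accession") not in (
                    "MS:1000523",  # 64-bit float
                    "MS:1000576",  # no compression
                    "MS:1000514",
                    "MS:1000515",
                ):
                    continue
            binary = bda.find("m:binary", ns)
            data = base64.b64decode(binary.text or "")
            if name:
                arrays[name] = np.frombuffer(data, dtype="<f8").copy()
        if rt is None:
            raise ValueError(f"spectrum {spec.get('id')} lacks a scan start time")
        scans.append(
            Scan(
                rt=rt,
                mz=arrays.get("m/z array", np.empty(0)),
                intensity=arrays.get("intensity array", np.empty(0)),
            )
        )
    scans.sort(key=lambda s: s.rt)
    return SyntheticRun(scans=scans, metadata={"source": str(path)})
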