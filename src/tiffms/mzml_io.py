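"""Reading, writing and FAIMS-demultiplexing of centroided MS1 mzML runs.

A FAIMS-equipped acquisition cycles through several compensation voltages
(CVs) within one LC-MS run; downstream matching must only ever compare
spectra acquired at the same CV.  This module reads centroided mzML,
exposes the per-spectrum CV (PSI-MS cvParam MS:1001581), splits a multi-CV
run into single-CV sub-runs, and assigns the non-adjacent fraction numbers
(1, 3, 5, ...) that keep match-between-runs from crossing CV boundaries.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

logger = logging.getLogger("tiffms")

#: Sentinel key for spectra that carry no FAIMS CV annotation.
NO_CV = None

#: CVs are compared after rounding to this resolution (volts) to absorb
#: floating-point encoding noise in mzML files.
CV_RESOLUTION = 0.1


class MzmlFormatError(ValueError):
    """Raised for unreadable, truncated, or profile-mode input."""


def round_cv(cv: float | None) -> float | None:
    """Round a compensation voltage to the comparison resolution (0.1 V)."""
    if cv is None:
        return None
    return round(float(cv) / CV_RESOLUTION) * CV_RESOLUTION


@dataclass
class Ms1Spectrum:
    """One centroided MS1 scan.

    Peaks are stored as parallel arrays sorted strictly ascending in m/z.
    ``cv`` (volts) and ``injection_time`` (ms) are optional metadata.
    """

    scan_id: str
    rt: float                      # minutes
    mz: np.ndarray                 # Th, strictly ascending
    intensity: np.ndarray          # counts, >= 0
    cv: float | None = None        # volts
    injection_time: float | None = None  # milliseconds

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt < 0:
            raise ValueError(f"negative retention time for scan {self.scan_id!r}")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"peaks not strictly ascending in m/z (scan {self.scan_id!r})")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in scan {self.scan_id!r}")
        self.cv = round_cv(self.cv)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class Run:
    """An ordered collection of MS1 spectra from one LC-MS analysis."""

    run_id: str
    spectra: list[Ms1Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: (s.rt, s.scan_id))

    @property
    def cv_set(self) -> set[float]:
        return {s.cv for s in self.spectra if s.cv is not None}

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _params_by_accession(element) -> dict[str, tuple[str, str | None]]:
    """All cvParams under an element: accession -> (value, unit name)."""
    out = {}
    for cvp in element.iter():
        if _local(cvp.tag) == "cvParam":
            out[cvp.get("accession")] = (cvp.get("value", ""), cvp.get("unitName"))
    return out


def _decode_binary_array(bda, spectrum_id: str, path: str) -> tuple[str | None, np.ndarray]:
    params = _params_by_accession(bda)
    kind = None
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    binary = None
    for child in bda:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    if binary is None:
        raise MzmlFormatError(
            f"truncated binaryDataArray in spectrum {spectrum_id!r} of {path}")
    raw = base64.b64decode(binary)
    if "MS:1000574" in params:          # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(element, path: str) -> Ms1Spectrum | None:
    spec_params = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            spec_params[child.get("accession")] = (child.get("value", ""), None)
    scan_params: dict = {}
    arrays: dict[str, np.ndarray] = {}
    for child in element.iter():
        tag = _local(child.tag)
        if tag == "scan" and not scan_params:
            scan_params = _params_by_accession(child)
        elif tag == "binaryDataArray":
            kind, values = _decode_binary_array(child, element.get("id", "?"), path)
            if kind:
                arrays[kind] = values
    level = spec_params.get("MS:1000511", ("", None))[0]
    if level and int(level) != 1:
        return None
    if "MS:1000128" in spec_params:     # profile spectrum
        raise MzmlFormatError(
            f"centroided input required: spectrum {element.get('id')!r} "
            f"in {path} is profile-mode")
    rt, rt_unit = scan_params.get("MS:1000016", ("0", "minute"))
    rt = float(rt) / (60.0 if rt_unit in ("second", "seconds") else 1.0)
    cv = None
    for block in (spec_params, scan_params):
        if "MS:1001581" in block:
            cv = float(block["MS:1001581"][0])
    it = scan_params.get("MS:1000927")
    if "mz" not in arrays or "intensity" not in arrays:
        raise MzmlFormatError(
            f"spectrum {element.get('id')!r} in {path} lacks m/z or intensity array")
    return Ms1Spectrum(
        scan_id=str(element.get("id", f"index={element.get('index')}")),
        rt=rt, mz=arrays["mz"], intensity=arrays["intensity"],
        cv=cv, injection_time=None if it is None else float(it[0]))


def read_run(path, run_id: str | None = None) -> Run:
    """Read all centroided MS1 spectra of an mzML file into a :class:`Run`.

    MS2+ spectra are ignored (the method is MS1-centric).  Profile-mode
    spectra raise :class:`MzmlFormatError`: centroided input is required.
    Handles 32/64-bit float arrays with or without zlib compression; the
    FAIMS CV is taken from cvParam MS:1001581 at spectrum or scan level.
    """
    path = str(path)
    spectra: list[Ms1Spectrum] = []
    try:
        for _, element in etree.iterparse(path,
                                          tag=(f"{{{_MZML_NS}}}spectrum", "spectrum")):
            spec = _parse_spectrum(element, path)
            if spec is not None:
                spectra.append(spec)
            element.clear(keep_tail=True)
    except MzmlFormatError:
        raise
    except (etree.XMLSyntaxError, KeyError, ValueError, OSError) as exc:
        raise MzmlFormatError(f"cannot read mzML file {path}: {exc}") from exc
    if run_id is None:
        run_id = path.rsplit("/", 1)[-1]
        for suffix in (".mzML", ".mzml"):
            if run_id.endswith(suffix):
                run_id = run_id[: -len(suffix)]
    return Run(run_id=run_id, spectra=spectra)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def split_by_cv(run: Run) -> dict[float | None, Run]:
    """Split a multi-CV run into single-CV sub-runs.

    Spectra lacking a CV annotation are grouped under the ``NO_CV`` sentinel
    key (with a warning when the run is only partially annotated).  Spectrum
    counts are conserved and RT order preserved within each group.
    """
    groups: dict[float | None, list[Ms1Spectrum]] = {}
    for spec in run.spectra:
        groups.setdefault(spec.cv, []).append(spec)
    if NO_CV in groups and len(groups) > 1:
        logger.warning(
            "run %s: %d spectra lack a FAIMS CV in a partially annotated run; "
            "grouped under the no-CV sentinel",
            run.run_id, len(groups[NO_CV]),
        )
    out = {}
    for cv, specs in groups.items():
        tag = "nocv" if cv is None else f"cv{cv:g}"
        out[cv] = Run(run_id=f"{run.run_id}.{tag}", spectra=specs)
    return out


def assign_fraction_numbers(cvs: list[float]) -> dict[float, int]:
    """Assign odd ("non-adjacent") fraction numbers 1, 3, 5, ... in CV order.

    Match-between-runs engines only align runs whose fraction numbers differ
    by at most 1; spacing the per-CV files two apart guarantees feature
    matching only occurs between files with the same CV.
    """
    rounded = [round_cv(cv) for cv in cvs]
    if len(set(rounded)) != len(rounded):
        raise ValueError(f"duplicate compensation voltages in {cvs}")
    return {cv: 2 * i + 1 for i, cv in enumerate(rounded)}


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cvparam(parent, accession, name, value="", unit=None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    if unit is not None:
        attrs.update(unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2])
    etree.SubElement(parent, "cvParam", attrs)


def _binary_array(parent, values, accession, name, unit=None):
    data = struct.pack(f"<{len(values)}d", *values)
    b64 = base64.b64encode(data).decode("ascii")
    el = etree.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(b64))})
    _cvparam(el, "MS:1000523", "64-bit float")
    _cvparam(el, "MS:1000576", "no compression")
    _cvparam(el, accession, name, unit=unit)
    etree.SubElement(el, "binary").text = b64


def write_run(run: Run, path) -> None:
    """Write a :class:`Run` as centroided MS1 mzML.

    Arrays are encoded as uncompressed 64-bit floats; the FAIMS CV is carried
    per spectrum as cvParam MS:1001581 so that ``read_run`` round-trips all
    modeled fields.
    """
    root = etree.Element("mzML", {"version": "1.1.0"}, nsmap={None: _MZML_NS})
    cvlist = etree.SubElement(root, "cvList", {"count": "2"})
    etree.SubElement(cvlist, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    etree.SubElement(cvlist, "cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    run_el = etree.SubElement(root, "run", {"id": run.run_id})
    slist = etree.SubElement(run_el, "spectrumList", {"count": str(len(run.spectra))})
    for i, spec in enumerate(run.spectra):
        sp = etree.SubElement(slist, "spectrum", {
            "index": str(i), "id": spec.scan_id,
            "defaultArrayLength": str(spec.mz.size)})
        _cvparam(sp, "MS:1000579", "MS1 spectrum")
        _cvparam(sp, "MS:1000511", "ms level", 1)
        _cvparam(sp, "MS:1000127", "centroid spectrum")
        if spec.cv is not None:
            _cvparam(sp, "MS:1001581", "FAIMS compensation voltage", f"{spec.cv:g}")
        scan_list = etree.SubElement(sp, "scanList", {"count": "1"})
        _cvparam(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cvparam(scan, "MS:1000016", "scan start time", repr(spec.rt),
                 unit=("UO", "UO:0000031", "minute"))
        if spec.injection_time is not None:
            _cvparam(scan, "MS:1000927", "ion injection time",
                     repr(spec.injection_time),
                     unit=("UO", "UO:0000028", "millisecond"))
        alist = etree.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        _binary_array(alist, spec.mz, "MS:1000514", "m/z array",
                      unit=("MS", "MS:1000040", "m/z"))
        _binary_array(alist, spec.intensity, "MS:1000515", "intensity array",
                      unit=("MS", "MS:1000131", "number of detector counts"))
    tree = etree.ElementTree(root)
    try:
        tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    except OSError as exc:
        raise OSError(f"cannot write mzML to {path}: {exc}") from exc
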