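"""COMBINE (OMEX) archive reading, writing and structural checks.

A COMBINE archive is a zip file with a ``manifest.xml`` member that lists
every file in the archive together with a format identifier URI and a
``master`` flag marking the entry point (here: the SED-ML document to
execute).  Writes are byte-deterministic — entries are ordered by location
and zip timestamps are pinned — so identical archives produce identical
files, which makes golden-file and round-trip testing possible.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from typing import BinaryIO, Dict, List, Union

from lxml import etree

from ._errors import SimexError

MANIFEST_NS = "http://identifiers.org/combine.specifications/omex-manifest"

FORMAT_OMEX = "http://identifiers.org/combine.specifications/omex"
FORMAT_OMEX_MANIFEST = "http://identifiers.org/combine.specifications/omex-manifest"
FORMAT_SEDML = "http://identifiers.org/combine.specifications/sed-ml"
FORMAT_SBML = "http://identifiers.org/combine.specifications/sbml"
FORMAT_BOOLNET = "http://purl.org/NET/mediatypes/text/x-boolnet"

# zip members carry this fixed timestamp so byte output is reproducible
_FIXED_DATE = (1980, 1, 1, 0, 0, 0)


def is_sedml_format(uri: str) -> bool:
    low = uri.lower()
    return "sed-ml" in low or "sedml" in low


def is_sbml_format(uri: str) -> bool:
    return "sbml" in uri.lower()


def is_boolnet_format(uri: str) -> bool:
    low = uri.lower()
    return "boolnet" in low or "bnet" in low


@dataclass(frozen=True)
class ContentEntry:
    """One manifest line: an archive-relative location, its format URI, master flag."""

    location: str
    format: str
    is_master: bool = False

    def check(self) -> None:
        loc = self.location
        if not loc:
            raise SimexError("INVARIANT_VIOLATION", "entry location is empty")
        if loc != "." and (loc.startswith("/") or ".." in loc.split("/") or "\\" in loc):
            raise SimexError("INVARIANT_VIOLATION", f"bad entry location {loc!r}")
        if not self.format:
            raise SimexError("INVARIANT_VIOLATION", f"entry {loc!r} has empty format")


@dataclass
class CombineArchive:
    """In-memory archive: manifest entries plus the member payload bytes."""

    entries: List[ContentEntry] = field(default_factory=list)
    payload: Dict[str, bytes] = field(default_factory=dict)

    def check(self) -> None:
        for entry in self.entries:
            entry.check()
        locations = [e.location for e in self.entries]
        if len(set(locations)) != len(locations):
            raise SimexError("INVARIANT_VIOLATION", "duplicate entry locations")
        masters = [e for e in self.entries if e.is_master]
        if len(masters) > 1:
            raise SimexError("INVARIANT_VIOLATION", "more than one master entry")
        if sum(1 for e in self.entries if e.location == ".") > 1:
            raise SimexError("INVARIANT_VIOLATION", "more than one '.' self-entry")
        for entry in self.entries:
            if entry.location != "." and entry.location not in self.payload:
                raise SimexError(
                    "ENTRY_FILE_MISSING",
                    f"manifest entry {entry.location!r} has no payload",
                )

    def get_entry(self, location: str) -> ContentEntry:
        for entry in self.entries:
            if entry.location == location:
                return entry
        raise SimexError("ENTRY_FILE_MISSING", f"no entry at {location!r}")


def _normalize_location(location: str) -> str:
    if location.startswith("./") and len(location) > 2:
        return location[2:]
    return location


def read_archive(path: Union[str, BinaryIO]) -> CombineArchive:
    """Read a COMBINE archive from a zip file path or binary stream."""
    try:
        zf = zipfile.ZipFile(path, "r")
    except (zipfile.BadZipFile, FileNotFoundError, IsADirectoryError) as exc:
        raise SimexError("NOT_A_ZIP", f"cannot open archive: {exc}")
    with zf:
        names = set(zf.namelist())
        if "manifest.xml" not in names:
            raise SimexError("MANIFEST_MISSING", "archive has no manifest.xml member")
        try:
            root = etree.fromstring(zf.read("manifest.xml"))
        except etree.XMLSyntaxError as exc:
            raise SimexError("MANIFEST_MALFORMED", f"manifest.xml is not valid XML: {exc}")
        if etree.QName(root).localname != "omexManifest":
            raise SimexError("MANIFEST_MALFORMED", "manifest root is not omexManifest")
        entries: List[ContentEntry] = []
        for child in root:
            if not isinstance(child.tag, str):
                continue
            if etree.QName(child).localname != "content":
                raise SimexError(
                    "MANIFEST_MALFORMED",
                    f"unknown manifest element {etree.QName(child).localname!r}",
                )
            location = child.get("location")
            fmt = child.get("format")
            if location is None or fmt is None:
                raise SimexError("MANIFEST_MALFORMED", "content element lacks location/format")
            master = (child.get("master") or "false").lower() == "true"
            entries.append(ContentEntry(_normalize_location(location), fmt, master))
        payload: Dict[str, bytes] = {}
        for entry in entries:
            if entry.location in (".", "manifest.xml"):
                continue
            if entry.location not in names:
                raise SimexError(
                    "ENTRY_FILE_MISSING",
                    f"manifest lists {entry.location!r} which is absent from the zip",
                )
            payload[entry.location] = zf.read(entry.location)
    archive = CombineArchive(entries=entries, payload=payload)
    archive.check()
    return archive


def _manifest_bytes(entries: List[ContentEntry]) -> bytes:
    root = etree.Element(f"{{{MANIFEST_NS}}}omexManifest", nsmap={None: MANIFEST_NS})
    for entry in sorted(entries, key=lambda e: e.location):
        el = etree.SubElement(root, f"{{{MANIFEST_NS}}}content")
        el.set("location", entry.location)
        el.set("format", entry.format)
        if entry.is_master:
            el.set("master", "true")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def write_archive(
    archive: CombineArchive, path: Union[str, BinaryIO], _check: bool = True
) -> None:
    """Write a deterministic zip: manifest plus payload, sorted, fixed timestamps."""
    entries = list(archive.entries)
    if not any(e.location == "." for e in entries):
        entries = [ContentEntry(".", FORMAT_OMEX)] + entries
    staged = CombineArchive(entries=entries, payload=archive.payload)
    if _check:
        staged.check()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("manifest.xml", date_time=_FIXED_DATE)
        zf.writestr(info, _manifest_bytes(entries))
        for location in sorted(archive.payload):
            info = zipfile.ZipInfo(location, date_time=_FIXED_DATE)
            zf.writestr(info, archive.payload[location])


def archive_to_bytes(archive: CombineArchive, _check: bool = True) -> bytes:
    buffer = io.BytesIO()
    write_archive(archive, buffer, _check=_check)
    return buffer.getvalue()


def archive_from_bytes(data: bytes) -> CombineArchive:
    return read_archive(io.BytesIO(data))


def list_master_sedml(archive: CombineArchive) -> List[str]:
    """Locations of the SED-ML documents to execute.

    If any SED-ML entry is flagged master, only master entries are returned;
    otherwise every SED-ML entry is returned.  Sorted by location.
    """
    sedml = [e for e in archive.entries if e.location != "." and is_sedml_format(e.format)]
    masters = [e for e in sedml if e.is_master]
    chosen = masters if masters else sedml
    return sorted(e.location for e in chosen)
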