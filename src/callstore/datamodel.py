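"""Core domain types for sample-first genotype storage.

A *genotyping protocol* groups everything that describes one genotyping
event: the VCF header metadata, the marker catalogue (one marker
information object, "MIO", per marker — the first nine VCF columns) and
the reference genome it was called against.  A *callset* holds one
sample's genotype calls for every marker of a protocol, keyed by marker
name — the transpose of the VCF's marker-first layout.

On upload two derived keys are added to every call:

``NT``
    the nucleotide rendering of the ``GT`` allele indices, comma-joined
    in GT order (index 0 is the reference allele, index *i* > 0 is the
    *i*-th alternate allele);
``DS``
    the dosage, by default the count of *reference* calls in ``GT``
    (``0/0`` -> 2, ``1/1`` -> 0 for a diploid), or ``NA`` when any
    allele slot is missing.  Most downstream tools count alternate
    alleles instead, so the convention is switchable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

__all__ = [
    "NA",
    "OBSERVATION_UNIT_TYPES",
    "GTFormatError",
    "AlleleRangeError",
    "MarkerInfo",
    "GenotypingProtocol",
    "GenotypeCall",
    "SampleCallset",
    "SizeModel",
    "ValidationReport",
    "split_gt",
    "derive_dosage",
    "derive_nt",
    "build_genotype_call",
    "validate_protocol",
    "max_markers",
    "estimate_bytes_per_marker",
]

#: Missing-data token used for dosages and matrix cells.
NA = "NA"

#: Controlled-vocabulary types an observation unit (the genotyped entity)
#: may have.
OBSERVATION_UNIT_TYPES = frozenset({"tissue_sample", "plant", "plot", "accession"})

Dosage = Union[int, float, str]


class GTFormatError(ValueError):
    """A GT string is malformed (mixed separators, bad allele token)."""


class AlleleRangeError(ValueError):
    """A GT allele index exceeds the number of alternate alleles."""


def split_gt(gt: str) -> tuple[list[str], str]:
    """Split a GT string into allele slots and its separator kind.

    Returns ``(slots, sep)`` where ``sep`` is ``"/"`` (unphased),
    ``"|"`` (phased) or ``""`` for a haploid single-slot call.  Raises
    :class:`GTFormatError` for mixed separators or tokens that are
    neither a non-negative integer nor ``"."``.
    """
    if not gt:
        raise GTFormatError("empty GT string")
    has_slash = "/" in gt
    has_pipe = "|" in gt
    if has_slash and has_pipe:
        raise GTFormatError(f"mixed phase separators in GT {gt!r}")
    sep = "/" if has_slash else ("|" if has_pipe else "")
    slots = gt.split(sep) if sep else [gt]
    for tok in slots:
        if tok == ".":
            continue
        if not tok.isdigit():
            raise GTFormatError(f"invalid allele token {tok!r} in GT {gt!r}")
    return slots, sep


def derive_dosage(gt: str, convention: str = "reference") -> Dosage:
    """Dosage of a GT string: count of reference (``"0"``) allele slots.

    Returns ``"NA"`` if any slot is missing (``.``).  With
    ``convention="alternate"`` the non-reference slots are counted
    instead, which is what most association/prediction tools expect.
    Phasing (``/`` vs ``|``) does not affect the result.

    >>> derive_dosage("0/0"), derive_dosage("1/1"), derive_dosage("./.")
    (2, 0, 'NA')
    """
    slots, _ = split_gt(gt)
    if any(s == "." for s in slots):
        return NA
    if convention == "reference":
        return sum(1 for s in slots if s == "0")
    if convention == "alternate":
        return sum(1 for s in slots if s != "0")
    raise ValueError(f"unknown dosage convention {convention!r}")


def derive_nt(gt: str, ref: str, alt: Iterable[str]) -> str:
    """Nucleotide string for a GT: one allele per slot, comma-joined.

    Index 0 maps to ``ref``, index *i* > 0 to ``alt[i-1]``; order follows
    the GT slots for both phased and unphased calls.  Missing slots
    render as ``"."``.
    """
    alt = list(alt)
    slots, _ = split_gt(gt)
    out = []
    for tok in slots:
        if tok == ".":
            out.append(".")
            continue
        idx = int(tok)
        if idx == 0:
            out.append(ref)
        elif idx <= len(alt):
            out.append(alt[idx - 1])
        else:
            raise AlleleRangeError(
                f"GT index {idx} out of range for {len(alt)} alternate allele(s)"
            )
    return ",".join(out)


@dataclass
class MarkerInfo:
    """One marker's record: the first nine VCF columns (the MIO)."""

    name: str
    chrom: str
    pos: int
    ref: str
    alt: list[str] = field(default_factory=list)
    qual: str = "."
    filter: str = "."
    info: str = "."
    format: str = "GT"
    #: Additional protocol-level marker metadata (e.g. DP/GQ summaries)
    #: serialized alongside the standard keys.
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be nonempty")
        if self.pos < 1:
            raise ValueError(f"marker {self.name}: pos must be >= 1 (got {self.pos})")
        if not self.ref:
            raise ValueError(f"marker {self.name}: ref allele must be nonempty")
        if self.ref in self.alt:
            raise ValueError(f"marker {self.name}: alt alleles must differ from ref")

    @property
    def format_keys(self) -> list[str]:
        return self.format.split(":") if self.format else []

    def to_json(self) -> dict:
        doc = {
            "name": self.name,
            "chrom": self.chrom,
            "pos": str(self.pos),
            "ref": self.ref,
            "alt": ",".join(self.alt) if self.alt else ".",
            "qual": self.qual,
            "filter": self.filter,
            "info": self.info,
            "format": self.format,
        }
        doc.update(self.extra)
        return doc

    @classmethod
    def from_json(cls, doc: Mapping) -> "MarkerInfo":
        std = {"name", "chrom", "pos", "ref", "alt", "qual", "filter", "info", "format"}
        alt = doc.get("alt", ".")
        return cls(
            name=doc["name"],
            chrom=doc["chrom"],
            pos=int(doc["pos"]),
            ref=doc["ref"],
            alt=[] if alt in (".", "") else str(alt).split(","),
            qual=str(doc.get("qual", ".")),
            filter=str(doc.get("filter", ".")),
            info=str(doc.get("info", ".")),
            format=str(doc.get("format", "GT")),
            extra={k: v for k, v in doc.items() if k not in std},
        )


@dataclass
class GenotypeCall:
    """One sample's call at one marker: GT plus derived NT/DS and any
    further FORMAT keys (AD, DP, GQ, PL, ...) kept verbatim."""

    GT: str
    NT: str = ""
    DS: Dosage = NA
    extra: dict[str, str] = field(default_factory=dict)

    @property
    def ploidy(self) -> int:
        return len(split_gt(self.GT)[0])

    @property
    def is_missing(self) -> bool:
        return any(s == "." for s in split_gt(self.GT)[0])

    def dosage_value(self) -> float:
        """DS as a float, or NaN for NA (for numeric matrices)."""
        if self.DS == NA:
            return float("nan")
        return float(self.DS)

    def to_json(self) -> dict:
        doc = {"GT": self.GT, "NT": self.NT, "DS": str(self.DS)}
        doc.update(self.extra)
        return doc

    @classmethod
    def from_json(cls, doc: Mapping) -> "GenotypeCall":
        ds: Dosage = doc.get("DS", NA)
        if isinstance(ds, str) and ds != NA:
            try:
                ds = int(ds)
            except ValueError:
                try:
                    ds = float(ds)
                except ValueError:
                    pass
        return cls(
            GT=doc["GT"],
            NT=doc.get("NT", ""),
            DS=ds,
            extra={k: v for k, v in doc.items() if k not in ("GT", "NT", "DS")},
        )


def build_genotype_call(
    format_keys: Iterable[str],
    format_values: Iterable[str],
    marker: MarkerInfo,
    convention: str = "reference",
) -> GenotypeCall:
    """Assemble a :class:`GenotypeCall` from positional FORMAT data.

    ``GT`` is stored verbatim and is mandatory.  ``NT`` and ``DS`` are
    preserved verbatim when the input provides them and derived from GT
    otherwise.  Every other key goes to ``extra`` untouched.
    """
    keys = list(format_keys)
    values = list(format_values)
    if "GT" not in keys:
        raise ValueError("FORMAT must minimally contain GT")
    # VCF permits trailing fields to be dropped; pad with "."
    if len(values) < len(keys):
        values = values + ["."] * (len(keys) - len(values))
    pairs = dict(zip(keys, values))
    gt = pairs.pop("GT")
    nt = pairs.pop("NT", None)
    ds: Dosage | None = pairs.pop("DS", None)
    if nt is None or nt == ".":
        nt = derive_nt(gt, marker.ref, marker.alt)
    if ds is None or ds == ".":
        ds = derive_dosage(gt, convention=convention)
    return GenotypeCall(GT=gt, NT=nt, DS=ds, extra=pairs)


@dataclass
class GenotypingProtocol:
    """A named genotyping event: header metadata plus marker catalogue.

    The marker catalogue is held redundantly as an ordered name list, a
    name-keyed mapping and an ordered array — mirroring the three stored
    property documents, which trade space for query flexibility.
    """

    protocol_id: str
    name: str
    description: str = ""
    reference_genome_name: str = ""
    species_name: str = ""
    sample_observation_unit_type_name: str = "accession"
    header_information_lines: list[str] = field(default_factory=list)
    marker_names: list[str] = field(default_factory=list)
    markers: dict[str, MarkerInfo] = field(default_factory=dict)
    markers_array: list[MarkerInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_observation_unit_type_name not in OBSERVATION_UNIT_TYPES:
            raise ValueError(
                "sample_observation_unit_type_name must be one of "
                f"{sorted(OBSERVATION_UNIT_TYPES)}"
            )

    def marker(self, name: str) -> MarkerInfo:
        return self.markers[name]

    def to_documents(self) -> dict[str, object]:
        """The three stored JSON documents, under their canonical keys."""
        return {
            "vcf_map_details": {
                "reference_genome_name": self.reference_genome_name,
                "species_name": self.species_name,
                "sample_observation_unit_type_name": self.sample_observation_unit_type_name,
                "header_information_lines": list(self.header_information_lines),
                "marker_names": list(self.marker_names),
            },
            "vcf_map_details_markers": {
                name: mio.to_json() for name, mio in self.markers.items()
            },
            "vcf_map_details_markers_array": [m.to_json() for m in self.markers_array],
        }

    @classmethod
    def from_documents(
        cls,
        protocol_id: str,
        name: str,
        docs: Mapping[str, object],
        description: str = "",
    ) -> "GenotypingProtocol":
        details = docs["vcf_map_details"]
        markers = {
            k: MarkerInfo.from_json(v)
            for k, v in docs["vcf_map_details_markers"].items()
        }
        array = [MarkerInfo.from_json(v) for v in docs["vcf_map_details_markers_array"]]
        return cls(
            protocol_id=protocol_id,
            name=name,
            description=description,
            reference_genome_name=details.get("reference_genome_name", ""),
            species_name=details.get("species_name", ""),
            sample_observation_unit_type_name=details.get(
                "sample_observation_unit_type_name", "accession"
            ),
            header_information_lines=list(details.get("header_information_lines", [])),
            marker_names=list(details.get("marker_names", [])),
            markers=markers,
            markers_array=array,
        )


@dataclass
class SampleCallset:
    """All of one sample's calls under one protocol, keyed by marker name."""

    sample_name: str
    protocol_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {name: call.to_json() for name, call in self.calls.items()}

    @classmethod
    def from_json(
        cls, sample_name: str, protocol_id: str, doc: Mapping
    ) -> "SampleCallset":
        return cls(
            sample_name=sample_name,
            protocol_id=protocol_id,
            calls={k: GenotypeCall.from_json(v) for k, v in doc.items()},
        )


@dataclass
class SizeModel:
    """Storage-limit arithmetic for a single JSON field.

    A relational engine caps one field at ``field_limit_bytes`` (1 GB by
    default); dividing by the serialized size of one marker's call
    object bounds how many markers one protocol can carry.
    """

    bytes_per_marker: int
    field_limit_bytes: int = 10**9

    def __post_init__(self) -> None:
        if self.bytes_per_marker <= 0 or self.field_limit_bytes <= 0:
            raise ValueError("SizeModel fields must be strictly positive")


def max_markers(m: SizeModel) -> int:
    """Largest marker count whose callset document fits in one field."""
    return m.field_limit_bytes // m.bytes_per_marker


def estimate_bytes_per_marker(callsets: Iterable[SampleCallset]) -> float:
    """Mean serialized byte length of one marker's call object.

    Averaged over all calls of all given callsets; includes the marker
    name key.  Returns 0.0 for empty input.
    """
    total = 0
    count = 0
    for cs in callsets:
        for name, call in cs.calls.items():
            total += len(json.dumps({name: call.to_json()}).encode())
            count += 1
    return total / count if count else 0.0


@dataclass
class ValidationReport:
    """Report-only result of protocol validation; never raises."""

    duplicate_marker_names: list[str] = field(default_factory=list)
    representation_mismatches: list[str] = field(default_factory=list)
    size_warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.duplicate_marker_names
            or self.representation_mismatches
            or self.size_warnings
        )

    def summary(self) -> str:
        if self.ok:
            return "protocol valid"
        parts = []
        if self.duplicate_marker_names:
            parts.append(f"duplicate markers: {self.duplicate_marker_names}")
        if self.representation_mismatches:
            parts.append(f"mismatches: {self.representation_mismatches}")
        if self.size_warnings:
            parts.append(f"size: {self.size_warnings}")
        return "; ".join(parts)


def validate_protocol(
    p: GenotypingProtocol, size_model: SizeModel | None = None
) -> ValidationReport:
    """Check the three marker representations agree and the protocol fits.

    Flags duplicated marker names, disagreements among ``marker_names``,
    ``markers`` and ``markers_array``, and — when a :class:`SizeModel`
    is supplied — a marker count exceeding what one stored field can
    hold.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for n in p.marker_names:
        if n in seen:
            report.duplicate_marker_names.append(n)
        seen.add(n)

    names = set(p.marker_names)
    map_names = set(p.markers)
    arr_names = [m.name for m in p.markers_array]
    if names != map_names:
        report.representation_mismatches.append(
            f"marker_names vs markers keys differ: "
            f"{sorted(names ^ map_names)}"
        )
    if set(arr_names) != names:
        report.representation_mismatches.append(
            f"marker_names vs markers_array differ: "
            f"{sorted(names ^ set(arr_names))}"
        )
    elif arr_names != p.marker_names:
        report.representation_mismatches.append(
            "markers_array order differs from marker_names order"
        )

    if size_model is not None:
        limit = max_markers(size_model)
        if len(p.marker_names) > limit:
            report.size_warnings.append(
                f"{len(p.marker_names)} markers exceed the estimated "
                f"per-field capacity of {limit} markers "
                f"({size_model.bytes_per_marker} B/marker, "
                f"{size_model.field_limit_bytes} B limit)"
            )
    return report
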