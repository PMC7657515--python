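"""VCF reading/writing and the marker-first <-> sample-first transpose.

VCF files are *marker first*: one row per marker, one column per sample.
The storage model is *sample first*: one document per sample, keyed by
marker.  The two layouts are mutual transposes, so loading and VCF
export each involve a transposition.  Both writers here are generators
that emit the file line-by-line, so exporting from sample-first storage
retains only one marker row of state at a time.

Positions are 1-based inclusive throughout, as in VCF; no internal
coordinate conversion happens anywhere in the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from .datamodel import (
    NA,
    GenotypeCall,
    GenotypingProtocol,
    MarkerInfo,
    SampleCallset,
    build_genotype_call,
)

__all__ = [
    "VcfFormatError",
    "MarkerFirstBlock",
    "read_vcf",
    "build_protocol",
    "transpose_to_sample_first",
    "transpose_to_marker_first",
    "write_vcf",
    "write_dosage_matrix",
]

_FIXED_COLS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT")


class VcfFormatError(ValueError):
    """The input does not parse as VCF 4.x."""


@dataclass
class MarkerFirstBlock:
    """A parsed VCF body in its native row-per-marker layout.

    ``cells[i][j]`` is the raw (still colon-delimited) FORMAT value
    string of sample *j* at marker *i*, exactly as it appeared in the
    file.
    """

    markers: list[MarkerInfo] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)
    cells: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, row in enumerate(self.cells):
            if len(row) != len(self.sample_names):
                raise ValueError(
                    f"cells row {i} has {len(row)} entries for "
                    f"{len(self.sample_names)} samples"
                )


def _as_line_iter(source: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, str):
        return iter(io.StringIO(source))
    return iter(source)


def read_vcf(source: str | IO[str] | Iterable[str]) -> tuple[list[str], MarkerFirstBlock]:
    """Parse VCF text into header lines and a :class:`MarkerFirstBlock`.

    ``source`` may be a string of VCF text, an open text stream, or any
    iterable of lines.  All ``##`` meta lines are captured verbatim (in
    order).  Markers whose ID column is ``.`` get a synthesized name
    ``<chrom>_<pos>`` (with an ordinal suffix on collision) so the
    name-keyed model always has a key.
    """
    header_lines: list[str] = []
    sample_names: list[str] | None = None
    markers: list[MarkerInfo] = []
    cells: list[list[str]] = []
    used_names: set[str] = set()

    for raw in _as_line_iter(source):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            header_lines.append(line)
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) < 8:
                raise VcfFormatError("#CHROM line has fewer than 8 columns")
            sample_names = cols[9:] if len(cols) > 9 else []
            continue
        if sample_names is None:
            raise VcfFormatError("data row encountered before #CHROM line")
        fields = line.split("\t")
        if sample_names and len(fields) < 9:
            raise VcfFormatError(
                f"data row has {len(fields)} columns; at least 9 required "
                f"when samples are present"
            )
        chrom, pos, mid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
        qual = fields[5] if len(fields) > 5 else "."
        filt = fields[6] if len(fields) > 6 else "."
        info = fields[7] if len(fields) > 7 else "."
        fmt = fields[8] if len(fields) > 8 else "GT"

        if mid == "." or not mid:
            mid = f"{chrom}_{pos}"
            if mid in used_names:
                k = 2
                while f"{mid}_{k}" in used_names:
                    k += 1
                mid = f"{mid}_{k}"
        used_names.add(mid)

        markers.append(
            MarkerInfo(
                name=mid,
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=[] if alt in (".", "") else alt.split(","),
                qual=qual,
                filter=filt,
                info=info,
                format=fmt,
            )
        )
        cells.append(fields[9 : 9 + len(sample_names)])

    if sample_names is None:
        raise VcfFormatError("no #CHROM column-header line found")
    return header_lines, MarkerFirstBlock(markers, sample_names, cells)


def build_protocol(
    header_lines: Sequence[str],
    block: MarkerFirstBlock,
    protocol_id: str,
    name: str,
    reference_genome_name: str = "",
    species_name: str = "",
    sample_observation_unit_type_name: str = "accession",
    description: str = "",
) -> GenotypingProtocol:
    """Assemble a protocol from parsed VCF parts.

    The stored per-marker ``format`` gains ``NT`` and ``DS`` (when the
    file did not already carry them), since those keys are always
    generated at load time and emitted on export.
    """
    markers: dict[str, MarkerInfo] = {}
    array: list[MarkerInfo] = []
    for m in block.markers:
        keys = m.format_keys
        fmt = ":".join(keys + [k for k in ("NT", "DS") if k not in keys])
        mio = MarkerInfo(
            name=m.name, chrom=m.chrom, pos=m.pos, ref=m.ref, alt=list(m.alt),
            qual=m.qual, filter=m.filter, info=m.info, format=fmt,
            extra=dict(m.extra),
        )
        markers[m.name] = mio
        array.append(mio)
    return GenotypingProtocol(
        protocol_id=protocol_id,
        name=name,
        description=description,
        reference_genome_name=reference_genome_name,
        species_name=species_name,
        sample_observation_unit_type_name=sample_observation_unit_type_name,
        header_information_lines=list(header_lines),
        marker_names=[m.name for m in array],
        markers=markers,
        markers_array=array,
    )


class CellError(ValueError):
    """A FORMAT cell failed to convert; carries marker+sample coordinates."""

    def __init__(self, marker: str, sample: str, cause: Exception):
        super().__init__(f"marker {marker!r}, sample {sample!r}: {cause}")
        self.marker = marker
        self.sample = sample
        self.cause = cause


def transpose_to_sample_first(
    block: MarkerFirstBlock,
    protocol: GenotypingProtocol,
    convention: str = "reference",
    chunk_size: int = 4096,
) -> list[SampleCallset]:
    """Convert a marker-first block into one callset per sample.

    Works in marker-row chunks: each chunk of rows is split cell-wise
    and appended to per-sample accumulators, so no full dense transpose
    is materialised beyond the callsets themselves.
    """
    callsets = [
        SampleCallset(sample_name=s, protocol_id=protocol.protocol_id)
        for s in block.sample_names
    ]
    for start in range(0, len(block.markers), chunk_size):
        for i in range(start, min(start + chunk_size, len(block.markers))):
            marker = block.markers[i]
            keys = marker.format_keys
            for j, cell in enumerate(block.cells[i]):
                try:
                    call = build_genotype_call(
                        keys, cell.split(":"), marker, convention=convention
                    )
                except ValueError as exc:
                    raise CellError(marker.name, block.sample_names[j], exc) from exc
                callsets[j].calls[marker.name] = call
    return callsets


def _render_cell(marker: MarkerInfo, call: GenotypeCall | None) -> str:
    """Raw FORMAT value string for one marker/sample, per the marker's
    (NT/DS-augmented) format key order.  Absent calls render missing."""
    keys = marker.format_keys
    if call is None:
        return ":".join("./." if k == "GT" else "." for k in keys)
    parts = []
    for k in keys:
        if k == "GT":
            parts.append(call.GT)
        elif k == "NT":
            parts.append(call.NT if call.NT else ".")
        elif k == "DS":
            parts.append(str(call.DS))
        else:
            parts.append(call.extra.get(k, "."))
    return ":".join(parts)


def write_vcf(
    protocol: GenotypingProtocol,
    callsets: Sequence[SampleCallset],
    sample_order: Sequence[str] | None = None,
) -> Iterator[str]:
    """Yield VCF lines: stored header verbatim, then one row per marker.

    Samples appear in ``sample_order`` (default: callset order).  A
    callset lacking a marker renders as a fully missing cell rather
    than erroring — partial callsets are legal downloads.
    """
    by_name = {cs.sample_name: cs for cs in callsets}
    order = list(sample_order) if sample_order is not None else [
        cs.sample_name for cs in callsets
    ]
    for line in protocol.header_information_lines:
        yield line + "\n"
    yield "\t".join(_FIXED_COLS[:9] + tuple(order)) + "\n"
    for name in protocol.marker_names:
        m = protocol.markers[name]
        row = [
            m.chrom,
            str(m.pos),
            m.name,
            m.ref,
            ",".join(m.alt) if m.alt else ".",
            m.qual,
            m.filter,
            m.info,
            m.format,
        ]
        for s in order:
            cs = by_name.get(s)
            row.append(_render_cell(m, cs.calls.get(name) if cs else None))
        yield "\t".join(row) + "\n"


def transpose_to_marker_first(
    protocol: GenotypingProtocol,
    callsets: Sequence[SampleCallset],
    sample_order: Sequence[str] | None = None,
) -> MarkerFirstBlock:
    """Rebuild the marker-first cell matrix from sample-first callsets.

    Inverse of :func:`transpose_to_sample_first` up to the NT/DS keys
    added at load time.
    """
    by_name = {cs.sample_name: cs for cs in callsets}
    order = list(sample_order) if sample_order is not None else [
        cs.sample_name for cs in callsets
    ]
    markers = [protocol.markers[n] for n in protocol.marker_names]
    cells = []
    for m in markers:
        row = []
        for s in order:
            cs = by_name.get(s)
            row.append(_render_cell(m, cs.calls.get(m.name) if cs else None))
        cells.append(row)
    return MarkerFirstBlock(markers=markers, sample_names=order, cells=cells)


def write_dosage_matrix(
    protocol: GenotypingProtocol,
    callsets: Sequence[SampleCallset],
    sample_order: Sequence[str] | None = None,
) -> Iterator[str]:
    """Yield the dosage matrix as TSV lines.

    Row 1 is ``Marker`` plus sample names; each further row is one
    marker's DS value per sample (``NA`` for missing or absent calls).
    """
    by_name = {cs.sample_name: cs for cs in callsets}
    order = list(sample_order) if sample_order is not None else [
        cs.sample_name for cs in callsets
    ]
    yield "\t".join(["Marker"] + order) + "\n"
    for name in protocol.marker_names:
        row = [name]
        for s in order:
            cs = by_name.get(s)
            call = cs.calls.get(name) if cs else None
            row.append(str(call.DS) if call is not None else NA)
        yield "\t".join(row) + "\n"
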