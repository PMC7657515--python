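"""Parameterized genotype search with a write-through file cache.

A query is canonicalized (lists sorted, unset fields dropped), digested
with MD5, and the digest keys a file in the cache directory.  On a miss
the result is computed from the store and streamed to a temp file which
is atomically renamed into place; a JSON sidecar written afterwards
marks the entry complete, so a half-written payload is never visible.
On a hit the cached bytes are served directly — identical queries are
byte-identical whether served cold or warm.

Cache entries are namespaced by the store's generation counter
(``gen-<N>/``), so any write to the store invalidates prior entries
without touching them.

Three output formats exist: ``vcf``, ``dosage_matrix`` (TSV) and
``internal_json`` (one JSON record per sample per line, including
sample metadata).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

from .datamodel import GenotypingProtocol, SampleCallset
from .store import GenotypeStore
from .vcf_io import write_dosage_matrix, write_vcf

__all__ = [
    "GenotypeQuery",
    "CacheEntry",
    "GenotypeSearch",
    "canonical_cache_key",
]

_FORMATS = {"vcf": ".vcf", "dosage_matrix": ".tsv", "internal_json": ".json"}


@dataclass
class GenotypeQuery:
    """The full search parameter surface.

    Minimally a list of accessions (or tissue samples) and one protocol
    must be supplied.  Marker filters (names, chromosomes, inclusive
    position range) and sample filters (trials, genotyping projects,
    pagination) are all optional.
    """

    accession_list: list[str] = field(default_factory=list)
    tissue_sample_list: list[str] = field(default_factory=list)
    trial_list: list[str] = field(default_factory=list)
    protocol_id_list: list[int] = field(default_factory=list)
    markerprofile_id_list: list[int] = field(default_factory=list)
    genotype_data_project_list: list[str] = field(default_factory=list)
    marker_name_list: list[str] = field(default_factory=list)
    chromosome_list: list[str] = field(default_factory=list)
    start_position: int | None = None
    end_position: int | None = None
    genotypeprop_keys_select: list[str] = field(default_factory=list)
    protocolprop_selects: list[str] = field(default_factory=list)
    compute_from_parents: bool = False
    metadata_only: bool = False
    limit: int | None = None
    offset: int | None = None
    format: str = "vcf"

    def validate(self) -> None:
        if not (self.accession_list or self.tissue_sample_list):
            raise ValueError("a list of accessions or tissue samples is required")
        if not self.protocol_id_list:
            raise ValueError("at least one genotyping protocol is required")
        if self.format not in _FORMATS:
            raise ValueError(f"format must be one of {sorted(_FORMATS)}")
        if (
            self.start_position is not None
            and self.end_position is not None
            and self.start_position > self.end_position
        ):
            raise ValueError("start_position must be <= end_position")


def canonical_cache_key(q: GenotypeQuery) -> str:
    """MD5 digest of the canonicalized query.

    Canonical form: list fields sorted, unset/empty fields dropped (so
    an unset list and an empty list hash identically), keys sorted,
    compact JSON.  The output format participates in the key.
    """
    doc = {}
    for key, value in asdict(q).items():
        if value is None or value == [] or value is False:
            continue
        if isinstance(value, list):
            value = sorted(value, key=str)
        doc[key] = value
    payload = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.md5(payload.encode()).hexdigest()


@dataclass
class CacheEntry:
    """A completed cache file and its creation metadata."""

    key: str
    format: str
    path: Path
    created_at: float
    generation: int

    def lines(self) -> Iterator[str]:
        """Stream the payload line-by-line (O(1) lines retained)."""
        with open(self.path) as fh:
            yield from fh

    def read_text(self) -> str:
        return self.path.read_text()


@dataclass
class SearchResult:
    """Handle returned by :meth:`GenotypeSearch.search`."""

    entry: CacheEntry
    from_cache: bool
    skipped_progeny: list[str] = field(default_factory=list)

    def lines(self) -> Iterator[str]:
        return self.entry.lines()

    def read_text(self) -> str:
        return self.entry.read_text()


def _subset_protocol(
    protocol: GenotypingProtocol, marker_names: Sequence[str]
) -> GenotypingProtocol:
    keep = list(marker_names)
    return GenotypingProtocol(
        protocol_id=protocol.protocol_id,
        name=protocol.name,
        description=protocol.description,
        reference_genome_name=protocol.reference_genome_name,
        species_name=protocol.species_name,
        sample_observation_unit_type_name=protocol.sample_observation_unit_type_name,
        header_information_lines=list(protocol.header_information_lines),
        marker_names=keep,
        markers={n: protocol.markers[n] for n in keep},
        markers_array=[protocol.markers[n] for n in keep],
    )


class GenotypeSearch:
    """Packaged genotype query surface over a :class:`GenotypeStore`."""

    def __init__(self, store: GenotypeStore, cache_root: str | Path):
        self.store = store
        self.cache_root = Path(cache_root)
        self.hits = 0
        self.misses = 0

    # -- sample / marker resolution ----------------------------------------

    def _resolve_samples(self, q: GenotypeQuery, protocol_id: int) -> list[str]:
        requested = sorted(set(q.accession_list) | set(q.tissue_sample_list))
        genotyped = set(self.store.genotyped_samples(protocol_id))
        if q.compute_from_parents:
            # progeny need not be genotyped themselves
            samples = [s for s in requested if self._parents_genotyped(s, protocol_id)]
        else:
            samples = [s for s in requested if s in genotyped]
        if q.trial_list:
            in_trials = self.store.stocks_in_projects(q.trial_list)
            samples = [s for s in samples if s in in_trials]
        if q.genotype_data_project_list:
            in_projects = self.store.stocks_in_projects(q.genotype_data_project_list)
            samples = [s for s in samples if s in in_projects]
        if q.offset:
            samples = samples[q.offset:]
        if q.limit is not None:
            samples = samples[: q.limit]
        return samples

    def _parents_genotyped(self, progeny: str, protocol_id: int) -> bool:
        try:
            parents = self.store.get_parents(progeny)
        except KeyError:
            return False
        if parents is None:
            return False
        genotyped = set(self.store.genotyped_samples(protocol_id))
        return parents[0] in genotyped and parents[1] in genotyped

    @staticmethod
    def _filter_markers(q: GenotypeQuery, protocol: GenotypingProtocol) -> list[str]:
        wanted = set(q.marker_name_list) if q.marker_name_list else None
        chroms = set(q.chromosome_list) if q.chromosome_list else None
        out = []
        for name in protocol.marker_names:
            m = protocol.markers[name]
            if wanted is not None and name not in wanted:
                continue
            if chroms is not None and m.chrom not in chroms:
                continue
            if q.start_position is not None and m.pos < q.start_position:
                continue
            if q.end_position is not None and m.pos > q.end_position:
                continue
            out.append(name)
        return out

    # -- rendering ----------------------------------------------------------

    def _progeny_callsets(
        self, q: GenotypeQuery, protocol: GenotypingProtocol, samples: Sequence[str]
    ) -> tuple[list[SampleCallset], list[str]]:
        """Mid-parent callsets for progeny of genotyped parents.

        Fractional dosages have no integer GT, so calls carry GT "./."
        and the averaged DS only.
        """
        from .popgen import mid_parent_dosage  # local import; popgen is heavier

        pid = int(protocol.protocol_id)
        callsets, skipped = [], []
        for s in samples:
            parents = self.store.get_parents(s)
            if parents is None:
                skipped.append(s)
                continue
            try:
                cs1 = self.store.get_callset(parents[0], pid)
                cs2 = self.store.get_callset(parents[1], pid)
            except KeyError:
                skipped.append(s)
                continue
            callsets.append(mid_parent_dosage(s, cs1, cs2, protocol))
        return callsets, skipped

    def _fetch_callsets(
        self, q: GenotypeQuery, protocol: GenotypingProtocol, samples: Sequence[str]
    ) -> tuple[list[SampleCallset], list[str]]:
        pid = int(protocol.protocol_id)
        if q.compute_from_parents:
            return self._progeny_callsets(q, protocol, samples)
        return [self.store.get_callset(s, pid) for s in samples], []

    def _render(
        self, q: GenotypeQuery, protocol: GenotypingProtocol,
        samples: Sequence[str], marker_names: Sequence[str],
        callsets: Sequence[SampleCallset],
    ) -> Iterator[str]:
        sub = _subset_protocol(protocol, marker_names)
        if q.compute_from_parents and q.format == "vcf":
            sub.header_information_lines = sub.header_information_lines + [
                "##callstore_note=genotypes computed from parents; "
                "GT unset, DS is the mid-parent dosage"
            ]
        if q.format == "vcf":
            yield from write_vcf(sub, callsets, sample_order=samples)
        elif q.format == "dosage_matrix":
            yield from write_dosage_matrix(sub, callsets, sample_order=samples)
        else:
            yield from self._render_internal_json(q, sub, samples, callsets)

    def _render_internal_json(
        self, q: GenotypeQuery, protocol: GenotypingProtocol,
        samples: Sequence[str], callsets: Sequence[SampleCallset],
    ) -> Iterator[str]:
        details = protocol.to_documents()["vcf_map_details"]
        if q.protocolprop_selects:
            details = {k: v for k, v in details.items() if k in q.protocolprop_selects}
        by_name = {cs.sample_name: cs for cs in callsets}
        for s in samples:
            record: dict = {
                "sample_name": s,
                "observation_unit_type": self.store.observation_unit_type(s),
                "protocol_id": protocol.protocol_id,
                "protocol_name": protocol.name,
                "protocol_metadata": details,
            }
            if not q.metadata_only:
                cs = by_name.get(s)
                calls = {}
                if cs is not None:
                    for name in protocol.marker_names:
                        call = cs.calls.get(name)
                        if call is None:
                            continue
                        doc = call.to_json()
                        if q.genotypeprop_keys_select:
                            doc = {
                                k: v for k, v in doc.items()
                                if k in q.genotypeprop_keys_select
                            }
                        calls[name] = doc
                record["calls"] = calls
            yield json.dumps(record, sort_keys=True) + "\n"

    # -- the cache-backed entry point ---------------------------------------

    def search(self, q: GenotypeQuery) -> SearchResult:
        """Serve a query, from cache when an identical one ran before."""
        q.validate()
        key = canonical_cache_key(q)
        gen_dir = self.cache_root / f"gen-{self.store.generation}"
        gen_dir.mkdir(parents=True, exist_ok=True)
        ext = _FORMATS[q.format]
        payload_path = gen_dir / f"{key}{ext}"
        meta_path = gen_dir / f"{key}{ext}.meta.json"

        if meta_path.exists() and payload_path.exists():
            self.hits += 1
            meta = json.loads(meta_path.read_text())
            entry = CacheEntry(
                key=key, format=q.format, path=payload_path,
                created_at=meta["created_at"], generation=meta["generation"],
            )
            return SearchResult(entry=entry, from_cache=True,
                                skipped_progeny=meta.get("skipped_progeny", []))

        self.misses += 1
        protocol_id = q.protocol_id_list[0]
        protocol = self.store.get_protocol(protocol_id)  # not-found raises
        samples = self._resolve_samples(q, protocol_id)
        marker_names = self._filter_markers(q, protocol)
        callsets, skipped = self._fetch_callsets(q, protocol, samples)
        samples = [s for s in samples if s not in set(skipped)]

        tmp_path = gen_dir / f".{key}{ext}.tmp-{os.getpid()}"
        with open(tmp_path, "w") as fh:
            for line in self._render(q, protocol, samples, marker_names, callsets):
                fh.write(line)
        os.replace(tmp_path, payload_path)
        meta = {
            "key": key,
            "format": q.format,
            "created_at": time.time(),
            "generation": self.store.generation,
            "skipped_progeny": skipped,
        }
        meta_path.write_text(json.dumps(meta))
        entry = CacheEntry(
            key=key, format=q.format, path=payload_path,
            created_at=meta["created_at"], generation=meta["generation"],
        )
        return SearchResult(entry=entry, from_cache=False, skipped_progeny=skipped)

    def compute_fresh(self, q: GenotypeQuery) -> str:
        """Bypass the cache entirely (oracle path for soundness checks)."""
        q.validate()
        protocol_id = q.protocol_id_list[0]
        protocol = self.store.get_protocol(protocol_id)
        samples = self._resolve_samples(q, protocol_id)
        marker_names = self._filter_markers(q, protocol)
        callsets, skipped = self._fetch_callsets(q, protocol, samples)
        samples = [s for s in samples if s not in set(skipped)]
        return "".join(self._render(q, protocol, samples, marker_names, callsets))
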