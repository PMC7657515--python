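"""Relational store with JSON-valued property fields.

The layout follows the natural-diversity pattern: *stocks* (the
genotyped/phenotyped entities), *projects* (field trials and genotyping
projects), *protocols* (genotyping events), property tables whose
``value`` column holds a JSON document, and an *experiment* link table
tying one of each together so queries can span phenotypes and genotypes
through ordinary joins.

The engine is embedded SQLite with its JSON1 functions; the big-JSON
index of the original design is abstracted as a dedicated
``(protocol_id, marker_name)`` lookup table with a btree index, which
answers "which protocols carry marker X" without scanning documents.

Protocols and callsets are immutable after upload — the premise that
makes downstream result caching sound.  Every write bumps a store-wide
generation counter that cache layers may namespace by.
"""

from __future__ import annotations

import json
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .datamodel import (
    OBSERVATION_UNIT_TYPES,
    GenotypingProtocol,
    SampleCallset,
    validate_protocol,
)

__all__ = [
    "GenotypeStore",
    "StoreConflictError",
    "LookupError_",
    "PhenotypeRecord",
    "PedigreeRecord",
    "normalize_name",
    "name_similarity",
]

logger = logging.getLogger(__name__)


class StoreConflictError(RuntimeError):
    """Attempt to overwrite an immutable record (protocol or callset)."""


class LookupError_(KeyError):
    """A referenced entity is not registered in the store."""


@dataclass
class PhenotypeRecord:
    """One phenotypic observation with its trial design metadata."""

    uniquename: str
    trait_name: str
    value: str
    project_name: str
    location: str = ""
    year: str = ""
    replicate: str = ""

    def numeric_value(self) -> float | None:
        try:
            return float(self.value)
        except (TypeError, ValueError):
            return None


@dataclass
class PedigreeRecord:
    progeny: str
    parent1: str
    parent2: str

    def __post_init__(self) -> None:
        if self.progeny in (self.parent1, self.parent2):
            raise ValueError(f"progeny {self.progeny!r} cannot be its own parent")


_NON_ALNUM = re.compile(r"[^A-Z0-9]")


def normalize_name(name: str) -> str:
    """Uppercase and strip non-alphanumerics — 'Tx303' and 'TX-303'
    normalize identically."""
    return _NON_ALNUM.sub("", name.upper())


def name_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity of two names in [0, 1]."""
    na, nb = normalize_name(a), normalize_name(b)
    if not na and not nb:
        return 1.0
    if not na or not nb:
        return 0.0
    dist = edlib.align(na, nb, task="distance")["editDistance"]
    return 1.0 - dist / max(len(na), len(nb))


@dataclass
class RegistrationReport:
    """Classification of incoming sample names against the catalogue."""

    exact: list[str] = field(default_factory=list)
    flagged: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    new: list[str] = field(default_factory=list)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS protocol (
    protocol_id INTEGER PRIMARY KEY,
    name TEXT UNIQUE NOT NULL,
    description TEXT DEFAULT ''
);
CREATE TABLE IF NOT EXISTS protocolprop (
    protocol_id INTEGER NOT NULL REFERENCES protocol(protocol_id),
    cvterm TEXT NOT NULL,
    value TEXT NOT NULL,
    PRIMARY KEY (protocol_id, cvterm)
);
CREATE TABLE IF NOT EXISTS protocol_marker (
    protocol_id INTEGER NOT NULL REFERENCES protocol(protocol_id),
    marker_name TEXT NOT NULL,
    PRIMARY KEY (protocol_id, marker_name)
);
CREATE INDEX IF NOT EXISTS idx_protocol_marker_name
    ON protocol_marker(marker_name);
CREATE TABLE IF NOT EXISTS stock (
    stock_id INTEGER PRIMARY KEY,
    uniquename TEXT UNIQUE NOT NULL,
    observation_unit_type TEXT NOT NULL,
    parent1_id INTEGER REFERENCES stock(stock_id),
    parent2_id INTEGER REFERENCES stock(stock_id)
);
CREATE TABLE IF NOT EXISTS project (
    project_id INTEGER PRIMARY KEY,
    name TEXT UNIQUE NOT NULL
);
CREATE TABLE IF NOT EXISTS phenotype (
    phenotype_id INTEGER PRIMARY KEY,
    stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
    trait_name TEXT NOT NULL,
    value TEXT NOT NULL,
    project_id INTEGER NOT NULL REFERENCES project(project_id),
    location TEXT DEFAULT '',
    year TEXT DEFAULT '',
    replicate TEXT DEFAULT ''
);
CREATE TABLE IF NOT EXISTS genotypeprop (
    genotype_id INTEGER PRIMARY KEY,
    stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
    protocol_id INTEGER NOT NULL REFERENCES protocol(protocol_id),
    value TEXT NOT NULL,
    UNIQUE (stock_id, protocol_id)
);
CREATE TABLE IF NOT EXISTS nd_experiment (
    experiment_id INTEGER PRIMARY KEY,
    experiment_type TEXT NOT NULL,
    project_id INTEGER REFERENCES project(project_id),
    protocol_id INTEGER REFERENCES protocol(protocol_id),
    stock_id INTEGER REFERENCES stock(stock_id),
    phenotype_id INTEGER REFERENCES phenotype(phenotype_id),
    genotype_id INTEGER REFERENCES genotypeprop(genotype_id)
);
"""


class GenotypeStore:
    """Embedded store for protocols, samples, callsets and phenotypes.

    Parameters
    ----------
    path:
        SQLite database file, or ``":memory:"`` (default) for an
        in-memory store.
    """

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)
        self.conn.execute(
            "INSERT OR IGNORE INTO meta (key, value) VALUES ('generation', '0')"
        )
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- generation counter -------------------------------------------------

    @property
    def generation(self) -> int:
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key = 'generation'"
        ).fetchone()
        return int(row["value"])

    def _bump_generation(self) -> None:
        self.conn.execute(
            "UPDATE meta SET value = CAST(value AS INTEGER) + 1 "
            "WHERE key = 'generation'"
        )

    # -- protocols ----------------------------------------------------------

    def store_protocol(self, p: GenotypingProtocol) -> int:
        """Persist a protocol as its three JSON property documents.

        Refuses to proceed if validation reports problems or a protocol
        of the same name already exists.
        """
        report = validate_protocol(p)
        if report.duplicate_marker_names or report.representation_mismatches:
            raise ValueError(f"protocol failed validation: {report.summary()}")
        try:
            cur = self.conn.execute(
                "INSERT INTO protocol (name, description) VALUES (?, ?)",
                (p.name, p.description),
            )
        except sqlite3.IntegrityError as exc:
            raise StoreConflictError(f"protocol name {p.name!r} already stored") from exc
        pid = cur.lastrowid
        for cvterm, doc in p.to_documents().items():
            self.conn.execute(
                "INSERT INTO protocolprop (protocol_id, cvterm, value) VALUES (?, ?, ?)",
                (pid, cvterm, json.dumps(doc)),
            )
        self.conn.executemany(
            "INSERT INTO protocol_marker (protocol_id, marker_name) VALUES (?, ?)",
            [(pid, n) for n in p.marker_names],
        )
        self._bump_generation()
        self.conn.commit()
        return pid

    def get_protocolprop(self, protocol_id: int, cvterm: str):
        row = self.conn.execute(
            "SELECT value FROM protocolprop WHERE protocol_id = ? AND cvterm = ?",
            (protocol_id, cvterm),
        ).fetchone()
        if row is None:
            raise LookupError_(f"no {cvterm!r} document for protocol {protocol_id}")
        return json.loads(row["value"])

    def get_protocol(self, protocol_id: int) -> GenotypingProtocol:
        row = self.conn.execute(
            "SELECT name, description FROM protocol WHERE protocol_id = ?",
            (protocol_id,),
        ).fetchone()
        if row is None:
            raise LookupError_(f"unknown protocol id {protocol_id}")
        docs = {
            cvterm: self.get_protocolprop(protocol_id, cvterm)
            for cvterm in (
                "vcf_map_details",
                "vcf_map_details_markers",
                "vcf_map_details_markers_array",
            )
        }
        return GenotypingProtocol.from_documents(
            str(protocol_id), row["name"], docs, description=row["description"]
        )

    def protocol_id_by_name(self, name: str) -> int:
        row = self.conn.execute(
            "SELECT protocol_id FROM protocol WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise LookupError_(f"unknown protocol name {name!r}")
        return row["protocol_id"]

    def protocols_with_marker(self, marker_name: str) -> list[int]:
        """Indexed marker-name lookup (the GIN-index stand-in)."""
        rows = self.conn.execute(
            "SELECT protocol_id FROM protocol_marker WHERE marker_name = ? "
            "ORDER BY protocol_id",
            (marker_name,),
        ).fetchall()
        return [r["protocol_id"] for r in rows]

    def protocols_with_marker_fullscan(self, marker_name: str) -> list[int]:
        """Oracle twin of :meth:`protocols_with_marker`: scans the JSON
        documents instead of the index table."""
        rows = self.conn.execute(
            "SELECT protocol_id, value FROM protocolprop "
            "WHERE cvterm = 'vcf_map_details_markers' ORDER BY protocol_id"
        ).fetchall()
        return [r["protocol_id"] for r in rows if marker_name in json.loads(r["value"])]

    # -- stocks and pedigree ------------------------------------------------

    def add_stock(
        self,
        uniquename: str,
        observation_unit_type: str = "accession",
    ) -> int:
        if observation_unit_type not in OBSERVATION_UNIT_TYPES:
            raise ValueError(
                f"observation unit type must be one of {sorted(OBSERVATION_UNIT_TYPES)}"
            )
        try:
            cur = self.conn.execute(
                "INSERT INTO stock (uniquename, observation_unit_type) VALUES (?, ?)",
                (uniquename, observation_unit_type),
            )
        except sqlite3.IntegrityError as exc:
            raise StoreConflictError(f"stock {uniquename!r} already exists") from exc
        self._bump_generation()
        self.conn.commit()
        return cur.lastrowid

    def stock_id(self, uniquename: str) -> int:
        row = self.conn.execute(
            "SELECT stock_id FROM stock WHERE uniquename = ?", (uniquename,)
        ).fetchone()
        if row is None:
            raise LookupError_(f"unknown stock {uniquename!r}")
        return row["stock_id"]

    def stock_names(self, observation_unit_type: str | None = None) -> list[str]:
        if observation_unit_type is None:
            rows = self.conn.execute(
                "SELECT uniquename FROM stock ORDER BY uniquename"
            ).fetchall()
        else:
            rows = self.conn.execute(
                "SELECT uniquename FROM stock WHERE observation_unit_type = ? "
                "ORDER BY uniquename",
                (observation_unit_type,),
            ).fetchall()
        return [r["uniquename"] for r in rows]

    def register_samples(
        self,
        names: Sequence[str],
        catalogue: Sequence[str] | None = None,
        threshold: float = 0.85,
    ) -> RegistrationReport:
        """Classify incoming names as exact / flagged near-match / new.

        Near-matches (typographical variants like ``Tx303`` vs
        ``TX-303``) are flagged with their candidates and similarity
        scores; nothing is merged automatically.
        """
        if not names:
            raise ValueError("names must be nonempty")
        if catalogue is None:
            catalogue = self.stock_names()
        existing = set(catalogue)
        report = RegistrationReport()
        for name in names:
            if name in existing:
                report.exact.append(name)
                continue
            near = sorted(
                (
                    (cand, score)
                    for cand in catalogue
                    if (score := name_similarity(name, cand)) >= threshold
                ),
                key=lambda cs: (-cs[1], cs[0]),
            )
            if near:
                report.flagged[name] = near
            else:
                report.new.append(name)
        return report

    def set_parents(self, progeny: str, parent1: str, parent2: str) -> None:
        rec = PedigreeRecord(progeny, parent1, parent2)
        pid1, pid2 = self.stock_id(rec.parent1), self.stock_id(rec.parent2)
        sid = self.stock_id(rec.progeny)
        self.conn.execute(
            "UPDATE stock SET parent1_id = ?, parent2_id = ? WHERE stock_id = ?",
            (pid1, pid2, sid),
        )
        self._bump_generation()
        self.conn.commit()

    def get_parents(self, progeny: str) -> tuple[str, str] | None:
        row = self.conn.execute(
            "SELECT p1.uniquename AS a, p2.uniquename AS b FROM stock s "
            "LEFT JOIN stock p1 ON s.parent1_id = p1.stock_id "
            "LEFT JOIN stock p2 ON s.parent2_id = p2.stock_id "
            "WHERE s.uniquename = ?",
            (progeny,),
        ).fetchone()
        if row is None:
            raise LookupError_(f"unknown stock {progeny!r}")
        if row["a"] is None or row["b"] is None:
            return None
        return row["a"], row["b"]

    def load_pedigree(self, records: Iterable[PedigreeRecord | Sequence[str]]) -> int:
        n = 0
        for rec in records:
            if not isinstance(rec, PedigreeRecord):
                rec = PedigreeRecord(*rec)
            self.set_parents(rec.progeny, rec.parent1, rec.parent2)
            n += 1
        return n

    # -- callsets -----------------------------------------------------------

    def store_callsets(
        self, protocol_id: int, callsets: Sequence[SampleCallset]
    ) -> int:
        """Persist one callset document per sample and link the
        experiment triplet (stock, protocol, genotype).

        All sample uniquenames must be registered beforehand; re-storing
        a (sample, protocol) pair is a conflict because uploaded
        genotypes are immutable.
        """
        unmatched = []
        ids = {}
        for cs in callsets:
            try:
                ids[cs.sample_name] = self.stock_id(cs.sample_name)
            except LookupError_:
                unmatched.append(cs.sample_name)
        if unmatched:
            raise LookupError_(f"unregistered sample names: {unmatched}")
        n = 0
        for cs in callsets:
            try:
                cur = self.conn.execute(
                    "INSERT INTO genotypeprop (stock_id, protocol_id, value) "
                    "VALUES (?, ?, ?)",
                    (ids[cs.sample_name], protocol_id, json.dumps(cs.to_json())),
                )
            except sqlite3.IntegrityError as exc:
                self.conn.rollback()
                raise StoreConflictError(
                    f"callset for {cs.sample_name!r} under protocol "
                    f"{protocol_id} already stored"
                ) from exc
            self.conn.execute(
                "INSERT INTO nd_experiment "
                "(experiment_type, protocol_id, stock_id, genotype_id) "
                "VALUES ('genotyping_experiment', ?, ?, ?)",
                (protocol_id, ids[cs.sample_name], cur.lastrowid),
            )
            n += 1
        self._bump_generation()
        self.conn.commit()
        return n

    def get_callset(self, sample_name: str, protocol_id: int) -> SampleCallset:
        row = self.conn.execute(
            "SELECT g.value FROM genotypeprop g JOIN stock s USING (stock_id) "
            "WHERE s.uniquename = ? AND g.protocol_id = ?",
            (sample_name, protocol_id),
        ).fetchone()
        if row is None:
            raise LookupError_(
                f"no callset for {sample_name!r} under protocol {protocol_id}"
            )
        return SampleCallset.from_json(
            sample_name, str(protocol_id), json.loads(row["value"])
        )

    def genotyped_samples(self, protocol_id: int) -> list[str]:
        rows = self.conn.execute(
            "SELECT s.uniquename FROM genotypeprop g JOIN stock s USING (stock_id) "
            "WHERE g.protocol_id = ? ORDER BY s.uniquename",
            (protocol_id,),
        ).fetchall()
        return [r["uniquename"] for r in rows]

    # -- phenotypes ---------------------------------------------------------

    def _project_id(self, name: str, create: bool = False) -> int:
        row = self.conn.execute(
            "SELECT project_id FROM project WHERE name = ?", (name,)
        ).fetchone()
        if row is not None:
            return row["project_id"]
        if not create:
            raise LookupError_(f"unknown project {name!r}")
        cur = self.conn.execute("INSERT INTO project (name) VALUES (?)", (name,))
        return cur.lastrowid

    def store_phenotypes(self, records: Iterable[PhenotypeRecord]) -> int:
        n = 0
        for rec in records:
            sid = self.stock_id(rec.uniquename)
            pid = self._project_id(rec.project_name, create=True)
            cur = self.conn.execute(
                "INSERT INTO phenotype "
                "(stock_id, trait_name, value, project_id, location, year, replicate) "
                "VALUES (?, ?, ?, ?, ?, ?, ?)",
                (sid, rec.trait_name, rec.value, pid, rec.location, rec.year,
                 rec.replicate),
            )
            self.conn.execute(
                "INSERT INTO nd_experiment "
                "(experiment_type, project_id, stock_id, phenotype_id) "
                "VALUES ('phenotyping_experiment', ?, ?, ?)",
                (pid, sid, cur.lastrowid),
            )
            n += 1
        self._bump_generation()
        self.conn.commit()
        return n

    def get_phenotypes(
        self,
        stock_names: Sequence[str] | None = None,
        trait_names: Sequence[str] | None = None,
        project_names: Sequence[str] | None = None,
    ) -> list[PhenotypeRecord]:
        sql = (
            "SELECT s.uniquename, p.trait_name, p.value, pr.name AS project, "
            "p.location, p.year, p.replicate "
            "FROM phenotype p JOIN stock s USING (stock_id) "
            "JOIN project pr USING (project_id) WHERE 1=1"
        )
        args: list = []
        for col, vals in (
            ("s.uniquename", stock_names),
            ("p.trait_name", trait_names),
            ("pr.name", project_names),
        ):
            if vals is not None:
                sql += f" AND {col} IN ({','.join('?' * len(vals))})"
                args.extend(vals)
        sql += " ORDER BY s.uniquename, p.trait_name, p.phenotype_id"
        return [
            PhenotypeRecord(
                uniquename=r["uniquename"], trait_name=r["trait_name"],
                value=r["value"], project_name=r["project"],
                location=r["location"], year=r["year"], replicate=r["replicate"],
            )
            for r in self.conn.execute(sql, args).fetchall()
        ]

    # -- cross-entity queries ----------------------------------------------

    def query_stocks_markers_and_trait(
        self,
        marker_names: Sequence[str],
        trait_name: str,
        project_name: str,
    ) -> list[str]:
        """Stocks genotyped for ANY of the markers and phenotyped for the
        trait within the named field trial.  Deterministic (sorted)."""
        if not marker_names:
            return []
        placeholders = ",".join("?" * len(marker_names))
        rows = self.conn.execute(
            "SELECT DISTINCT s.uniquename FROM stock s "
            "JOIN genotypeprop g USING (stock_id) "
            "JOIN protocol_marker pm ON pm.protocol_id = g.protocol_id "
            "JOIN phenotype ph ON ph.stock_id = s.stock_id "
            "JOIN project pr ON pr.project_id = ph.project_id "
            f"WHERE pm.marker_name IN ({placeholders}) "
            "AND ph.trait_name = ? AND pr.name = ? "
            "ORDER BY s.uniquename",
            (*marker_names, trait_name, project_name),
        ).fetchall()
        return [r["uniquename"] for r in rows]

    def query_stocks_genotype_and_phenotype(
        self,
        protocol_name: str,
        marker_name: str,
        marker_dp_min: float | None = None,
        marker_gq_min: float | None = None,
        required_nt: str | None = None,
        required_gt: str | None = None,
        trait_name: str | None = None,
        trait_min: float | None = None,
    ) -> list[str]:
        """Conjunctive genotype + phenotype query on one marker.

        DP/GQ thresholds apply to *protocol-level* marker metadata (the
        stored MIO); NT and GT are exact string matches on the sample's
        call (so a phased ``0|0`` does not satisfy a required ``0/0``);
        the trait filter is a numeric ``>`` comparison.  Phenotype
        values that do not parse as numbers are skipped with a warning.
        """
        pid = self.protocol_id_by_name(protocol_name)
        markers_doc = self.get_protocolprop(pid, "vcf_map_details_markers")
        mio = markers_doc.get(marker_name)
        if mio is None:
            return []
        for key, bound in (("DP", marker_dp_min), ("GQ", marker_gq_min)):
            if bound is not None:
                raw = mio.get(key)
                if raw is None or float(raw) <= bound:
                    return []

        sql = (
            "SELECT DISTINCT s.uniquename, "
            "json_extract(g.value, '$.' || ? || '.NT') AS nt, "
            "json_extract(g.value, '$.' || ? || '.GT') AS gt "
            "FROM stock s JOIN genotypeprop g USING (stock_id) "
            "WHERE g.protocol_id = ?"
        )
        rows = self.conn.execute(sql, (marker_name, marker_name, pid)).fetchall()
        matched = set()
        for r in rows:
            if required_nt is not None and r["nt"] != required_nt:
                continue
            if required_gt is not None and r["gt"] != required_gt:
                continue
            matched.add(r["uniquename"])

        if trait_name is not None:
            passing = set()
            for rec in self.get_phenotypes(trait_names=[trait_name]):
                val = rec.numeric_value()
                if val is None:
                    logger.warning(
                        "skipping non-numeric phenotype value %r for %s/%s",
                        rec.value, rec.uniquename, rec.trait_name,
                    )
                    continue
                if trait_min is None or val > trait_min:
                    passing.add(rec.uniquename)
            matched &= passing
        return sorted(matched)

    def stocks_in_projects(self, project_names: Sequence[str]) -> set[str]:
        if not project_names:
            return set()
        placeholders = ",".join("?" * len(project_names))
        rows = self.conn.execute(
            "SELECT DISTINCT s.uniquename FROM stock s "
            "JOIN nd_experiment e USING (stock_id) "
            "JOIN project pr USING (project_id) "
            f"WHERE pr.name IN ({placeholders})",
            tuple(project_names),
        ).fetchall()
        return {r["uniquename"] for r in rows}

    def observation_unit_type(self, uniquename: str) -> str:
        row = self.conn.execute(
            "SELECT observation_unit_type FROM stock WHERE uniquename = ?",
            (uniquename,),
        ).fetchone()
        if row is None:
            raise LookupError_(f"unknown stock {uniquename!r}")
        return row["observation_unit_type"]

    # -- integrity ----------------------------------------------------------

    def consistency_sweep(self) -> list[str]:
        """Verify every experiment link resolves; returns violations."""
        problems = []
        checks = [
            ("project_id", "project", "project_id"),
            ("protocol_id", "protocol", "protocol_id"),
            ("stock_id", "stock", "stock_id"),
            ("phenotype_id", "phenotype", "phenotype_id"),
            ("genotype_id", "genotypeprop", "genotype_id"),
        ]
        for col, table, pk in checks:
            rows = self.conn.execute(
                f"SELECT e.experiment_id FROM nd_experiment e "
                f"LEFT JOIN {table} t ON e.{col} = t.{pk} "
                f"WHERE e.{col} IS NOT NULL AND t.{pk} IS NULL"
            ).fetchall()
            problems.extend(
                f"experiment {r['experiment_id']}: dangling {col}" for r in rows
            )
        return problems
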