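"""Protein records with membrane-topology annotations.

The data model mirrors the UniProt convention for membrane proteins:
each record carries an amino-acid sequence plus a list of positional
features of kind TOPO_DOM (a Cytoplasmic / Extracellular / Lumenal
stretch), TRANSMEM (a membrane-spanning segment) or INTRAMEM.  All
coordinates are 1-based inclusive, exactly as UniProt prints them.

Three ingest routes are supported: the UniProt tabular export (TSV with
feature-string columns), FASTA plus a sidecar feature TSV, and a
versioned JSON fixture format for lossless round trips.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FeatureKind",
    "TopoFeature",
    "ProteinRecord",
    "RecordSet",
    "RecordParseError",
    "parse_feature_string",
    "read_records_tsv",
    "read_records_fasta_plus_features",
    "read_records_json",
    "write_records_json",
    "write_records_tsv",
    "render_feature_string",
]

JSON_SCHEMA_VERSION = 1


class RecordParseError(ValueError):
    pass


class FeatureKind(str, Enum):
    TOPO_DOM = "TOPO_DOM"
    TRANSMEM = "TRANSMEM"
    INTRAMEM = "INTRAMEM"


MEMBRANE_KINDS = frozenset({FeatureKind.TRANSMEM, FeatureKind.INTRAMEM})


@dataclass(frozen=True)
class TopoFeature:
    """One topology feature: 1-based inclusive interval with a free-text note."""

    kind: FeatureKind
    start: int
    end: int
    note: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise RecordParseError(
                f"invalid feature interval {self.kind.value} {self.start}..{self.end}"
            )

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ProteinRecord:
    accession: str
    sequence: str
    entry_name: str = ""
    features: list[TopoFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence or not self.sequence.isalpha():
            raise RecordParseError(
                f"{self.accession}: sequence must be non-empty and alphabetic"
            )
        self.validate_features()

    def validate_features(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise RecordParseError(
                    f"{self.accession}: feature {f.kind.value} {f.start}..{f.end} "
                    f"extends past sequence length {n}"
                )
        # same-kind features must be disjoint; cross-kind overlap is a warning
        by_kind: dict[FeatureKind, list[TopoFeature]] = {}
        for f in self.features:
            by_kind.setdefault(f.kind, []).append(f)
        for kind, feats in by_kind.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start <= a.end:
                    raise RecordParseError(
                        f"{self.accession}: overlapping {kind.value} features "
                        f"{a.start}..{a.end} and {b.start}..{b.end}"
                    )
        ordered = sorted(self.features, key=lambda f: (f.start, f.end))
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end and a.kind != b.kind:
                warnings.warn(
                    f"{self.accession}: {a.kind.value} {a.start}..{a.end} overlaps "
                    f"{b.kind.value} {b.start}..{b.end}",
                    stacklevel=2,
                )

    def features_of(self, *kinds: FeatureKind) -> list[TopoFeature]:
        want = set(kinds)
        return [f for f in self.features if f.kind in want]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RecordSet:
    """An ordered collection of protein records with free-text provenance."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.accession in seen:
                raise RecordParseError(f"duplicate accession {r.accession}")
            seen.add(r.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, accession: str) -> ProteinRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)


# UniProt tabular feature dialect: `KIND a..b; /note="..."; ...` records
_FEATURE_TOKEN = re.compile(r"(?P<kind>[A-Z_]+)\s+(?P<pos>[^;]+)")
_NOTE_TOKEN = re.compile(r'/note="(?P<note>[^"]*)"')


def parse_feature_string(text: str, kind: FeatureKind) -> list[TopoFeature]:
    """Parse a UniProt feature-column string into features of one kind.

    The dialect is semicolon-separated: ``TOPO_DOM 1..5; /note="Extracellular";
    TOPO_DOM 27..80; /note="Cytoplasmic"``.  Qualifiers other than ``/note``
    (``/evidence`` etc.) are ignored.  Empty text yields an empty list.
    """
    feats: list[TopoFeature] = []
    if not text or not text.strip():
        return feats
    current: dict | None = None
    for tok_i, token in enumerate(text.split(";")):
        token = token.strip()
        if not token:
            continue
        if token.startswith("/"):
            m = _NOTE_TOKEN.match(token)
            if m and current is not None:
                current["note"] = m.group("note")
            continue
        m = _FEATURE_TOKEN.match(token)
        if m is None:
            raise RecordParseError(f"unparseable feature token {token!r} (token {tok_i})")
        tok_kind, pos = m.group("kind"), m.group("pos").strip()
        if tok_kind != kind.value:
            raise RecordParseError(
                f"expected {kind.value} feature, got {tok_kind!r} (token {tok_i})"
            )
        if current is not None:
            feats.append(_finish(current, kind))
        if ".." not in pos:
            # single-residue features print as a bare position
            if not pos.isdigit():
                raise RecordParseError(f"malformed interval {pos!r} (token {tok_i})")
            a = b = pos
        else:
            a, _, b = pos.partition("..")
        if not (a.strip().isdigit() and b.strip().isdigit()):
            raise RecordParseError(f"malformed interval {pos!r} (token {tok_i})")
        start, end = int(a), int(b)
        if start > end:
            raise RecordParseError(
                f"inverted interval {start}..{end} (token {tok_i})"
            )
        current = {"start": start, "end": end, "note": ""}
    if current is not None:
        feats.append(_finish(current, kind))
    return feats


def _finish(d: dict, kind: FeatureKind) -> TopoFeature:
    return TopoFeature(kind=kind, start=d["start"], end=d["end"], note=d["note"])


DEFAULT_COLUMNS = {
    "accession": "Entry",
    "entry_name": "Entry Name",
    "sequence": "Sequence",
    "topo_dom": "Topological domain",
    "transmem": "Transmembrane",
    "intramem": "Intramembrane",
}


def read_records_tsv(path_or_stream, columns: dict[str, str] | None = None) -> RecordSet:
    """Read a UniProt-style TSV export into a :class:`RecordSet`.

    ``columns`` remaps logical names (accession, sequence, topo_dom,
    transmem, intramem, entry_name) to header names; the defaults match
    UniProt exports.  The intramem and entry_name columns are optional.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path_or_stream, sep="\t", dtype=str, keep_default_na=False)
    for logical in ("accession", "sequence", "topo_dom", "transmem"):
        if cols[logical] not in df.columns:
            raise RecordParseError(f"missing required column {cols[logical]!r}")
    records: list[ProteinRecord] = []
    for i, row in df.iterrows():
        acc = row[cols["accession"]].strip()
        seq = row[cols["sequence"]].strip()
        if not seq:
            raise RecordParseError(f"row {i} ({acc}): empty sequence")
        feats: list[TopoFeature] = []
        try:
            feats += parse_feature_string(row[cols["topo_dom"]], FeatureKind.TOPO_DOM)
            feats += parse_feature_string(row[cols["transmem"]], FeatureKind.TRANSMEM)
            if cols["intramem"] in df.columns:
                feats += parse_feature_string(row[cols["intramem"]], FeatureKind.INTRAMEM)
        except RecordParseError as e:
            raise RecordParseError(f"row {i} ({acc}): {e}") from e
        entry_name = row[cols["entry_name"]] if cols["entry_name"] in df.columns else ""
        records.append(
            ProteinRecord(accession=acc, sequence=seq, entry_name=entry_name, features=feats)
        )
    return RecordSet(records=records, provenance=[f"read_records_tsv: {len(records)} records"])


def read_records_fasta_plus_features(fasta, features_tsv=None) -> RecordSet:
    """Read FASTA sequences joined with a sidecar feature TSV.

    The sidecar columns are ``accession``, ``kind``, ``start``, ``end``,
    ``note``.  FASTA entries without feature rows get empty feature lists;
    feature rows referencing absent accessions are an error.
    """
    seqs: dict[str, str] = {}
    names: dict[str, str] = {}
    for rec in SeqIO.parse(fasta, "fasta"):
        acc = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        seqs[acc] = str(rec.seq)
        names[acc] = rec.description
    feats_by_acc: dict[str, list[TopoFeature]] = {a: [] for a in seqs}
    if features_tsv is not None:
        fdf = pd.read_csv(features_tsv, sep="\t", dtype=str, keep_default_na=False)
        for col in ("accession", "kind", "start", "end"):
            if col not in fdf.columns:
                raise RecordParseError(f"feature TSV missing column {col!r}")
        orphans = sorted(set(fdf["accession"]) - set(seqs))
        if orphans:
            raise RecordParseError(
                f"feature rows reference absent accessions: {', '.join(orphans)}"
            )
        for _, row in fdf.iterrows():
            feats_by_acc[row["accession"]].append(
                TopoFeature(
                    kind=FeatureKind(row["kind"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    note=row.get("note", ""),
                )
            )
    records = [
        ProteinRecord(
            accession=acc, sequence=seq, entry_name=names[acc], features=feats_by_acc[acc]
        )
        for acc, seq in seqs.items()
    ]
    return RecordSet(
        records=records,
        provenance=[f"read_records_fasta_plus_features: {len(records)} records"],
    )


def render_feature_string(features: Iterable[TopoFeature], kind: FeatureKind) -> str:
    """Render features of one kind back into the UniProt column dialect."""
    parts = []
    for f in sorted((f for f in features if f.kind == kind), key=lambda f: f.start):
        token = f"{kind.value} {f.start}..{f.end}"
        if f.note:
            token += f'; /note="{f.note}"'
        parts.append(token)
    return "; ".join(parts)


def write_records_tsv(record_set: RecordSet, path_or_stream) -> None:
    """Write a record set in the UniProt TSV export dialect (round-trips
    through :func:`read_records_tsv`)."""
    rows = [
        {
            "Entry": r.accession,
            "Entry Name": r.entry_name,
            "Sequence": r.sequence,
            "Topological domain": render_feature_string(r.features, FeatureKind.TOPO_DOM),
            "Transmembrane": render_feature_string(r.features, FeatureKind.TRANSMEM),
            "Intramembrane": render_feature_string(r.features, FeatureKind.INTRAMEM),
        }
        for r in record_set
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Entry",
            "Entry Name",
            "Sequence",
            "Topological domain",
            "Transmembrane",
            "Intramembrane",
        ],
    ).to_csv(path_or_stream, sep="\t", index=False)


def write_records_json(record_set: RecordSet, stream: IO[str] | None = None) -> str:
    """Serialize a record set to the versioned JSON fixture format."""
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "provenance": record_set.provenance,
        "records": [
            {
                "accession": r.accession,
                "entry_name": r.entry_name,
                "sequence": r.sequence,
                "features": [
                    {"kind": f.kind.value, "start": f.start, "end": f.end, "note": f.note}
                    for f in r.features
                ],
            }
            for r in record_set
        ],
    }
    text = json.dumps(doc, indent=1, sort_keys=True)
    if stream is not None:
        stream.write(text)
    return text


def read_records_json(source) -> RecordSet:
    """Read the JSON fixture format; rejects unknown schema versions."""
    if isinstance(source, str):
        doc = json.loads(source)
    else:
        doc = json.load(source)
    version = doc.get("schema_version")
    if version != JSON_SCHEMA_VERSION:
        raise RecordParseError(
            f"unsupported schema version {version!r} (expected {JSON_SCHEMA_VERSION})"
        )
    records = [
        ProteinRecord(
            accession=r["accession"],
            entry_name=r.get("entry_name", ""),
            sequence=r["sequence"],
            features=[
                TopoFeature(
                    kind=FeatureKind(f["kind"]),
                    start=f["start"],
                    end=f["end"],
                    note=f.get("note", ""),
                )
                for f in r.get("features", [])
            ],
        )
        for r in doc["records"]
    ]
    return RecordSet(records=records, provenance=list(doc.get("provenance", [])))
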