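"""Shared fixtures and a fully independent naive oracle.

The oracle here parses pattern text and checks topology constraints with
its own code — plain loops over start positions and feature intervals —
so census results can be cross-checked against an implementation that
shares nothing with the package's scan path.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as _hyp_settings

from topomotif.records import FeatureKind, ProteinRecord, TopoFeature

_hyp_settings.register_profile("default", derandomize=True, deadline=None)
_hyp_settings.load_profile("default")

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_parse(text: str) -> list[set[str] | None]:
    """Parse pattern text into residue sets (None = wildcard)."""
    out: list[set[str] | None] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "@":
            out.append(None)
            i += 1
        elif c == "[":
            j = text.index("]", i)
            out.append(set(text[i + 1 : j]))
            i = j + 1
        else:
            out.append({c})
            i += 1
    return out


def oracle_scan(pattern_text: str, seq: str, offset: int = 1, anchored: bool = False):
    """All-start-positions scan; returns (start, end, substring) tuples."""
    elements = oracle_parse(pattern_text.upper())
    seq = seq.upper()
    m = len(elements)
    hits = []
    for i in range(len(seq) - m + 1):
        ok = True
        for k, el in enumerate(elements):
            r = seq[i + k]
            if el is None:
                if not r.isalpha():
                    ok = False
                    break
            elif r not in el:
                ok = False
                break
        if ok and (not anchored or i + m == len(seq)):
            hits.append((offset + i, offset + i + m - 1, seq[i : i + m]))
    return hits


def oracle_census_passing(
    records,
    pattern_text: str,
    anchored: bool,
    window_len: int | None,
    require_cytoplasmic: bool,
    min_distance: int | None,
):
    """Independent census: passing (accession, start, end) triples."""
    passing = []
    for rec in records:
        n = len(rec.sequence)
        doms = [f for f in rec.features if f.kind == FeatureKind.TOPO_DOM]
        tms = [
            f
            for f in rec.features
            if f.kind in (FeatureKind.TRANSMEM, FeatureKind.INTRAMEM)
        ]
        covering = [f for f in doms if f.start <= n <= f.end]
        if not covering or not covering[0].note.lower().startswith("cytoplasmic"):
            continue
        lo = 1 if window_len is None or window_len >= n else n - window_len + 1
        for start, end, sub in oracle_scan(pattern_text, rec.sequence, 1, anchored):
            if start < lo:
                continue
            if require_cytoplasmic:
                inside = any(
                    f.start <= start and end <= f.end
                    and f.note.lower().startswith("cytoplasmic")
                    for f in doms
                )
                if not inside:
                    continue
            if min_distance is not None and tms:
                if any(f.start <= end and start <= f.end for f in tms):
                    continue
                gaps = [
                    start - f.end - 1 if f.end < start else f.start - end - 1
                    for f in tms
                ]
                if min(gaps) < min_distance:
                    continue
            passing.append((rec.accession, start, end))
    return sorted(passing)


def make_single_pass(
    accession: str = "P00001",
    nterm: int = 5,
    tm: tuple[int, int] = (6, 26),
    tail_seq: str = "",
    seq_len: int | None = None,
    cterm_note: str = "Cytoplasmic",
) -> ProteinRecord:
    """A single-pass record: extracellular N-term, one TM, annotated tail."""
    tm_start, tm_end = tm
    if tail_seq:
        seq_len = tm_end + len(tail_seq)
    assert seq_len is not None and seq_len > tm_end
    filler = ("GAS" * (seq_len // 3 + 2))[:seq_len]
    seq = filler[:tm_end] + (tail_seq if tail_seq else filler[tm_end:seq_len])
    seq = seq[:seq_len]
    feats = [
        TopoFeature(FeatureKind.TOPO_DOM, 1, tm_start - 1, "Extracellular"),
        TopoFeature(FeatureKind.TRANSMEM, tm_start, tm_end, "Helical"),
        TopoFeature(FeatureKind.TOPO_DOM, tm_end + 1, seq_len, cterm_note),
    ]
    return ProteinRecord(accession=accession, sequence=seq, features=feats)


@pytest.fixture
def single_pass_record() -> ProteinRecord:
    return make_single_pass()
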