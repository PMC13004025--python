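"""Synthetic membrane proteins with known topology and planted motifs.

The generator emulates the annotation structure of plasma-membrane
proteins as the census consumes it: alternating Cytoplasmic /
Extracellular topological domains separated by TRANSMEM segments, a
C-terminal tail on a chosen side of the membrane, and short motifs
planted at controlled sequence distances from the nearest membrane
boundary.  Each generated record carries ground truth, and library-level
truth sets are recomputed by an independent naive scanner so accidental
background matches are part of the truth rather than a source of test
flakiness.

Background residues are drawn from a composition that down-weights
leucine and the aromatic/PDZ class residues (L, F, Y, W, M, V, N at 0.3
relative weight, all other standard residues at 1.0) to keep accidental
motif hits rare but nonzero.

A separate constructor builds fixture records embedding literature
peptides (GLUT4 tail ``TELEYLGP`` at 498, DMT1-II ``QPELYLL`` at 551,
the MOR recycling hexapeptide ``QLENLE`` at 406, and the three screen
hits LTKL/LEVL/LAAL) at their native coordinates inside synthetic
scaffolds, so coordinate-reporting can be checked against published
positions without fetching full native sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .census import PatternSpec, SearchConfig
from .patterns import regex_find_matches
from .records import FeatureKind, MEMBRANE_KINDS, ProteinRecord, RecordSet, TopoFeature

__all__ = [
    "TopologySpec",
    "PlantSpec",
    "GroundTruth",
    "DEFAULT_MIX",
    "generate_protein",
    "generate_library",
    "paper_peptide_fixtures",
    "naive_passing_set",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_DOWNWEIGHTED = set("LFYWMVN")
_WEIGHTS = np.array([0.3 if r in _DOWNWEIGHTED else 1.0 for r in RESIDUES])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

DEFAULT_TM_LEN = 21


@dataclass(frozen=True)
class TopologySpec:
    """Layout of one synthetic membrane protein.

    The sequence tiles as: N-terminal domain, then ``n_tm`` membrane
    segments of ``tm_len`` residues separated by ``loop_lens`` loops,
    then a C-terminal tail of ``tail_len`` on the ``cterm_side`` of the
    membrane.  Domain sidedness alternates; with ``n_tm == 0`` the whole
    chain is a single domain on ``cterm_side``.
    """

    n_tm: int
    tail_len: int
    cterm_side: str = "cytoplasmic"  # or "extracellular"
    tm_len: int = DEFAULT_TM_LEN
    loop_lens: tuple[int, ...] = ()
    nterm_len: int = 30

    def __post_init__(self) -> None:
        if self.cterm_side not in ("cytoplasmic", "extracellular"):
            raise ValueError(f"bad cterm_side {self.cterm_side!r}")
        if self.n_tm < 0 or self.tail_len < 1 or self.tm_len < 1 or self.nterm_len < 0:
            raise ValueError("negative or zero segment length")
        if self.n_tm > 1 and len(self.loop_lens) != self.n_tm - 1:
            raise ValueError(
                f"need {self.n_tm - 1} loop lengths for {self.n_tm} membrane segments"
            )

    @property
    def total_length(self) -> int:
        return (
            self.nterm_len + self.n_tm * self.tm_len + sum(self.loop_lens) + self.tail_len
        )

    def render_features(self) -> list[TopoFeature]:
        """Tile TOPO_DOM / TRANSMEM features over [1, total_length]."""
        note = {"cytoplasmic": "Cytoplasmic", "extracellular": "Extracellular"}
        if self.n_tm == 0:
            return [
                TopoFeature(
                    FeatureKind.TOPO_DOM, 1, self.total_length, note[self.cterm_side]
                )
            ]
        # sides alternate ending on cterm_side; parity fixes the N-term side
        sides = []
        side = self.cterm_side
        for _ in range(self.n_tm + 1):
            sides.append(side)
            side = "extracellular" if side == "cytoplasmic" else "cytoplasmic"
        sides.reverse()
        feats: list[TopoFeature] = []
        pos = 1
        domain_lens = [self.nterm_len, *self.loop_lens, self.tail_len]
        for i, dlen in enumerate(domain_lens):
            if dlen > 0:
                feats.append(
                    TopoFeature(FeatureKind.TOPO_DOM, pos, pos + dlen - 1, note[sides[i]])
                )
                pos += dlen
            if i < self.n_tm:
                feats.append(
                    TopoFeature(FeatureKind.TRANSMEM, pos, pos + self.tm_len - 1, "Helical")
                )
                pos += self.tm_len
        return feats


@dataclass(frozen=True)
class PlantSpec:
    """One motif planted into a cytoplasmic region.

    ``location`` is ``"tail"`` or ``"loop:k"`` (1-based loop index);
    ``distance_from_tm`` is the strict residue gap between the nearest
    membrane boundary and the motif's first residue.
    """

    motif_text: str
    location: str = "tail"
    distance_from_tm: int = 20

    def __post_init__(self) -> None:
        if not self.motif_text or not self.motif_text.isalpha():
            raise ValueError("motif_text must be a non-empty residue string")
        if self.distance_from_tm < 0:
            raise ValueError("distance_from_tm must be non-negative")


@dataclass
class GroundTruth:
    """Planted intervals per record plus oracle-recomputed passing sets."""

    planted: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    passing: dict[str, set[str]] = field(default_factory=dict)  # pattern name -> accessions

    def to_jsonable(self) -> dict:
        return {
            "planted": {
                acc: [[s, e, m] for s, e, m in sorted(v)] for acc, v in sorted(self.planted.items())
            },
            "passing": {name: sorted(accs) for name, accs in sorted(self.passing.items())},
        }


def _plant_interval(topo: TopologySpec, plant: PlantSpec) -> tuple[int, int]:
    """1-based interval where a plant lands, validating room and sidedness."""
    feats = topo.render_features()
    domains = [f for f in feats if f.kind == FeatureKind.TOPO_DOM]
    if plant.location == "tail":
        target = domains[-1]
        upstream_membrane = topo.n_tm > 0
    elif plant.location.startswith("loop:"):
        k = int(plant.location.split(":", 1)[1])
        if not (1 <= k <= max(0, topo.n_tm - 1)):
            raise ValueError(f"no loop {k} in a {topo.n_tm}-segment topology")
        target = domains[k]  # domain 0 is the N-terminal one
        upstream_membrane = True
    else:
        raise ValueError(f"bad plant location {plant.location!r}")
    if target.note != "Cytoplasmic":
        raise ValueError(
            f"plant location {plant.location!r} is {target.note}, not cytoplasmic"
        )
    m = len(plant.motif_text)
    if not upstream_membrane:
        # no membrane: distance is undefined, place at offset from domain start
        start = target.start + plant.distance_from_tm
    else:
        start = target.start + plant.distance_from_tm
    end = start + m - 1
    if end > target.end:
        raise ValueError(
            f"{plant.location} too short for motif at distance "
            f"{plant.distance_from_tm} (domain {target.start}..{target.end})"
        )
    # inner loops: the downstream membrane segment must not sit closer than
    # the requested distance, or the planted distance would not be realized
    if plant.location.startswith("loop:"):
        downstream_gap = target.end - end
        if downstream_gap < plant.distance_from_tm:
            raise ValueError(
                f"loop too short: downstream gap {downstream_gap} < requested "
                f"distance {plant.distance_from_tm}"
            )
    return start, end


def generate_protein(
    seed: int,
    topo: TopologySpec,
    plants: list[PlantSpec] = (),
    accession: str = "SYN00001",
) -> tuple[ProteinRecord, list[tuple[int, int, str]]]:
    """Generate one synthetic record with ``plants`` placed exactly.

    Returns the record and the list of planted (start, end, motif)
    intervals.  Reproducible: the same seed yields the same record.
    """
    rng = np.random.default_rng(seed)
    n = topo.total_length
    seq = list(rng.choice(list(RESIDUES), size=n, p=_WEIGHTS))
    placed: list[tuple[int, int, str]] = []
    for plant in plants:
        start, end = _plant_interval(topo, plant)
        for prev_s, prev_e, _ in placed:
            if start <= prev_e and prev_s <= end:
                raise ValueError("planted motifs overlap")
        seq[start - 1 : end] = list(plant.motif_text.upper())
        placed.append((start, end, plant.motif_text.upper()))
    record = ProteinRecord(
        accession=accession,
        entry_name=f"{accession}_SYN",
        sequence="".join(seq),
        features=topo.render_features(),
    )
    return record, placed


# Archetype mix for library generation.  Proportions must sum to 1.
DEFAULT_MIX: dict[str, float] = {
    "single_pass_cyto_plant": 0.30,  # cytoplasmic tail with a planted LxxL
    "single_pass_cyto": 0.20,
    "single_pass_extracellular": 0.20,
    "multi_pass_cyto_plant": 0.15,
    "multi_pass_cyto": 0.10,
    "no_tm_cyto": 0.05,
}

_PLANT_MOTIFS = ["LENL", "LEYL", "LTKL", "LAAL", "LEVL"]


def _archetype(label: str, rng: np.random.Generator) -> tuple[TopologySpec, list[PlantSpec]]:
    tail = int(rng.integers(40, 90))
    if label == "single_pass_cyto_plant":
        topo = TopologySpec(n_tm=1, tail_len=tail, cterm_side="cytoplasmic")
        dist = int(rng.choice([5, 10, 14, 15, 16, 20, 30]))
        motif = str(rng.choice(_PLANT_MOTIFS))
        return topo, [PlantSpec(motif, "tail", min(dist, tail - len(motif)))]
    if label == "single_pass_cyto":
        return TopologySpec(n_tm=1, tail_len=tail, cterm_side="cytoplasmic"), []
    if label == "single_pass_extracellular":
        return TopologySpec(n_tm=1, tail_len=tail, cterm_side="extracellular"), []
    if label in ("multi_pass_cyto_plant", "multi_pass_cyto"):
        n_tm = int(rng.choice([3, 5, 7]))
        loops = tuple(int(rng.integers(8, 60)) for _ in range(n_tm - 1))
        topo = TopologySpec(n_tm=n_tm, tail_len=tail, cterm_side="cytoplasmic", loop_lens=loops)
        if label == "multi_pass_cyto":
            return topo, []
        motif = str(rng.choice(_PLANT_MOTIFS))
        dist = int(rng.choice([5, 14, 15, 25]))
        return topo, [PlantSpec(motif, "tail", min(dist, tail - len(motif)))]
    if label == "no_tm_cyto":
        return TopologySpec(n_tm=0, tail_len=int(rng.integers(60, 150)), cterm_side="cytoplasmic"), []
    raise ValueError(f"unknown archetype {label!r}")


def generate_library(
    seed: int,
    n: int,
    mix: dict[str, float] | None = None,
    patterns: list[PatternSpec] | None = None,
    config: SearchConfig = SearchConfig(),
) -> tuple[RecordSet, GroundTruth]:
    """Generate ``n`` records drawn from an archetype ``mix``.

    Truth passing sets are recomputed with the naive oracle under
    ``config`` for every pattern in ``patterns`` (defaults to the five
    packaged patterns), so accidental background matches are included and
    the truth is exact by construction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mix proportions sum to {total}, not 1")
    if patterns is None:
        from .census import default_patterns

        patterns = default_patterns()
    rng = np.random.default_rng(seed)
    labels = sorted(mix)
    probs = np.array([mix[l] for l in labels])
    truth = GroundTruth()
    records = []
    for i in range(n):
        label = str(rng.choice(labels, p=probs))
        acc = f"SYN{i + 1:05d}"
        topo, plants = _archetype(label, rng)
        child_seed = int(rng.integers(0, 2**31 - 1))
        record, placed = generate_protein(child_seed, topo, plants, accession=acc)
        records.append(record)
        truth.planted[acc] = placed
    record_set = RecordSet(records=records, provenance=[f"generate_library(seed={seed}, n={n})"])
    for spec in patterns:
        truth.passing[spec.name] = naive_passing_set(record_set, spec, config)
    return record_set, truth


def naive_passing_set(
    record_set: RecordSet, spec: PatternSpec, config: SearchConfig = SearchConfig()
) -> set[str]:
    """Independent oracle: regex overlap scan plus direct interval checks.

    Re-derives the cytoplasmic-tail filter, C-terminal window, domain
    containment and membrane distance straight from the feature lists,
    sharing no code with the pipeline's scan path.
    """
    passing: set[str] = set()
    min_dist = config.min_membrane_distance  # the census-wide hard floor only
    for record in record_set:
        n = len(record.sequence)
        topo_doms = [f for f in record.features if f.kind == FeatureKind.TOPO_DOM]
        # cytoplasmic C terminus
        tail_dom = next((f for f in topo_doms if f.start <= n <= f.end), None)
        if tail_dom is None or not tail_dom.note.lower().startswith("cytoplasmic"):
            continue
        window_start = 1
        if config.window_len is not None and config.window_len < n:
            window_start = n - config.window_len + 1
        membranes = [f for f in record.features if f.kind in MEMBRANE_KINDS]
        for m in regex_find_matches(spec.pattern, record.sequence, offset=1):
            if m.start < window_start:
                continue
            if spec.pattern.anchor_cterm and m.end != n:
                continue
            if config.require_cytoplasmic_match:
                ok = any(
                    f.start <= m.start and m.end <= f.end
                    and f.note.lower().startswith("cytoplasmic")
                    for f in topo_doms
                )
                if not ok:
                    continue
            if min_dist is not None and membranes:
                if any(f.start <= m.end and m.start <= f.end for f in membranes):
                    continue  # distance 0 inside a membrane segment
                gaps = [
                    m.start - f.end - 1 if f.end < m.start else f.start - m.end - 1
                    for f in membranes
                ]
                if min(gaps) < min_dist:
                    continue
            passing.add(record.accession)
            break
    return passing


# Literature peptides embedded at their native coordinates.  The scaffold
# filler is a fixed GAS repeat: it contains none of the residues that the
# five motif classes key on, so every motif hit in these fixtures comes
# from the embedded peptide (or its junction with the filler).
_PEPTIDE_FIXTURES = [
    # (accession, entry name, peptide, 1-based start of peptide)
    ("SYNGLUT4", "GLUT4_SYNTH", "TELEYLGP", 498),
    ("SYNDMT1II", "DMT1II_SYNTH", "QPELYLL", 551),
    ("SYNMOR", "MOR_SYNTH", "QLENLE", 406),
    ("SYNACY9", "ACY9_SYNTH", "LTKL", 1344),
    ("SYNS12A7", "S12A7_SYNTH", "LEVL", 1058),
    ("SYNPLXA1", "PLXNA1_SYNTH", "LAAL", 1867),
]


def paper_peptide_fixtures() -> RecordSet:
    """Synthetic full-length records embedding published peptides.

    Each record places its peptide at the published coordinate inside a
    single-pass scaffold whose transmembrane segment ends far enough
    upstream that the motif clears the 15-residue membrane-distance
    floor.  Coordinates, not native sequence context, are what these
    fixtures certify.
    """
    records = []
    for acc, entry_name, peptide, start in _PEPTIDE_FIXTURES:
        end = start + len(peptide) - 1
        total = end  # peptide runs to the C terminus
        tm_end = start - 25  # clears the 15-residue distance floor
        tm_start = tm_end - DEFAULT_TM_LEN + 1
        filler = ("GAS" * (total // 3 + 1))[:total]
        seq = filler[: start - 1] + peptide + filler[end:]
        seq = seq[:total]
        features = [
            TopoFeature(FeatureKind.TOPO_DOM, 1, tm_start - 1, "Extracellular"),
            TopoFeature(FeatureKind.TRANSMEM, tm_start, tm_end, "Helical"),
            TopoFeature(FeatureKind.TOPO_DOM, tm_end + 1, total, "Cytoplasmic"),
        ]
        records.append(
            ProteinRecord(
                accession=acc, entry_name=entry_name, sequence=seq, features=features
            )
        )
    return RecordSet(records=records, provenance=["paper_peptide_fixtures"])
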