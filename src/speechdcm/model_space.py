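"""Model space for effective connectivity of speech-sound prediction.

The hypothesis space covers a bilateral fronto-temporal network of up to ten
sources -- primary auditory cortex (A1), Wernicke's area (W), Geschwind's
territory (G), Broca's area (B) and the supplementary motor area (SMA) in
each hemisphere -- wired along the arcuate fasciculus (A1-W-G-B, plus the
direct W-B segment) and the frontal aslant (B-SMA).

Each hemisphere independently realises one of five pathway levels:

====== ==========================================================
level  forward edges added in that hemisphere
====== ==========================================================
L0     none (A1 only)
L1     A1->W
L2     A1->W, W->B            (arcuate, direct segment only)
L3a    A1->W, W->G, G->B      (arcuate, indirect segments only)
L3b    A1->W, W->G, G->B, W->B (arcuate, direct and indirect)
====== ==========================================================

Constraints: the two "level 3" variants are never mixed across hemispheres,
and an SMA (aslant) extension may only hang off a hemisphere that realises
the deepest pathway present in the model (and at least L2, so that B exists).
These rules yield exactly 48 structures; each is instantiated twice -- once
with condition effects on forward connections only and once on forward and
backward connections -- giving 96 models in five families.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field


class Region(str, enum.Enum):
    A1 = "A1"
    W = "W"
    G = "G"
    B = "B"
    SMA = "SMA"


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Level(str, enum.Enum):
    """Per-hemisphere pathway depth."""

    L0 = "L0"
    L1 = "L1"
    L2 = "L2"
    L3A = "L3a"
    L3B = "L3b"

    @property
    def rank(self) -> int:
        return {"L0": 0, "L1": 1, "L2": 2, "L3a": 3, "L3b": 3}[self.value]


class Modulation(str, enum.Enum):
    FORWARD_ONLY = "forward_only"
    FORWARD_AND_BACKWARD = "forward_and_backward"


class Family(str, enum.Enum):
    NULL = "null"
    ARC_DIRECT = "arc_direct"
    ARC_DIR_IND = "arc_dir_ind"
    ARCASLANT_DIRECT = "arcaslant_direct"
    ARCASLANT_DIR_IND = "arcaslant_dir_ind"


class EdgeKind(str, enum.Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    INPUT = "input"
    INTRINSIC_MODULATED = "intrinsic_modulated"


#: hierarchy depth of each region (A1 lowest, SMA highest)
HIERARCHY_DEPTH = {Region.A1: 1, Region.W: 2, Region.G: 3, Region.B: 4, Region.SMA: 5}

#: mean MNI coordinates (mm) of the ten sources
MNI_COORDS = {
    (Region.A1, Hemisphere.LEFT): (-52, -19, 7),
    (Region.A1, Hemisphere.RIGHT): (50, -21, 7),
    (Region.W, Hemisphere.LEFT): (-57, -20, 1),
    (Region.W, Hemisphere.RIGHT): (54, -19, 1),
    (Region.G, Hemisphere.LEFT): (-53, -32, 33),
    (Region.G, Hemisphere.RIGHT): (51, -33, 34),
    (Region.B, Hemisphere.LEFT): (-48, 13, 17),
    (Region.B, Hemisphere.RIGHT): (49, 12, 17),
    (Region.SMA, Hemisphere.LEFT): (-28, -2, 52),
    (Region.SMA, Hemisphere.RIGHT): (28, -1, 51),
}

#: forward chains realised by each level (within one hemisphere)
_LEVEL_FORWARD = {
    Level.L0: (),
    Level.L1: ((Region.A1, Region.W),),
    Level.L2: ((Region.A1, Region.W), (Region.W, Region.B)),
    Level.L3A: ((Region.A1, Region.W), (Region.W, Region.G), (Region.G, Region.B)),
    Level.L3B: (
        (Region.A1, Region.W),
        (Region.W, Region.G),
        (Region.G, Region.B),
        (Region.W, Region.B),
    ),
}


@dataclass(frozen=True)
class NodeSpec:
    region: Region
    hemisphere: Hemisphere
    mni: tuple[int, int, int]
    hierarchy_depth: int

    @property
    def name(self) -> str:
        return f"{self.hemisphere.value[0].upper()}{self.region.value}"


def node_table() -> list[NodeSpec]:
    """The ten network nodes: left hemisphere first, ascending hierarchy."""
    nodes = []
    for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
        for region in sorted(Region, key=lambda r: HIERARCHY_DEPTH[r]):
            nodes.append(
                NodeSpec(
                    region=region,
                    hemisphere=hemi,
                    mni=MNI_COORDS[(region, hemi)],
                    hierarchy_depth=HIERARCHY_DEPTH[region],
                )
            )
    return nodes


def node_index(region: Region, hemisphere: Hemisphere) -> int:
    """Position of a node in the canonical node_table ordering."""
    hemi_off = 0 if hemisphere is Hemisphere.LEFT else 5
    return hemi_off + HIERARCHY_DEPTH[region] - 1


@dataclass(frozen=True)
class StructureSpec:
    level_left: Level
    level_right: Level
    sma_left: bool = False
    sma_right: bool = False

    def __post_init__(self) -> None:
        err = self._violation()
        if err:
            raise ValueError(err)

    def _violation(self) -> str | None:
        levels = {self.level_left, self.level_right}
        if levels == {Level.L3A, Level.L3B}:
            return "L3a and L3b may not be mixed across hemispheres"
        max_rank = max(self.level_left.rank, self.level_right.rank)
        for sma, level in ((self.sma_left, self.level_left), (self.sma_right, self.level_right)):
            if sma and (level.rank < 2 or level.rank != max_rank):
                return "SMA only allowed on a maximal-level hemisphere with level >= L2"
        return None

    @property
    def max_level_rank(self) -> int:
        return max(self.level_left.rank, self.level_right.rank)

    @property
    def has_sma(self) -> bool:
        return self.sma_left or self.sma_right

    def as_tuple(self) -> tuple[str, str, bool, bool]:
        return (self.level_left.value, self.level_right.value, self.sma_left, self.sma_right)


@dataclass(frozen=True)
class ModelSpec:
    structure: StructureSpec
    modulation: Modulation
    model_id: int
    family: Family

    @property
    def label(self) -> str:
        s = self.structure
        sma = "".join(h for h, f in (("L", s.sma_left), ("R", s.sma_right)) if f) or "-"
        mod = "F" if self.modulation is Modulation.FORWARD_ONLY else "FB"
        return f"{s.level_left.value}/{s.level_right.value}/sma:{sma}/{mod}"


@dataclass(frozen=True)
class EdgeSpec:
    source: NodeSpec
    target: NodeSpec
    kind: EdgeKind


_LEVEL_ORDER = [Level.L0, Level.L1, Level.L2, Level.L3A, Level.L3B]


def enumerate_structures() -> list[StructureSpec]:
    """All 48 valid structures in canonical lexicographic order."""
    out = []
    for ll, lr, sl, sr in itertools.product(_LEVEL_ORDER, _LEVEL_ORDER, (False, True), (False, True)):
        try:
            out.append(StructureSpec(ll, lr, sl, sr))
        except ValueError:
            continue
    return out


def family_of(structure: StructureSpec) -> Family:
    """Family label as a pure function of the structure.

    Classification is by the deepest arcuate pathway present anywhere in the
    model (L2 = direct-only, L3* = includes the indirect G route) crossed
    with whether any aslant (SMA) extension exists.
    """
    rank = structure.max_level_rank
    if rank <= 1:
        return Family.NULL
    if rank == 2:
        return Family.ARCASLANT_DIRECT if structure.has_sma else Family.ARC_DIRECT
    return Family.ARCASLANT_DIR_IND if structure.has_sma else Family.ARC_DIR_IND


def expand_models() -> list[ModelSpec]:
    """The 96 models: each structure twice, forward-only then forward+backward."""
    models = []
    mid = 1
    for structure in enumerate_structures():
        fam = family_of(structure)
        for mod in (Modulation.FORWARD_ONLY, Modulation.FORWARD_AND_BACKWARD):
            models.append(ModelSpec(structure=structure, modulation=mod, model_id=mid, family=fam))
            mid += 1
    return models


def _hemisphere_forward_pairs(level: Level, sma: bool) -> list[tuple[Region, Region]]:
    pairs = list(_LEVEL_FORWARD[level])
    if sma:
        pairs.append((Region.B, Region.SMA))
    return pairs


def edges_of(model: ModelSpec) -> list[EdgeSpec]:
    """Full edge list: forward + matching backward extrinsic edges, stimulus
    input edges into both A1, and intrinsic-modulation self-edges at A1.

    Backward edges are always structurally present as reversals of the
    forward set; the model's `modulation` field decides which of them carry
    condition-dependent gains (see :func:`modulated_edge_pairs`).
    """
    nodes = {(n.region, n.hemisphere): n for n in node_table()}
    edges: list[EdgeSpec] = []
    s = model.structure
    for hemi, level, sma in (
        (Hemisphere.LEFT, s.level_left, s.sma_left),
        (Hemisphere.RIGHT, s.level_right, s.sma_right),
    ):
        for src, tgt in _hemisphere_forward_pairs(level, sma):
            edges.append(EdgeSpec(nodes[(src, hemi)], nodes[(tgt, hemi)], EdgeKind.FORWARD))
    # backward set = exact reversal of the forward set
    edges.extend(
        EdgeSpec(e.target, e.source, EdgeKind.BACKWARD)
        for e in list(edges)
        if e.kind is EdgeKind.FORWARD
    )
    for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
        a1 = nodes[(Region.A1, hemi)]
        edges.append(EdgeSpec(a1, a1, EdgeKind.INPUT))
        edges.append(EdgeSpec(a1, a1, EdgeKind.INTRINSIC_MODULATED))
    return edges


def modulated_edge_pairs(model: ModelSpec) -> list[tuple[int, int, EdgeKind]]:
    """(source_index, target_index, kind) of extrinsic edges whose gains
    change between conditions under this model's modulation scheme."""
    kinds = {EdgeKind.FORWARD}
    if model.modulation is Modulation.FORWARD_AND_BACKWARD:
        kinds.add(EdgeKind.BACKWARD)
    return [
        (node_index(e.source.region, e.source.hemisphere), node_index(e.target.region, e.target.hemisphere), e.kind)
        for e in edges_of(model)
        if e.kind in kinds
    ]


@dataclass
class FamilyPartition:
    scheme: str
    groups: dict[str, list[int]] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in self.groups.items()}

    @property
    def model_ids(self) -> list[int]:
        return sorted(itertools.chain.from_iterable(self.groups.values()))


_FIVE_FAMILY_ORDER = [
    Family.NULL,
    Family.ARC_DIRECT,
    Family.ARC_DIR_IND,
    Family.ARCASLANT_DIRECT,
    Family.ARCASLANT_DIR_IND,
]


def build_partitions(models: list[ModelSpec] | None = None) -> list[FamilyPartition]:
    """The four family partitions used for group-level inference.

    - ``fwd_vs_fwdbwd``: 48 forward-only vs 48 forward+backward models.
    - ``five_families``: Null / Arcuate-direct / Arcuate-dir+ind /
      Arcuate-Aslant-direct / Arcuate-Aslant-dir+ind (8/10/28/14/36).
    - ``arcuate_vs_arcaslant``: 38 arcuate-only vs 50 aslant-extended models
      (Null family excluded).
    - ``geschwind_vs_none``: 64 models routing through Geschwind's territory
      vs 24 direct-only models (Null family excluded).
    """
    if models is None:
        models = expand_models()

    fwd = [m.model_id for m in models if m.modulation is Modulation.FORWARD_ONLY]
    fwdbwd = [m.model_id for m in models if m.modulation is Modulation.FORWARD_AND_BACKWARD]
    by_family = {fam: [m.model_id for m in models if m.family is fam] for fam in Family}

    return [
        FamilyPartition("fwd_vs_fwdbwd", {"forward": fwd, "forward_and_backward": fwdbwd}),
        FamilyPartition(
            "five_families", {fam.value: by_family[fam] for fam in _FIVE_FAMILY_ORDER}
        ),
        FamilyPartition(
            "arcuate_vs_arcaslant",
            {
                "arcuate": sorted(by_family[Family.ARC_DIRECT] + by_family[Family.ARC_DIR_IND]),
                "arcaslant": sorted(
                    by_family[Family.ARCASLANT_DIRECT] + by_family[Family.ARCASLANT_DIR_IND]
                ),
            },
        ),
        FamilyPartition(
            "geschwind_vs_none",
            {
                "geschwind": sorted(
                    by_family[Family.ARC_DIR_IND] + by_family[Family.ARCASLANT_DIR_IND]
                ),
                "no_geschwind": sorted(
                    by_family[Family.ARC_DIRECT] + by_family[Family.ARCASLANT_DIRECT]
                ),
            },
        ),
    ]


def get_partition(scheme: str, models: list[ModelSpec] | None = None) -> FamilyPartition:
    for p in build_partitions(models):
        if p.scheme == scheme:
            return p
    raise KeyError(f"unknown partition scheme: {scheme!r}")


def model_by_id(model_id: int) -> ModelSpec:
    models = expand_models()
    if not 1 <= model_id <= len(models):
        raise KeyError(f"model_id out of range: {model_id}")
    return models[model_id - 1]


def find_model(
    level_left: Level | str,
    level_right: Level | str,
    sma_left: bool = False,
    sma_right: bool = False,
    modulation: Modulation | str = Modulation.FORWARD_AND_BACKWARD,
) -> ModelSpec:
    """Look up a model by its defining tuple."""
    structure = StructureSpec(Level(level_left), Level(level_right), sma_left, sma_right)
    modulation = Modulation(modulation)
    for m in expand_models():
        if m.structure == structure and m.modulation is modulation:
            return m
    raise KeyError("no such model")


def export_models(fmt: str = "json") -> str:
    """Serialise the model space (one row per model with its edge list)."""
    rows = []
    for m in expand_models():
        rows.append(
            {
                "model_id": m.model_id,
                "level_left": m.structure.level_left.value,
                "level_right": m.structure.level_right.value,
                "sma_left": m.structure.sma_left,
                "sma_right": m.structure.sma_right,
                "modulation": m.modulation.value,
                "family": m.family.value,
                "edges": [
                    {
                        "source_region": e.source.region.value,
                        "source_hemisphere": e.source.hemisphere.value,
                        "target_region": e.target.region.value,
                        "target_hemisphere": e.target.hemisphere.value,
                        "kind": e.kind.value,
                    }
                    for e in edges_of(m)
                ],
            }
        )
    if fmt == "json":
        return json.dumps(rows, indent=2)
    if fmt == "csv":
        lines = ["model_id,level_left,level_right,sma_left,sma_right,modulation,family,n_edges"]
        for r in rows:
            lines.append(
                f"{r['model_id']},{r['level_left']},{r['level_right']},"
                f"{int(r['sma_left'])},{int(r['sma_right'])},{r['modulation']},"
                f"{r['family']},{len(r['edges'])}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format: {fmt!r}")


def node_table_tsv() -> str:
    lines = ["region\themisphere\tx\ty\tz"]
    for n in node_table():
        lines.append(f"{n.region.value}\t{n.hemisphere.value}\t{n.mni[0]}\t{n.mni[1]}\t{n.mni[2]}")
    return "\n".join(lines) + "\n"


def audit_counts() -> dict[str, int]:
    """Model-space census: total, per-modulation and per-family counts."""
    models = expand_models()
    parts = {p.scheme: p for p in build_partitions(models)}
    counts = {
        "n_structures": len(enumerate_structures()),
        "n_models": len(models),
        "n_forward_only": len(parts["fwd_vs_fwdbwd"].groups["forward"]),
        "n_forward_and_backward": len(parts["fwd_vs_fwdbwd"].groups["forward_and_backward"]),
    }
    for name, ids in parts["five_families"].groups.items():
        counts[f"family_{name}"] = len(ids)
    counts["family_arcuate"] = len(parts["arcuate_vs_arcaslant"].groups["arcuate"])
    counts["family_arcaslant"] = len(parts["arcuate_vs_arcaslant"].groups["arcaslant"])
    counts["family_geschwind"] = len(parts["geschwind_vs_none"].groups["geschwind"])
    counts["family_no_geschwind"] = len(parts["geschwind_vs_none"].groups["no_geschwind"])
    return counts
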