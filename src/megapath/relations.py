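"""Literature-derived regulatory relations and polarity-consistent network filtering.

A relation table encodes directed literature edges (source regulates target,
with a positive or negative polarity) between genes, a driver gene and a
disease label. From these edges two candidate gene sets are mined:

* ``promoted_inhibitors`` — genes promoted by the driver that themselves
  inhibit the disease (driver →+ gene and gene ⊣ disease);
* ``contra_directional`` — genes on which the driver and the disease act
  with opposite polarity (driver →+ gene and disease ⊣ gene, or
  driver ⊣ gene and disease →+ gene).

Candidates are then filtered against pooled expression statistics: a gene
survives only when its pooled log2 fold-change is significant at the chosen
alpha AND its sign is consistent with the literature polarity (a gene the
driver promotes while the driver itself is suppressed in disease must go
down; a gene the driver suppresses must go up).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .meta import MetaResult

logger = logging.getLogger(__name__)

RELATION_COLUMNS = ("source", "target", "polarity", "relation_type", "refs")


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class RelationType(str, Enum):
    EXPRESSION_REGULATION = "expression-regulation"
    ACTIVATION_INHIBITION = "activation-inhibition"
    OTHER = "other"


class Category(str, Enum):
    """Final network-gene categories."""

    PROMOTED_INHIBITOR_DOWN = "promoted_inhibitor_down"
    CONTRA_DOWN = "contra_down"
    CONTRA_UP = "contra_up"


def normalize_symbol(name: str) -> str:
    """Trim and upper-case an entity name (literature exports mix cases)."""
    return name.strip().upper()


@dataclass(frozen=True)
class RelationTriple:
    """One directed literature edge with polarity and supporting references."""

    source: str
    target: str
    polarity: Polarity
    relation_type: RelationType = RelationType.OTHER
    refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", normalize_symbol(self.source))
        object.__setattr__(self, "target", normalize_symbol(self.target))
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        object.__setattr__(self, "relation_type", RelationType(self.relation_type))
        if self.source == self.target:
            raise ValueError(f"self-relation not allowed: {self.source}")


@dataclass(frozen=True)
class CandidateSets:
    """Driver/disease candidate genes split by the polarity pattern that matched.

    ``contra_down`` holds genes the driver promotes while the disease inhibits
    them (expected to drop with the driver); ``contra_up`` genes the driver
    inhibits while the disease promotes them (expected to rise).
    """

    promoted_inhibitors: frozenset[str]
    contra_down: frozenset[str]
    contra_up: frozenset[str]

    @property
    def contra_directional(self) -> frozenset[str]:
        return self.contra_down | self.contra_up

    def __post_init__(self) -> None:
        if self.promoted_inhibitors & self.contra_directional:
            raise ValueError("promoted_inhibitors must be disjoint from contra sets")


@dataclass(frozen=True)
class NetworkGene:
    """A candidate retained in the final driver–disease connecting network."""

    gene: str
    category: Category
    lfc: float
    p_value: float


class RelationTableError(ValueError):
    """Malformed relation table (bad header, polarity token, or self-edge)."""


def load_relations(path: str | Path) -> list[RelationTriple]:
    """Load a tab-separated relation table.

    Expected header: ``source  target  polarity  relation_type  refs``.
    Polarity tokens must be ``positive`` or ``negative``; anything else is a
    :class:`RelationTableError` naming the offending line. ``refs`` is a
    ``;``-separated free-text list and may be empty. Unknown relation-type
    tokens are mapped to ``other``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise RelationTableError(f"{path}: empty relation table (no header)")
        missing = set(RELATION_COLUMNS[:4]) - set(reader.fieldnames)
        if missing:
            raise RelationTableError(f"{path}: missing columns {sorted(missing)}")
        triples: list[RelationTriple] = []
        for lineno, row in enumerate(reader, start=2):
            pol = (row["polarity"] or "").strip().lower()
            if pol not in (Polarity.POSITIVE.value, Polarity.NEGATIVE.value):
                raise RelationTableError(
                    f"{path}:{lineno}: unknown polarity token {row['polarity']!r}"
                )
            rtype = (row.get("relation_type") or "").strip().lower()
            try:
                rel_type = RelationType(rtype)
            except ValueError:
                rel_type = RelationType.OTHER
            refs = tuple(
                r.strip() for r in (row.get("refs") or "").split(";") if r.strip()
            )
            try:
                triples.append(
                    RelationTriple(row["source"], row["target"], Polarity(pol), rel_type, refs)
                )
            except ValueError as exc:
                raise RelationTableError(f"{path}:{lineno}: {exc}") from exc
    return triples


def write_relations(triples: Iterable[RelationTriple], path: str | Path) -> None:
    """Write a relation table in the dialect :func:`load_relations` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(RELATION_COLUMNS) + "\n")
        for t in triples:
            fh.write(
                f"{t.source}\t{t.target}\t{t.polarity.value}\t"
                f"{t.relation_type.value}\t{';'.join(t.refs)}\n"
            )


def candidate_sets(
    relations: Iterable[RelationTriple],
    driver: str,
    disease: str,
    restrict_types: Iterable[RelationType | str] | None = None,
) -> CandidateSets:
    """Mine driver/disease candidate gene sets from literature edges.

    Parameters
    ----------
    relations
        Literature edges. Duplicates are harmless (set semantics).
    driver, disease
        Entity names; compared case-insensitively after trimming. The driver
        must occur in the relations, otherwise a ``ValueError`` is raised.
    restrict_types
        Optional whitelist of relation types admitted to the set logic.
        Default is permissive (all types participate).

    A gene qualifying for both the promoted-inhibitor and a contra pattern is
    assigned to ``promoted_inhibitors`` only (the two published sets form a
    partition). A gene matching both contra patterns is assigned
    ``contra_down`` with a warning.
    """
    driver = normalize_symbol(driver)
    disease = normalize_symbol(disease)
    admitted: set[RelationType] | None = None
    if restrict_types is not None:
        admitted = {RelationType(t) for t in restrict_types}

    rels = [
        t
        for t in relations
        if admitted is None or t.relation_type in admitted
    ]
    if not any(driver in (t.source, t.target) for t in rels):
        raise ValueError(f"driver {driver!r} absent from relation table")

    driver_pos = {t.target for t in rels if t.source == driver and t.polarity is Polarity.POSITIVE}
    driver_neg = {t.target for t in rels if t.source == driver and t.polarity is Polarity.NEGATIVE}
    inhibits_disease = {
        t.source for t in rels if t.target == disease and t.polarity is Polarity.NEGATIVE
    }
    disease_pos = {t.target for t in rels if t.source == disease and t.polarity is Polarity.POSITIVE}
    disease_neg = {t.target for t in rels if t.source == disease and t.polarity is Polarity.NEGATIVE}

    promoted = (driver_pos & inhibits_disease) - {disease}
    contra_down = (driver_pos & disease_neg) - promoted - {disease}
    contra_up = (driver_neg & disease_pos) - promoted - {disease}
    both = contra_down & contra_up
    if both:
        logger.warning(
            "genes matching both contra patterns assigned contra_down: %s",
            sorted(both),
        )
        contra_up -= both
    return CandidateSets(frozenset(promoted), frozenset(contra_down), frozenset(contra_up))


def classify_network(
    candidates: CandidateSets,
    meta: Mapping[str, "MetaResult"],
    alpha: float = 0.05,
) -> list[NetworkGene]:
    """Filter candidates by pooled significance and polarity-consistent direction.

    A candidate is retained iff its pooled two-sided p-value is below
    ``alpha`` and the sign of its pooled log2 fold-change matches the
    literature expectation: promoted inhibitors and contra_down genes must be
    down-regulated (lfc < 0), contra_up genes up-regulated (lfc > 0).
    Candidates with no pooled result (not measured on enough platforms) are
    dropped with a warning. Output is sorted by gene symbol.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    meta_norm = {normalize_symbol(g): r for g, r in meta.items()}
    out: list[NetworkGene] = []
    rules = (
        (candidates.promoted_inhibitors, Category.PROMOTED_INHIBITOR_DOWN, -1),
        (candidates.contra_down, Category.CONTRA_DOWN, -1),
        (candidates.contra_up, Category.CONTRA_UP, +1),
    )
    missing: list[str] = []
    for genes, category, sign in rules:
        for g in genes:
            res = meta_norm.get(g)
            if res is None:
                missing.append(g)
                continue
            if res.p_value < alpha and res.pooled_lfc * sign > 0:
                out.append(NetworkGene(g, category, res.pooled_lfc, res.p_value))
    if missing:
        logger.warning("%d candidate gene(s) without pooled statistics dropped: %s",
                       len(missing), sorted(missing))
    return sorted(out, key=lambda n: n.gene)


def write_network(network: Iterable[NetworkGene], path: str | Path) -> None:
    """Write the classified network as TSV (gene, category, lfc, p_value)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tcategory\tlfc\tp_value\n")
        for n in network:
            fh.write(f"{n.gene}\t{n.category.value}\t{n.lfc:.6g}\t{n.p_value:.6g}\n")


def to_graphml(
    relations: Iterable[RelationTriple], network: Iterable[NetworkGene], path: str | Path
) -> None:
    """Optional GraphML export of the classified network (requires networkx)."""
    import networkx as nx

    keep = {n.gene: n for n in network}
    g = nx.DiGraph()
    for gene, rec in keep.items():
        g.add_node(gene, category=rec.category.value, lfc=rec.lfc, p_value=rec.p_value)
    for t in relations:
        if t.source in keep or t.target in keep:
            g.add_edge(t.source, t.target, polarity=t.polarity.value,
                       relation_type=t.relation_type.value)
    nx.write_graphml(g, str(path))
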