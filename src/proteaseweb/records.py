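"""Domain records for protease-web datasets.

A dataset is three tables: proteins (with role and class annotations),
cleavages (protease -> substrate, with a curated physiological-relevance
label), and inhibitions (inhibitor -> target protease).  Accessions are
opaque unique identifiers; no external namespace (UniProt, MEROPS) is
validated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CATALYTIC_CLASSES",
    "INHIBITOR_CLASSES",
    "ROLES",
    "ProteinRecord",
    "CleavageRecord",
    "InhibitionRecord",
    "ValidationError",
    "validate_records",
]

#: MEROPS-style catalytic classes: aspartic, cysteine, metallo, serine,
#: threonine.  "none" marks non-protease proteins.
CATALYTIC_CLASSES = frozenset({"A", "C", "M", "S", "T", "none"})

#: Inhibitor class labels mirror the protease classes they act on, plus
#: "broad" for inhibitors annotated against more than one class.
INHIBITOR_CLASSES = frozenset({"A", "C", "M", "S", "T", "broad"})

ROLES = frozenset({"protease", "inhibitor", "substrate_only"})

RELEVANCE_LEVELS = frozenset({"yes", "no", "unknown"})


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """An annotated protein node.

    A protein is a protease and/or inhibitor when it carries a MEROPS-style
    identifier; everything else participating only as a cleavage target is
    ``substrate_only``.  Trap inhibitors (alpha-2-macroglobulin / PZP style)
    physically cage proteases of any catalytic class upon bait cleavage.
    """

    accession: str
    gene_name: str = ""
    merops_id: str | None = None
    roles: frozenset[str] = field(default_factory=frozenset)
    catalytic_class: str = "none"
    inhibitor_classes: frozenset[str] = field(default_factory=frozenset)
    trap_inhibitor: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        bad = self.roles - ROLES
        if bad:
            raise ValidationError(
                f"{self.accession}: unknown roles {sorted(bad)}"
            )
        if self.catalytic_class not in CATALYTIC_CLASSES:
            raise ValidationError(
                f"{self.accession}: unknown catalytic class "
                f"{self.catalytic_class!r}"
            )
        bad = self.inhibitor_classes - INHIBITOR_CLASSES
        if bad:
            raise ValidationError(
                f"{self.accession}: unknown inhibitor classes {sorted(bad)}"
            )
        if "protease" in self.roles and self.catalytic_class == "none":
            raise ValidationError(
                f"{self.accession}: protease role requires a catalytic class"
            )
        if "inhibitor" in self.roles and not self.inhibitor_classes:
            raise ValidationError(
                f"{self.accession}: inhibitor role requires inhibitor classes"
            )
        if self.trap_inhibitor and "inhibitor" not in self.roles:
            raise ValidationError(
                f"{self.accession}: trap_inhibitor flag requires inhibitor role"
            )

    @property
    def is_protease(self) -> bool:
        return "protease" in self.roles

    @property
    def is_inhibitor(self) -> bool:
        return "inhibitor" in self.roles

    def to_node_attrs(self) -> dict:
        """Scalar node attributes, safe for GraphML/GML round trips."""
        return {
            "gene_name": self.gene_name,
            "merops_id": self.merops_id or "",
            "roles": ";".join(sorted(self.roles)),
            "catalytic_class": self.catalytic_class,
            "inhibitor_classes": ";".join(sorted(self.inhibitor_classes)),
            "trap_inhibitor": int(self.trap_inhibitor),
        }

    @classmethod
    def from_node_attrs(cls, accession: str, attrs: dict) -> "ProteinRecord":
        merops = attrs.get("merops_id", "") or None
        roles = frozenset(r for r in str(attrs.get("roles", "")).split(";") if r)
        inh = frozenset(
            c for c in str(attrs.get("inhibitor_classes", "")).split(";") if c
        )
        return cls(
            accession=accession,
            gene_name=attrs.get("gene_name", ""),
            merops_id=merops,
            roles=roles,
            catalytic_class=attrs.get("catalytic_class", "none"),
            inhibitor_classes=inh,
            trap_inhibitor=bool(int(attrs.get("trap_inhibitor", 0))),
        )


@dataclass(frozen=True)
class CleavageRecord:
    """A directed cleavage: protease cuts substrate.

    ``physiological_relevance`` is the curated in-vivo-likelihood label
    ("yes", "no", "unknown") used by the high-confidence filter.
    """

    protease_acc: str
    substrate_acc: str
    physiological_relevance: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if self.physiological_relevance not in RELEVANCE_LEVELS:
            raise ValidationError(
                f"cleavage {self.protease_acc}->{self.substrate_acc}: "
                f"bad relevance {self.physiological_relevance!r}"
            )


@dataclass(frozen=True)
class InhibitionRecord:
    """A directed inhibition: inhibitor blocks a target protease."""

    inhibitor_acc: str
    protease_acc: str


def validate_records(
    proteins: list[ProteinRecord],
    cleavages: list[CleavageRecord],
    inhibitions: list[InhibitionRecord],
) -> None:
    """Cross-record referential and role checks.

    Raises :class:`ValidationError` on duplicate accessions, edges whose
    source lacks the required role, or edges referencing unknown proteins.
    """
    by_acc: dict[str, ProteinRecord] = {}
    for rec in proteins:
        if rec.accession in by_acc:
            raise ValidationError(f"duplicate accession {rec.accession!r}")
        by_acc[rec.accession] = rec

    for i, clv in enumerate(cleavages):
        for acc in (clv.protease_acc, clv.substrate_acc):
            if acc not in by_acc:
                raise ValidationError(
                    f"cleavage row {i}: unknown accession {acc!r}"
                )
        if not by_acc[clv.protease_acc].is_protease:
            raise ValidationError(
                f"cleavage row {i}: {clv.protease_acc!r} lacks protease role"
            )
    for i, inh in enumerate(inhibitions):
        for acc in (inh.inhibitor_acc, inh.protease_acc):
            if acc not in by_acc:
                raise ValidationError(
                    f"inhibition row {i}: unknown accession {acc!r}"
                )
        if not by_acc[inh.inhibitor_acc].is_inhibitor:
            raise ValidationError(
                f"inhibition row {i}: {inh.inhibitor_acc!r} lacks inhibitor role"
            )
        if not by_acc[inh.protease_acc].is_protease:
            raise ValidationError(
                f"inhibition row {i}: target {inh.protease_acc!r} lacks "
                "protease role"
            )
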