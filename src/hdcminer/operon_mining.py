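"""Role calling and decarboxylase-antiporter gene-cluster detection.

A protein's role (pyruvoyl- or PLP-dependent histidine decarboxylase,
amino-acid antiporter, maturation factor hdcB, histidyl-tRNA synthetase,
or one of the arginine decarboxylases adiA/aaxB) is assigned from its
profile-HMM hits: among hits whose full-sequence e-value passes the
role-specific cutoff, the smallest e-value wins.  Cutoffs default to
1e-100 for the custom PLP-decarboxylase profile and 1e-40 for the
pyruvoyl (PF02329), antiporter (PTHR42770) and accessory profiles.

A histamine-secretion gene cluster is a genomic locus where a histidine
decarboxylase and an antiporter lie in the same gene neighborhood — fewer
than three genes apart, i.e. at most ``max_intervening`` (default 2)
genes between them.  Detection seeds on every qualifying
(decarboxylase, antiporter) pair, greedily extends with any role-bearing
gene within the same neighborhood distance of a member, and merges
overlapping seeds into maximal clusters; equivalently, a cluster is a
maximal chain of role-bearing genes (consecutive chain members at most
``max_intervening`` genes apart) that contains at least one qualifying
decarboxylase-antiporter pair.  Clusters never span contigs; strand is
ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from hdcminer.annotation_io import DomainHit, Gene, GenomeAnnotation

logger = logging.getLogger(__name__)


class Role(str, Enum):
    HDCA_PYR = "HDCA_PYR"
    HDCA_PLP = "HDCA_PLP"
    ANTIPORTER = "ANTIPORTER"
    HDCB = "HDCB"
    HISRS = "HISRS"
    ADIA = "ADIA"
    AAXB = "AAXB"
    OTHER = "OTHER"


#: Labels used in architecture strings (ordinal order, joined by "/").
ROLE_LABELS: dict[Role, str] = {
    Role.HDCA_PYR: "hdcA_pyr",
    Role.HDCA_PLP: "hdcA_plp",
    Role.ANTIPORTER: "antiporter",
    Role.HDCB: "hdcB",
    Role.HISRS: "hisRS",
    Role.ADIA: "adiA",
    Role.AAXB: "aaxB",
}

HDCA_ROLES = frozenset({Role.HDCA_PYR, Role.HDCA_PLP})
ACCESSORY_ROLES = frozenset({Role.HDCB, Role.HISRS, Role.ADIA, Role.AAXB})
THREE_COMPONENT_ROLES = frozenset({Role.ADIA, Role.AAXB})


@dataclass(frozen=True)
class ProfileRole:
    """Role (and optional antiporter subtype) conferred by one profile."""

    role: Role
    antiporter_subtype: str | None = None


#: Default profile->role configuration.  PF02329 is the Pfam pyruvoyl
#: histidine-decarboxylase profile and PTHR42770 the PANTHER amino-acid
#: antiporter profile; HDC_PLP_custom stands for the custom PLP-dependent
#: decarboxylase profile; subtype-specific antiporter entries carry the
#: gadC/aaxC/adiC annotation.  The remaining *_custom profiles cover the
#: accessory genes.
DEFAULT_PROFILE_ROLE_MAP: dict[str, ProfileRole] = {
    "HDC_PLP_custom": ProfileRole(Role.HDCA_PLP),
    "PF02329": ProfileRole(Role.HDCA_PYR),
    "PTHR42770": ProfileRole(Role.ANTIPORTER),
    "PTHR42770_gadC": ProfileRole(Role.ANTIPORTER, "gadC"),
    "PTHR42770_aaxC": ProfileRole(Role.ANTIPORTER, "aaxC"),
    "PTHR42770_adiC": ProfileRole(Role.ANTIPORTER, "adiC"),
    "HDCB_custom": ProfileRole(Role.HDCB),
    "HISRS_custom": ProfileRole(Role.HISRS),
    "ADIA_custom": ProfileRole(Role.ADIA),
    "AAXB_custom": ProfileRole(Role.AAXB),
}


@dataclass
class RoleThresholds:
    """Per-role e-value cutoffs (a hit passes when e-value <= cutoff)."""

    plp_hdcA_max_evalue: float = 1e-100
    pyruvoyl_hdcA_max_evalue: float = 1e-40
    antiporter_max_evalue: float = 1e-40
    accessory_max_evalue: float = 1e-40
    profile_role_map: Mapping[str, ProfileRole] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_ROLE_MAP)
    )

    def __post_init__(self) -> None:
        for name in (
            "plp_hdcA_max_evalue",
            "pyruvoyl_hdcA_max_evalue",
            "antiporter_max_evalue",
            "accessory_max_evalue",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def cutoff_for(self, role: Role) -> float:
        if role is Role.HDCA_PLP:
            return self.plp_hdcA_max_evalue
        if role is Role.HDCA_PYR:
            return self.pyruvoyl_hdcA_max_evalue
        if role is Role.ANTIPORTER:
            return self.antiporter_max_evalue
        if role in ACCESSORY_ROLES:
            return self.accessory_max_evalue
        raise ValueError(f"no cutoff for role {role}")


@dataclass(frozen=True)
class RoleCall:
    protein_id: str
    role: Role
    antiporter_subtype: str | None = None
    best_evalue: float = math.inf

    def __post_init__(self) -> None:
        if self.antiporter_subtype is not None and self.role is not Role.ANTIPORTER:
            raise ValueError("antiporter_subtype only valid for ANTIPORTER role")


@dataclass
class NeighborhoodRule:
    """Neighborhood distance: max number of genes between cluster neighbors."""

    max_intervening: int = 2

    def __post_init__(self) -> None:
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")


@dataclass
class GeneCluster:
    """A detected decarboxylase-antiporter locus with architecture flags."""

    genome_id: str
    contig_id: str
    members: list[tuple[Gene, RoleCall]]
    pathway: str = ""
    architecture: str = ""
    has_hdcB: bool = False
    has_hisRS: bool = False
    three_component: bool = False
    duplicated_antiporter: bool = False

    def member_roles(self) -> list[Role]:
        return [rc.role for _, rc in self.members]

    def validate(self, rule: NeighborhoodRule | None = None) -> None:
        roles = set(self.member_roles())
        if not roles & HDCA_ROLES or Role.ANTIPORTER not in roles:
            raise ValueError("cluster must contain an hdcA and an antiporter")
        ordinals = [g.ordinal for g, _ in self.members]
        if ordinals != sorted(ordinals):
            raise ValueError("cluster members must be sorted by ordinal")
        if rule is not None:
            for (a, _), (b, _) in zip(self.members, self.members[1:]):
                if b.ordinal - a.ordinal - 1 > rule.max_intervening:
                    raise ValueError("adjacent members exceed the neighborhood distance")


# ---------------------------------------------------------------------------
# Role calling
# ---------------------------------------------------------------------------

def call_roles(
    hits: Iterable[DomainHit], thresholds: RoleThresholds | None = None
) -> dict[str, RoleCall]:
    """Assign each protein the role of its best passing profile hit.

    A hit passes when its full-sequence e-value is at or below the cutoff
    of the role its profile confers (cutoffs are inclusive: an e-value
    exactly at the cutoff passes).  Among passing hits the smallest
    e-value wins; ties break on profile id for determinism.  Proteins
    with no passing hit are absent from the returned mapping (treated as
    role OTHER downstream); unknown profiles are ignored.
    """
    thresholds = thresholds or RoleThresholds()
    best: dict[str, tuple[float, str, ProfileRole]] = {}
    for hit in hits:
        profile_role = thresholds.profile_role_map.get(hit.profile_id)
        if profile_role is None:
            logger.debug("ignoring hit to unknown profile %s", hit.profile_id)
            continue
        if hit.evalue > thresholds.cutoff_for(profile_role.role):
            continue
        key = (hit.evalue, hit.profile_id, profile_role)
        current = best.get(hit.protein_id)
        if current is None or key[:2] < current[:2]:
            best[hit.protein_id] = key
    return {
        protein_id: RoleCall(
            protein_id=protein_id,
            role=pr.role,
            antiporter_subtype=pr.antiporter_subtype,
            best_evalue=evalue,
        )
        for protein_id, (evalue, _profile, pr) in best.items()
    }


def near_threshold_report(
    hits: Iterable[DomainHit],
    thresholds: RoleThresholds | None = None,
    factor: float = 10.0,
) -> pd.DataFrame:
    """List failing hits within *factor* of their cutoff, for human review.

    This is the deterministic replacement for manual curation of
    borderline profile matches: a hit that misses its role cutoff but has
    e-value <= factor x cutoff is worth a look.
    """
    thresholds = thresholds or RoleThresholds()
    rows = []
    for hit in hits:
        profile_role = thresholds.profile_role_map.get(hit.profile_id)
        if profile_role is None:
            continue
        cutoff = thresholds.cutoff_for(profile_role.role)
        if cutoff < hit.evalue <= factor * cutoff:
            rows.append(
                {
                    "protein_id": hit.protein_id,
                    "profile_id": hit.profile_id,
                    "role": profile_role.role.value,
                    "evalue": hit.evalue,
                    "cutoff": cutoff,
                    "ratio": hit.evalue / cutoff,
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "profile_id", "role", "evalue", "cutoff", "ratio"]
    )


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def _has_seed_pair(members: list[tuple[Gene, RoleCall]], max_intervening: int) -> bool:
    """Is some (hdcA, antiporter) pair within the neighborhood distance?

    The intervening count between two genes is the number of genes of any
    kind strictly between them on the contig (ordinal difference minus 1).
    """
    hdca = [g.ordinal for g, rc in members if rc.role in HDCA_ROLES]
    anti = [g.ordinal for g, rc in members if rc.role is Role.ANTIPORTER]
    return any(abs(a - b) - 1 <= max_intervening for a in hdca for b in anti)


def find_clusters(
    annotation: GenomeAnnotation,
    roles: Mapping[str, RoleCall],
    rule: NeighborhoodRule | None = None,
) -> list[GeneCluster]:
    """Detect maximal decarboxylase-antiporter clusters on each contig.

    Role-bearing genes (any non-OTHER role) are chained: consecutive
    role-bearing genes separated by at most ``rule.max_intervening`` other
    genes belong to the same chain.  Every chain containing a histidine
    decarboxylase and an antiporter within the neighborhood distance of
    each other is emitted as one cluster, with architecture flags
    populated.  This is exactly the fixed point of seeding on qualifying
    pairs and greedily merging/extending within the distance.
    """
    rule = rule or NeighborhoodRule()
    clusters: list[GeneCluster] = []
    for contig_id, genes in annotation.genes_by_contig.items():
        role_genes = [
            (g, roles[g.protein_id])
            for g in genes
            if g.protein_id in roles and roles[g.protein_id].role is not Role.OTHER
        ]
        chain: list[tuple[Gene, RoleCall]] = []
        chains: list[list[tuple[Gene, RoleCall]]] = []
        for item in role_genes:
            if chain and item[0].ordinal - chain[-1][0].ordinal - 1 > rule.max_intervening:
                chains.append(chain)
                chain = []
            chain.append(item)
        if chain:
            chains.append(chain)
        for members in chains:
            if _has_seed_pair(members, rule.max_intervening):
                cluster = GeneCluster(
                    genome_id=annotation.genome_id,
                    contig_id=contig_id,
                    members=members,
                )
                clusters.append(classify_architecture(cluster))
    return clusters


def classify_architecture(cluster: GeneCluster) -> GeneCluster:
    """Populate the architecture string and layout flags of a cluster.

    The architecture lists member role labels in ordinal order (e.g.
    ``hdcA_pyr/antiporter/hdcB``).  Pathway is PYR, PLP or BOTH from the
    decarboxylase roles present; three_component marks an arginine
    decarboxylase (adiA or aaxB) sharing the locus; duplicated_antiporter
    marks two antiporters flanking a decarboxylase.
    """
    cluster.validate()
    roles = cluster.member_roles()
    cluster.architecture = "/".join(ROLE_LABELS[r] for r in roles)
    has_pyr = Role.HDCA_PYR in roles
    has_plp = Role.HDCA_PLP in roles
    cluster.pathway = "BOTH" if (has_pyr and has_plp) else ("PYR" if has_pyr else "PLP")
    cluster.has_hdcB = Role.HDCB in roles
    cluster.has_hisRS = Role.HISRS in roles
    cluster.three_component = bool(set(roles) & THREE_COMPONENT_ROLES)
    anti_idx = [i for i, r in enumerate(roles) if r is Role.ANTIPORTER]
    hdca_idx = [i for i, r in enumerate(roles) if r in HDCA_ROLES]
    cluster.duplicated_antiporter = any(
        a < h < b for a in anti_idx for b in anti_idx for h in hdca_idx
    )
    return cluster


def genomes_with_clusters(clusters: Iterable[GeneCluster]) -> set[str]:
    return {c.genome_id for c in clusters}


def clusters_to_frame(clusters: Iterable[GeneCluster]) -> pd.DataFrame:
    """Tabulate clusters for the TSV report."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "member_gene_ids": ";".join(g.gene_id for g, _ in c.members),
                "member_roles": ";".join(rc.role.value for _, rc in c.members),
                "antiporter_subtypes": ";".join(
                    rc.antiporter_subtype or "NA"
                    for _, rc in c.members
                    if rc.role is Role.ANTIPORTER
                ),
                "architecture": c.architecture,
                "pathway": c.pathway,
                "has_hdcB": c.has_hdcB,
                "has_hisRS": c.has_hisRS,
                "three_component": c.three_component,
                "duplicated_antiporter": c.duplicated_antiporter,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "contig_id",
            "member_gene_ids",
            "member_roles",
            "antiporter_subtypes",
            "architecture",
            "pathway",
            "has_hdcB",
            "has_hisRS",
            "three_component",
            "duplicated_antiporter",
        ],
    )
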