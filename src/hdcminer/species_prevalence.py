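"""Species-level prevalence of histamine-secretion gene clusters.

A species is a histamine-secreting bacterium (HSB) when more than half of
its sequenced strains carry a decarboxylase-antiporter cluster (strict
> 0.5: exactly half does not qualify).  A species where some but at most
half of the strains carry the cluster is strain-specific.  A genome with
any number of clusters counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from hdcminer.annotation_io import GenomeAnnotation, SpeciesMap, ValidationError
from hdcminer.operon_mining import GeneCluster


@dataclass(frozen=True)
class SpeciesPrevalence:
    species_id: str
    n_genomes: int
    n_with_cluster: int
    prevalence: float
    pathways_present: frozenset[str]
    is_hsb: bool
    is_strain_specific: bool
    lineage: tuple[str, ...] = ()


def summarize_species(
    clusters: Iterable[GeneCluster],
    species_map: SpeciesMap,
    annotations: Iterable[GenomeAnnotation],
    hsb_threshold: float = 0.5,
) -> list[SpeciesPrevalence]:
    """Aggregate per-genome cluster presence into per-species prevalence.

    Every annotated genome must be present in the species map, and every
    cluster must come from an annotated, mapped genome.  Pathways present
    are the union of cluster pathways over the species' genomes (a BOTH
    cluster contributes both PYR and PLP).
    """
    genome_ids = []
    for ann in annotations:
        if ann.genome_id not in species_map:
            raise ValidationError(f"genome {ann.genome_id} missing from species map")
        genome_ids.append(ann.genome_id)
    genome_set = set(genome_ids)

    carriers: dict[str, set[str]] = {}
    pathways: dict[str, set[str]] = {}
    for cluster in clusters:
        if cluster.genome_id not in species_map or cluster.genome_id not in genome_set:
            raise ValidationError(
                f"cluster genome {cluster.genome_id} not in species map/annotations"
            )
        sp = species_map.species_of(cluster.genome_id)
        carriers.setdefault(sp, set()).add(cluster.genome_id)
        if cluster.pathway == "BOTH":
            pathways.setdefault(sp, set()).update({"PYR", "PLP"})
        else:
            pathways.setdefault(sp, set()).add(cluster.pathway)

    species_genomes: dict[str, list[str]] = {}
    for g in genome_ids:
        species_genomes.setdefault(species_map.species_of(g), []).append(g)

    out = []
    for sp in sorted(species_genomes):
        n = len(species_genomes[sp])
        k = len(carriers.get(sp, ()))
        prevalence = k / n
        is_hsb = prevalence > hsb_threshold
        out.append(
            SpeciesPrevalence(
                species_id=sp,
                n_genomes=n,
                n_with_cluster=k,
                prevalence=prevalence,
                pathways_present=frozenset(pathways.get(sp, ())),
                is_hsb=is_hsb,
                is_strain_specific=(k > 0 and not is_hsb),
                lineage=species_map.lineage_of(species_genomes[sp][0]),
            )
        )
    return out


def hsb_species(summaries: Iterable[SpeciesPrevalence]) -> set[str]:
    """Species flagged as histamine-secreting (>50% of strains with cluster)."""
    return {s.species_id for s in summaries if s.is_hsb}


def prevalence_to_frame(summaries: Iterable[SpeciesPrevalence]) -> pd.DataFrame:
    rows = [
        {
            "species_id": s.species_id,
            "lineage": ";".join(s.lineage),
            "n_genomes": s.n_genomes,
            "n_with_cluster": s.n_with_cluster,
            "n_without_cluster": s.n_genomes - s.n_with_cluster,
            "prevalence": s.prevalence,
            "pathways_present": ",".join(sorted(s.pathways_present)),
            "is_hsb": s.is_hsb,
            "is_strain_specific": s.is_strain_specific,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "lineage",
            "n_genomes",
            "n_with_cluster",
            "n_without_cluster",
            "prevalence",
            "pathways_present",
            "is_hsb",
            "is_strain_specific",
        ],
    )
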