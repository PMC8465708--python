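"""Seeded generators for every input the pipeline consumes.

Two families of synthetic data are produced:

* annotated genomes with histamine-secretion operons planted at a
  controlled strain prevalence, together with a matching profile-hit
  table, species map and a truth table of the planted clusters.  Planted
  member proteins receive hits drawn log-uniformly below the role
  cutoffs; decoy genes receive no hit or a failing hit (optionally close
  to the cutoff, to exercise boundary behaviour).  No sequence-level
  realism is attempted — hits are planted, not computed from homology.

* overdispersed species count tables (gamma-Poisson, i.e. negative
  binomial, with log-normal baseline compositions and library sizes)
  with disease-associated fold changes planted in a controlled subset of
  species, plus per-sample operon read counts derived binomially from
  the summed relative abundance of operon-bearing species.

All randomness flows from a single integer seed through per-genome /
per-table substreams, so outputs are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hdcminer.annotation_io import (
    DomainHit,
    GenomeAnnotation,
    SpeciesMap,
    write_domtblout,
    write_gff3,
    write_species_map,
)
from hdcminer.enrichment import CountTable
from hdcminer.operon_abundance import OperonReadCounts
from hdcminer.operon_mining import (
    HDCA_ROLES,
    ROLE_LABELS,
    Role,
    RoleThresholds,
)

#: role token -> (profile id, role, antiporter subtype)
_TOKEN_PROFILES: dict[str, tuple[str, Role, str | None]] = {
    "hdcA_pyr": ("PF02329", Role.HDCA_PYR, None),
    "hdcA_plp": ("HDC_PLP_custom", Role.HDCA_PLP, None),
    "antiporter": ("PTHR42770", Role.ANTIPORTER, None),
    "antiporter:gadC": ("PTHR42770_gadC", Role.ANTIPORTER, "gadC"),
    "antiporter:aaxC": ("PTHR42770_aaxC", Role.ANTIPORTER, "aaxC"),
    "antiporter:adiC": ("PTHR42770_adiC", Role.ANTIPORTER, "adiC"),
    "hdcB": ("HDCB_custom", Role.HDCB, None),
    "hisRS": ("HISRS_custom", Role.HISRS, None),
    "adiA": ("ADIA_custom", Role.ADIA, None),
    "aaxB": ("AAXB_custom", Role.AAXB, None),
}


class SpecError(ValueError):
    """A simulation spec is internally inconsistent."""


@dataclass
class SpeciesSimSpec:
    """One species in a genome simulation."""

    species_id: str
    n_strains: int
    operon_prevalence: float
    architecture: Sequence[str]  # role tokens, e.g. ("hdcA_pyr", "antiporter:gadC")
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.operon_prevalence <= 1:
            raise SpecError("operon_prevalence must be in [0,1]")
        roles = [token_role(t) for t in self.architecture]
        if self.architecture and (
            not set(roles) & HDCA_ROLES or Role.ANTIPORTER not in roles
        ):
            raise SpecError(
                f"{self.species_id}: architecture must contain an hdcA and an antiporter"
            )


@dataclass
class GenomeSimSpec:
    species: list[SpeciesSimSpec]
    decoys_per_genome: int = 8
    genes_per_contig: int = 30
    near_threshold_fraction: float = 0.0
    max_member_gap: int = 2  # decoys allowed between adjacent planted members
    detect_max_intervening: int = 2  # planted pairs kept detectable at this distance
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.near_threshold_fraction <= 1:
            raise SpecError("near_threshold_fraction must be in [0,1]")
        if min(self.decoys_per_genome, self.genes_per_contig) < 0:
            raise SpecError("counts must be >= 0")


@dataclass
class SimulatedGenomes:
    annotations: list[GenomeAnnotation]
    hits: list[DomainHit]
    species_map: SpeciesMap
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gff3(self.annotations, outdir / "genomes.gff3")
        write_domtblout(self.hits, outdir / "hits.domtblout")
        write_species_map(self.species_map, outdir / "species_map.tsv")
        self.truth.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)


def token_role(token: str) -> Role:
    try:
        return _TOKEN_PROFILES[token][1]
    except KeyError:
        raise SpecError(f"unknown role token {token!r}") from None


def _planted_count(n_strains: int, prevalence: float) -> int:
    """round(n * p) with exact .5 rounded up (away from zero)."""
    return int(np.floor(n_strains * prevalence + 0.5))


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def _min_pair_intervening(tokens: Sequence[str], gaps: Sequence[int]) -> int:
    """Smallest gene count between any planted (hdcA, antiporter) pair.

    Between member slots i < j there are (j - i - 1) members plus the
    decoy gaps in slots i..j-1.
    """
    roles = [token_role(t) for t in tokens]
    hdca = [i for i, r in enumerate(roles) if r in HDCA_ROLES]
    anti = [i for i, r in enumerate(roles) if r is Role.ANTIPORTER]
    best = None
    for a in hdca:
        for b in anti:
            i, j = min(a, b), max(a, b)
            between = (j - i - 1) + sum(gaps[i:j])
            best = between if best is None else min(best, between)
    return best if best is not None else 10**9


def _truth_flags(tokens: Sequence[str]) -> dict:
    """Architecture string and layout flags computed from the planted tokens."""
    roles = [token_role(t) for t in tokens]
    labels = [ROLE_LABELS[r] for r in roles]
    anti = [i for i, r in enumerate(roles) if r is Role.ANTIPORTER]
    hdca = [i for i, r in enumerate(roles) if r in HDCA_ROLES]
    has_pyr = Role.HDCA_PYR in roles
    has_plp = Role.HDCA_PLP in roles
    return {
        "architecture": "/".join(labels),
        "pathway": "BOTH" if has_pyr and has_plp else ("PYR" if has_pyr else "PLP"),
        "has_hdcB": Role.HDCB in roles,
        "has_hisRS": Role.HISRS in roles,
        "three_component": bool({Role.ADIA, Role.AAXB} & set(roles)),
        "duplicated_antiporter": any(
            a < h < b for a in anti for b in anti for h in hdca
        ),
    }


def simulate_genomes(spec: GenomeSimSpec) -> SimulatedGenomes:
    """Generate annotated genomes with planted operons plus a hit table.

    For each species exactly ``round(n_strains x operon_prevalence)``
    strains (chosen by a seeded permutation) receive one planted cluster:
    member genes inserted at a random locus, adjacent members separated
    by 0..max_member_gap decoy genes, with gaps shrunk where needed so
    some decarboxylase-antiporter pair stays within
    ``detect_max_intervening`` genes.  Planted member proteins get hits
    drawn log-uniformly in [cutoff x 1e-20, cutoff]; a seeded subset of
    decoys gets failing hits, a ``near_threshold_fraction`` of them
    within 10x of the cutoff.
    """
    thresholds = RoleThresholds()
    annotations: list[GenomeAnnotation] = []
    hits: list[DomainHit] = []
    mapping: dict[str, tuple[str, tuple[str, ...]]] = {}
    truth_rows: list[dict] = []

    for sp_idx, sp in enumerate(spec.species):
        n_carry = _planted_count(sp.n_strains, sp.operon_prevalence)
        order_rng = np.random.default_rng([spec.seed, sp_idx])
        carriers = set(order_rng.permutation(sp.n_strains)[:n_carry].tolist())
        for strain in range(sp.n_strains):
            genome_id = f"{sp.species_id}_s{strain}"
            contig_id = f"{genome_id}_c1"
            mapping[genome_id] = (sp.species_id, sp.lineage)
            rng = np.random.default_rng([spec.seed, sp_idx, strain])

            tokens = list(sp.architecture) if strain in carriers else []
            n_members = len(tokens)
            if spec.genes_per_contig < n_members * (spec.max_member_gap + 1):
                raise SpecError("genes_per_contig too small for the planted cluster")

            # layout: member tokens spliced into the decoy run, with decoy
            # gaps of 0..max_member_gap genes between adjacent members
            decoy_pool = spec.genes_per_contig
            if tokens:
                gaps = [
                    int(rng.integers(0, spec.max_member_gap + 1))
                    for _ in range(n_members - 1)
                ]
                while _min_pair_intervening(tokens, gaps) > spec.detect_max_intervening:
                    gaps[int(np.argmax(gaps))] = 0
                free = decoy_pool - sum(gaps)
                insert_at = int(rng.integers(0, free + 1))
                slots: list[str | None] = [None] * insert_at
                for m, token in enumerate(tokens):
                    slots.append(token)
                    if m < len(gaps):
                        slots.extend([None] * gaps[m])
                slots.extend([None] * (free - insert_at))
            else:
                gaps = []
                slots = [None] * decoy_pool

            # gene coordinates along the contig
            records = []
            cursor = 1
            member_gene_ids: list[str] = []
            decoy_protein_ids: list[str] = []
            for k, token in enumerate(slots):
                start = cursor + int(rng.integers(20, 200))
                end = start + int(rng.integers(300, 2400))
                cursor = end
                gene_id = f"{genome_id}_g{k}"
                records.append(
                    dict(
                        gene_id=gene_id,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand="+" if rng.random() < 0.5 else "-",
                        protein_id=gene_id,
                    )
                )
                if token is not None:
                    member_gene_ids.append(gene_id)
                    profile_id, role, _subtype = _TOKEN_PROFILES[token]
                    cutoff = thresholds.cutoff_for(role)
                    hits.append(
                        DomainHit(
                            protein_id=gene_id,
                            profile_id=profile_id,
                            evalue=_log_uniform(rng, cutoff * 1e-20, cutoff),
                            bitscore=float(rng.uniform(200, 900)),
                        )
                    )
                else:
                    decoy_protein_ids.append(gene_id)

            # decoy hits: failing e-values, some near the cutoff
            n_decoy_hits = min(spec.decoys_per_genome, len(decoy_protein_ids))
            chosen = rng.choice(len(decoy_protein_ids), size=n_decoy_hits, replace=False)
            profile_ids = sorted(thresholds.profile_role_map)
            for idx in sorted(int(i) for i in chosen):
                profile_id = profile_ids[int(rng.integers(0, len(profile_ids)))]
                role = thresholds.profile_role_map[profile_id].role
                cutoff = thresholds.cutoff_for(role)
                if rng.random() < spec.near_threshold_fraction:
                    evalue = _log_uniform(rng, cutoff * 1.0000001, cutoff * 10)
                else:
                    evalue = _log_uniform(rng, cutoff * 1e10, 1e-2)
                hits.append(
                    DomainHit(
                        protein_id=decoy_protein_ids[idx],
                        profile_id=profile_id,
                        evalue=evalue,
                        bitscore=float(rng.uniform(5, 60)),
                    )
                )

            annotations.append(GenomeAnnotation.from_records(genome_id, records))
            if tokens:
                truth_rows.append(
                    {
                        "genome_id": genome_id,
                        "species_id": sp.species_id,
                        "contig_id": contig_id,
                        "member_gene_ids": ";".join(member_gene_ids),
                        "all_adjacent": all(g == 0 for g in gaps),
                        **_truth_flags(tokens),
                    }
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "genome_id",
            "species_id",
            "contig_id",
            "member_gene_ids",
            "all_adjacent",
            "architecture",
            "pathway",
            "has_hdcB",
            "has_hisRS",
            "three_component",
            "duplicated_antiporter",
        ],
    )
    return SimulatedGenomes(
        annotations=annotations,
        hits=hits,
        species_map=SpeciesMap(mapping=mapping),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceSimSpec:
    """Negative-binomial species count table with planted disease effects.

    Baseline species compositions are log-normal (sigma
    ``baseline_sigma``); library sizes are log-normal around
    ``library_size_mean``; counts are gamma-Poisson with dispersion
    ``dispersion``.  In disease samples the mean of each affected
    species is multiplied by ``planted_fold_change``.  Affected species
    are an exact ``round(fraction x group size)`` subset of each group
    by default; with ``random_affected`` each species is affected
    independently with its group's fraction as probability (the
    sampling model under which the downstream Z-test is calibrated).
    """

    n_species: int = 200
    n_hsb: int = 40
    n_control: int = 30
    n_disease: int = 30
    library_size_mean: int = 3_000_000
    library_size_sigma: float = 0.25
    baseline_sigma: float = 1.0
    dispersion: float = 0.3
    planted_fold_change: float = 8.0
    fraction_hsb_affected: float = 0.5
    fraction_other_affected: float = 0.05
    random_affected: bool = False
    study: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hsb > self.n_species:
            raise SpecError("n_hsb cannot exceed n_species")
        if self.dispersion <= 0:
            raise SpecError("dispersion must be > 0")
        if self.planted_fold_change < 1:
            raise SpecError("planted_fold_change must be >= 1")
        for f in (self.fraction_hsb_affected, self.fraction_other_affected):
            if not 0 <= f <= 1:
                raise SpecError("affected fractions must be in [0,1]")


@dataclass
class AbundanceTruth:
    hsb_species: list[str]
    affected_species: list[str]


def simulate_abundance(spec: AbundanceSimSpec) -> tuple[CountTable, AbundanceTruth]:
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_species
    species = [f"sp{i:04d}" for i in range(n)]
    hsb = species[: spec.n_hsb]
    is_hsb = np.zeros(n, dtype=bool)
    is_hsb[: spec.n_hsb] = True

    if spec.planted_fold_change == 1.0:
        affected = np.zeros(n, dtype=bool)
    elif spec.random_affected:
        draws = rng.random(n)
        affected = np.where(is_hsb, draws < spec.fraction_hsb_affected,
                            draws < spec.fraction_other_affected)
    else:
        affected = np.zeros(n, dtype=bool)
        hsb_idx = np.flatnonzero(is_hsb)
        other_idx = np.flatnonzero(~is_hsb)
        k_hsb = _planted_count(len(hsb_idx), spec.fraction_hsb_affected)
        k_other = _planted_count(len(other_idx), spec.fraction_other_affected)
        affected[rng.choice(hsb_idx, size=k_hsb, replace=False)] = True
        affected[rng.choice(other_idx, size=k_other, replace=False)] = True

    base = rng.lognormal(0.0, spec.baseline_sigma, n)
    rel = base / base.sum()
    n_samples = spec.n_control + spec.n_disease
    mu_log = np.log(spec.library_size_mean) - spec.library_size_sigma**2 / 2
    libs = rng.lognormal(mu_log, spec.library_size_sigma, n_samples)
    mult = np.ones((n, n_samples))
    mult[affected, spec.n_control:] = spec.planted_fold_change
    mu = rel[:, None] * libs[None, :] * mult
    lam = rng.gamma(1.0 / spec.dispersion, spec.dispersion * mu)
    counts = rng.poisson(lam).astype(np.int64)

    sample_ids = [f"{spec.study}_ctl{i:03d}" for i in range(spec.n_control)] + [
        f"{spec.study}_dis{i:03d}" for i in range(spec.n_disease)
    ]
    conditions = ["control"] * spec.n_control + ["disease"] * spec.n_disease
    table = CountTable(
        counts=pd.DataFrame(counts, index=species, columns=sample_ids),
        sample_meta=pd.DataFrame(
            {"study": spec.study, "condition": conditions}, index=pd.Index(sample_ids, name="sample_id")
        ),
    )
    truth = AbundanceTruth(
        hsb_species=hsb,
        affected_species=[species[i] for i in np.flatnonzero(affected)],
    )
    return table, truth


def simulate_operon_reads(
    table: CountTable,
    hsb_species: Iterable[str],
    length_weight: float = 8e-4,
    seed: int = 0,
) -> list[OperonReadCounts]:
    """Binomial per-sample operon read counts.

    Per sample the total mapped reads equal the library size and the
    operon reads are binomial with success probability
    ``length_weight`` x (summed relative abundance of operon-bearing
    species).  ``length_weight`` is roughly operon length over mean
    genome length.
    """
    if length_weight <= 0:
        raise ValueError("length_weight must be > 0")
    rng = np.random.default_rng([seed, 2])
    hsb = [s for s in table.counts.index if s in set(hsb_species)]
    totals = table.counts.sum(axis=0)
    mass = table.counts.loc[hsb].sum(axis=0) / totals if hsb else totals * 0.0
    out = []
    for sample_id in table.counts.columns:
        total = int(totals[sample_id])
        p = min(1.0, length_weight * float(mass[sample_id]))
        reads = int(rng.binomial(total, p))
        out.append(
            OperonReadCounts(
                sample_id=sample_id,
                condition=str(table.sample_meta.at[sample_id, "condition"]),
                reads_on_operon=reads,
                total_mapped=total,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Demo preset
# ---------------------------------------------------------------------------

def demo_genome_spec(seed: int = 0) -> GenomeSimSpec:
    """Five species, six strains each, mixed planted architectures."""
    return GenomeSimSpec(
        species=[
            SpeciesSimSpec(
                "speciesA", 6, 1.0, ("hdcA_pyr", "antiporter:gadC", "hdcB"),
                lineage=("d__Bacteria", "p__Firmicutes"),
            ),
            SpeciesSimSpec(
                "speciesB", 6, 0.5, ("hdcA_pyr", "hdcB", "antiporter:aaxC", "hisRS"),
                lineage=("d__Bacteria", "p__Firmicutes"),
            ),
            SpeciesSimSpec(
                "speciesC", 6, 5 / 6, ("adiA", "antiporter:aaxC", "hdcA_pyr"),
                lineage=("d__Bacteria", "p__Fusobacteriota"),
            ),
            SpeciesSimSpec(
                "speciesD", 6, 2 / 3, ("aaxB", "antiporter:aaxC", "hdcA_pyr"),
                lineage=("d__Bacteria", "p__Bacteroidota"),
            ),
            SpeciesSimSpec(
                "speciesE", 6, 1.0, ("antiporter:adiC", "hdcA_plp", "antiporter:adiC"),
                lineage=("d__Bacteria", "p__Proteobacteria"),
            ),
        ],
        decoys_per_genome=8,
        genes_per_contig=30,
        near_threshold_fraction=0.0,
        seed=seed,
    )
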