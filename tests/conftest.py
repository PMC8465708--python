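from __future__ import annotations

import numpy as np
import pytest

from hdcminer.annotation_io import GenomeAnnotation
from hdcminer.operon_mining import Role, RoleCall
from hdcminer.synthetic_data import demo_genome_spec, simulate_genomes

#: role tokens usable in hand-built contigs
TOKEN_ROLES = {
    "hdcA_pyr": Role.HDCA_PYR,
    "hdcA_plp": Role.HDCA_PLP,
    "antiporter": Role.ANTIPORTER,
    "hdcB": Role.HDCB,
    "hisRS": Role.HISRS,
    "adiA": Role.ADIA,
    "aaxB": Role.AAXB,
}


def make_contig(tokens, genome_id="g1", contig_id="c1", start_ordinals=None):
    """Build a one-contig annotation from role tokens (None = no role).

    Returns (annotation, roles) where *roles* maps protein ids of the
    role-bearing genes to RoleCalls.  ``start_ordinals`` optionally
    places the i-th token at the given ordinal, padding with role-less
    genes.
    """
    if start_ordinals is not None:
        n = max(start_ordinals) + 1
        slots = [None] * n
        for tok, o in zip(tokens, start_ordinals):
            slots[o] = tok
    else:
        slots = list(tokens)
    records = []
    roles = {}
    pos = 1
    for k, tok in enumerate(slots):
        start, end = pos + 10, pos + 500
        pos = end
        pid = f"{genome_id}_{contig_id}_g{k}"
        records.append(
            dict(gene_id=pid, contig_id=contig_id, start=start, end=end, strand="+",
                 protein_id=pid)
        )
        if tok is not None:
            roles[pid] = RoleCall(protein_id=pid, role=TOKEN_ROLES[tok], best_evalue=1e-60)
    return GenomeAnnotation.from_records(genome_id, records), roles


def random_contig(rng: np.random.Generator, max_genes: int = 12):
    """A random contig mixing role-bearing and role-less genes."""
    n = int(rng.integers(2, max_genes + 1))
    tokens = []
    names = list(TOKEN_ROLES)
    for _ in range(n):
        if rng.random() < 0.55:
            tokens.append(None)
        else:
            tokens.append(names[int(rng.integers(0, len(names)))])
    return make_contig(tokens)


@pytest.fixture(scope="session")
def demo_sim():
    """The demo genome simulation (5 species x 6 strains), seed 1."""
    return simulate_genomes(demo_genome_spec(seed=1))
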