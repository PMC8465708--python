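import numpy as np
import pytest

from _oracles import brute_force_cluster_sets
from conftest import make_contig, random_contig
from hdcminer.annotation_io import DomainHit
from hdcminer.operon_mining import (
    NeighborhoodRule,
    Role,
    RoleThresholds,
    call_roles,
    classify_architecture,
    find_clusters,
    near_threshold_report,
)


def hit(protein, profile, evalue):
    return DomainHit(protein_id=protein, profile_id=profile, evalue=evalue, bitscore=100.0)


class TestCallRoles:
    @pytest.mark.parametrize(
        "profile,evalue,expected_role",
        [
            ("HDC_PLP_custom", 1e-100, Role.HDCA_PLP),  # cutoff inclusive
            ("HDC_PLP_custom", 2e-100, None),
            ("PF02329", 1e-41, Role.HDCA_PYR),
            ("PF02329", 1e-40, Role.HDCA_PYR),  # boundary passes
            ("PF02329", 1e-39, None),
            ("PTHR42770", 1e-40, Role.ANTIPORTER),
            ("PTHR42770", 1.0000001e-40, None),
            ("HDCB_custom", 1e-45, Role.HDCB),
            ("unknown_profile", 1e-200, None),
        ],
    )
    def test_evalue_cutoffs(self, profile, evalue, expected_role):
        roles = call_roles([hit("p1", profile, evalue)])
        if expected_role is None:
            assert "p1" not in roles
        else:
            assert roles["p1"].role is expected_role

    def test_smallest_evalue_wins(self):
        roles = call_roles([hit("p1", "PF02329", 1e-50), hit("p1", "PTHR42770", 1e-60)])
        assert roles["p1"].role is Role.ANTIPORTER
        assert roles["p1"].best_evalue == 1e-60

    def test_antiporter_subtype_from_winning_profile(self):
        roles = call_roles([hit("p1", "PTHR42770_gadC", 1e-55)])
        assert roles["p1"].role is Role.ANTIPORTER
        assert roles["p1"].antiporter_subtype == "gadC"

    def test_near_threshold_report_lists_borderline_hits(self):
        hits = [hit("p1", "PF02329", 5e-40), hit("p2", "PF02329", 1e-30),
                hit("p3", "PF02329", 1e-41)]
        report = near_threshold_report(hits)
        assert list(report.protein_id) == ["p1"]
        assert report.ratio.iloc[0] == pytest.approx(5.0)


class TestFindClusters:
    def test_pair_with_two_intervening_genes_clusters(self):
        ann, roles = make_contig(["hdcA_pyr", "antiporter"], start_ordinals=[5, 8])
        clusters = find_clusters(ann, roles)
        assert len(clusters) == 1
        assert clusters[0].pathway == "PYR"

    def test_pair_with_three_intervening_genes_does_not_cluster(self):
        ann, roles = make_contig(["hdcA_pyr", "antiporter"], start_ordinals=[5, 9])
        assert find_clusters(ann, roles) == []

    def test_three_component_architecture(self):
        ann, roles = make_contig(["adiA", "antiporter", "hdcA_pyr"])
        (c,) = find_clusters(ann, roles)
        assert c.three_component
        assert c.architecture == "adiA/antiporter/hdcA_pyr"

    def test_duplicated_antiporter_flag(self):
        ann, roles = make_contig(["antiporter", "hdcA_plp", "antiporter"])
        (c,) = find_clusters(ann, roles)
        assert c.duplicated_antiporter
        assert c.pathway == "PLP"

    def test_no_cluster_across_contigs(self):
        ann1, roles1 = make_contig(["hdcA_pyr"], contig_id="c1")
        ann2, roles2 = make_contig(["antiporter"], contig_id="c2")
        ann1.genes_by_contig.update(ann2.genes_by_contig)
        assert find_clusters(ann1, {**roles1, **roles2}) == []

    def test_hdca_and_antiporter_alone_needed(self):
        # a chain containing both roles but with no qualifying pair is not a cluster
        ann, roles = make_contig(
            ["hdcA_pyr", None, None, "hisRS", None, None, "antiporter"],
        )
        assert find_clusters(ann, roles, NeighborhoodRule(max_intervening=2)) == []

    def test_reversal_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ann, roles = random_contig(rng)
            fwd = find_clusters(ann, roles)
            genes = next(iter(ann.genes_by_contig.values()))
            n = len(genes)
            rev_records = [
                dict(gene_id=g.gene_id, contig_id=g.contig_id, start=10_000 - g.end,
                     end=10_000 - g.start, strand=g.strand, protein_id=g.protein_id)
                for g in genes
            ]
            from hdcminer.annotation_io import GenomeAnnotation

            rev_ann = GenomeAnnotation.from_records(ann.genome_id, rev_records)
            rev = find_clusters(rev_ann, roles)
            fwd_sets = {frozenset(g.gene_id for g, _ in c.members) for c in fwd}
            rev_sets = {frozenset(g.gene_id for g, _ in c.members) for c in rev}
            assert fwd_sets == rev_sets

    def test_pairs_clustered_monotone_in_max_intervening(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            ann, roles = random_contig(rng)
            counts = []
            for mi in range(0, 5):
                clusters = find_clusters(ann, roles, NeighborhoodRule(mi))
                pairs = 0
                for c in clusters:
                    hdca = [g for g, rc in c.members if rc.role in (Role.HDCA_PYR, Role.HDCA_PLP)]
                    anti = [g for g, rc in c.members if rc.role is Role.ANTIPORTER]
                    pairs += len(hdca) * len(anti)
                counts.append(pairs)
            assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_agrees_with_bruteforce_on_small_contigs(self):
        rng = np.random.default_rng(3)
        for i in range(60):
            ann, roles = random_contig(rng)
            mi = i % 4
            genes = next(iter(ann.genes_by_contig.values()))
            expected = brute_force_cluster_sets(genes, roles, mi)
            got = {
                frozenset(g.ordinal for g, _ in c.members)
                for c in find_clusters(ann, roles, NeighborhoodRule(mi))
            }
            assert got == expected


class TestClassifyArchitecture:
    @pytest.mark.parametrize(
        "tokens,architecture,flags",
        [
            (
                ["hdcA_pyr", "antiporter", "hdcB"],
                "hdcA_pyr/antiporter/hdcB",
                dict(has_hdcB=True, has_hisRS=False, three_component=False),
            ),
            (
                ["hdcA_pyr", "hdcB", "antiporter", "hisRS"],
                "hdcA_pyr/hdcB/antiporter/hisRS",
                dict(has_hdcB=True, has_hisRS=True, three_component=False),
            ),
            (
                ["aaxB", "antiporter", "hdcA_pyr"],
                "aaxB/antiporter/hdcA_pyr",
                dict(has_hdcB=False, has_hisRS=False, three_component=True),
            ),
        ],
    )
    def test_flags_and_architecture_string(self, tokens, architecture, flags):
        ann, roles = make_contig(tokens)
        (c,) = find_clusters(ann, roles)
        assert c.architecture == architecture
        for attr, value in flags.items():
            assert getattr(c, attr) is value

    def test_both_pathways_in_one_locus(self):
        ann, roles = make_contig(["hdcA_pyr", "antiporter", "hdcA_plp"])
        (c,) = find_clusters(ann, roles)
        assert c.pathway == "BOTH"

    def test_invalid_cluster_rejected(self):
        ann, roles = make_contig(["hdcA_pyr", "antiporter"])
        (c,) = find_clusters(ann, roles)
        c.members = [c.members[0]]  # drop the antiporter
        with pytest.raises(ValueError):
            classify_architecture(c)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            RoleThresholds(antiporter_max_evalue=0)
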