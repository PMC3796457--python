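import math
import random

import pytest

from kanseek.annotation import (
    GeneAssignment,
    annotate_regions,
    assign_region,
    position_distribution,
)
from kanseek.errors import ConfigError, ValidationError
from kanseek.io_formats import BindingRegion, GeneModel, read_fixture_table


def gene(gene_id="g1", strand="+", body=(1000, 2000), cds=None, chrom="chr1"):
    cds = cds or body
    return GeneModel(gene_id, chrom, strand, body[0], body[1], cds[0], cds[1])


def region(summit, rid="r1", chrom="chr1"):
    return BindingRegion(rid, chrom, summit - 50, summit + 50, summit=summit, enrichment=(4.0,), fdr=(0.01,))


class TestAssignRegion:
    def test_upstream_plus_strand(self):
        (a,) = assign_region(region(500), [gene()])
        assert (a.distance, a.location) == (500, "UP")  # 1000 - 500

    def test_contained_summit(self):
        (a,) = assign_region(region(1500), [gene()])
        assert (a.distance, a.location) == (0, "IN_CDS")

    def test_upstream_minus_strand_is_high_side(self):
        (a,) = assign_region(region(2300), [gene(strand="-")])
        assert (a.distance, a.location) == (300, "UP")

    def test_downstream_both_strands(self):
        (a_plus,) = assign_region(region(2300), [gene(strand="+")])
        assert (a_plus.distance, a_plus.location) == (300, "DOWN")
        (a_minus,) = assign_region(region(500), [gene(strand="-")])
        assert (a_minus.distance, a_minus.location) == (500, "DOWN")

    def test_window_excludes_far_genes(self):
        assert assign_region(region(500), [gene()], window=400) == []
        assert len(assign_region(region(500), [gene()], window=500)) == 1

    def test_is_nearest_unique_with_lexicographic_tie_break(self):
        genes = [
            gene("gb", body=(1000, 2000)),
            gene("ga", body=(3000, 4000)),  # same 500 bp distance from summit 2500
        ]
        assignments = assign_region(region(2500), genes)
        nearest = [a for a in assignments if a.is_nearest]
        assert len(nearest) == 1 and nearest[0].gene_id == "ga"

    def test_multiple_assignments_within_window(self):
        genes = [gene("g1", body=(1000, 2000)), gene("g2", body=(5000, 6000))]
        assignments = assign_region(region(2500), genes)
        assert {a.gene_id for a in assignments} == {"g1", "g2"}

    def test_bad_window_raises(self):
        with pytest.raises(ConfigError):
            assign_region(region(500), [gene()], window=0)

    def test_invariant_distance_zero_iff_in_cds(self):
        with pytest.raises(ValidationError):
            GeneAssignment("r", "g", 0, "UP")
        with pytest.raises(ValidationError):
            GeneAssignment("r", "g", 5, "IN_CDS")

    def test_gene_order_invariance(self):
        rng = random.Random(20240904)
        genes = [gene(f"g{i}", rng.choice("+-"), (i * 3000 + 1000, i * 3000 + 2500)) for i in range(20)]
        r = region(rng.randrange(0, 60000))
        baseline = assign_region(r, genes)
        for _ in range(5):
            shuffled = genes[:]
            rng.shuffle(shuffled)
            assert assign_region(r, shuffled) == baseline

    def test_strand_antisymmetry(self):
        rng = random.Random(20240905)
        genes = [gene(f"g{i}", rng.choice("+-"), (i * 4000 + 2000, i * 4000 + 3000)) for i in range(15)]
        flipped = [
            GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+", g.body_start, g.body_end, g.cds_start, g.cds_end)
            for g in genes
        ]
        for _ in range(50):
            r = region(rng.randrange(100, 64000))
            for a, b in zip(assign_region(r, genes), assign_region(r, flipped)):
                assert a.gene_id == b.gene_id and a.distance == b.distance
                if a.location == "IN_CDS":
                    assert b.location == "IN_CDS"
                else:
                    assert {a.location, b.location} == {"UP", "DOWN"}

    def test_midpoint_anchor(self):
        r = BindingRegion("r1", "chr1", 0, 400, summit=10, enrichment=(4.0,), fdr=(0.01,))
        (by_summit,) = assign_region(r, [gene()])
        (by_mid,) = assign_region(r, [gene()], anchor="midpoint")
        assert by_summit.distance == 990 and by_mid.distance == 800


class TestFixtureRowReconstruction:
    """Each printed (distance, location) pair is reproduced on a toy locus."""

    @pytest.mark.parametrize("name", ["table1", "table2"])
    def test_rows(self, name):
        df = read_fixture_table(name)
        body = (50000, 62000)
        for _, row in df.iterrows():
            loc = str(row["Location"]).strip()
            g = gene(body=body)
            if loc == "in CDS":
                summit = 55000
                expected = (0, "IN_CDS")
            elif loc == "UP":
                d = int(row["Distance"])
                summit = body[0] - d
                expected = (d, "UP")
            else:
                d = int(row["Distance"])
                summit = body[1] + d
                expected = (d, "DOWN")
            (a,) = assign_region(region(summit), [g])
            assert (a.distance, a.location) == expected


class TestPositionDistribution:
    def _assignments(self, labels):
        out = []
        for i, (location, distance) in enumerate(labels):
            out.append(GeneAssignment(f"r{i}", "g", distance, location, is_nearest=True))
        return out

    def test_all_upstream(self):
        a = self._assignments([("UP", 400), ("UP", 999), ("UP", 1)])
        summary = position_distribution(a)
        assert summary.as_dict()["upstream_0_1kb"] == (3, 1.0)

    def test_empty_input_yields_empty_summary(self):
        summary = position_distribution([])
        assert summary.labels == () and summary.counts == ()

    def test_bins_and_proportions(self):
        a = self._assignments([("UP", 400), ("IN_CDS", 0), ("DOWN", 100), ("UP", 5000)])
        summary = position_distribution(a)
        d = summary.as_dict()
        assert d["upstream_0_1kb"] == (1, 0.25)
        assert d["gene_body"] == (1, 0.25)
        assert d["downstream_0_1kb"] == (1, 0.25)
        assert d["distal"] == (1, 0.25)
        assert math.isclose(sum(summary.proportions), 1.0)

    def test_unassigned_regions_fall_in_distal(self):
        regions = [region(100, rid="r0"), region(999999, rid="rX")]
        a = self._assignments([("UP", 400)])
        summary = position_distribution(a, regions=regions)
        assert summary.as_dict()["distal"] == (1, 0.5)

    def test_no_distal_bin_raises(self):
        regions = [region(100, rid="rX")]
        with pytest.raises(ConfigError):
            position_distribution([], regions=regions, bin_scheme=("upstream_0_1kb",))

    def test_mixture_recovery_on_synthetic_regions(self, mixture_study):
        """Recovered positional mixture within 3 binomial SE per bin (n >= 2000)."""
        study = mixture_study
        assignments = annotate_regions(study.regions, study.genes)
        summary = position_distribution(assignments, regions=study.regions)
        n = len(study.regions)
        assert n >= 2000
        expected = {
            "upstream_0_1kb": study.config.mixture["upstream_1kb"],
            "gene_body": study.config.mixture["gene_body"],
            "downstream_0_1kb": study.config.mixture["downstream_1kb"],
            "distal": study.config.mixture["distal"],
        }
        for label, (count, prop) in summary.as_dict().items():
            p = expected[label]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(prop - p) <= 3 * se, (label, prop, p)
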