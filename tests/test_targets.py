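import numpy as np
import pytest

from tfosmap.classify import AssayKey, Category, classify_tfos
from tfosmap.formats import GenomicInterval, Peak, read_chains
from tfosmap.reciprocal_map import build_bijective_map
from tfosmap.targets import (
    EnhancerGeneLink,
    OrthologTable,
    compare_target_conservation,
    link_targets,
    read_links,
    read_orthologs,
    retained_target_fraction,
)

from tfosmap.classify import AnalogTable


@pytest.fixture(scope="module")
def simple_setting():
    txt = "chain 1000 chrT 200 + 10 60 chrQ 300 + 110 160 1\n50\n"
    m = build_bijective_map(read_chains(txt), {"chrT": 200}, {"chrQ": 300})
    comp = {AssayKey("MEL", "CTCF"): [
        Peak(GenomicInterval("chrQ", 120, 130), cell="MEL", tf="CTCF",
             signal=1.0, species="mouse")]}
    peaks = [Peak(GenomicInterval("chrT", 20, 30, name="mxi1"), cell="K562",
                  tf="MXI1", signal=1.0, species="human")]
    classified = classify_tfos(peaks, m, comp, AnalogTable([("K562", "MEL")]))
    return m, classified


def link(chrom, start, end, gene, species=""):
    return EnhancerGeneLink(GenomicInterval(chrom, start, end), gene, species)


class TestLinkTargets:
    def test_shared_orthologous_target_scores_one(self, simple_setting):
        """A repurposed element whose homologous site links to the
        orthologous gene keeps a conserved regulatory output."""
        m, classified = simple_setting
        (rec,) = link_targets(
            classified,
            links_a=[link("chrT", 25, 80, "ACAP3")],
            links_b=[link("chrQ", 115, 135, "Acap3")],
            orthologs=OrthologTable([("ACAP3", "Acap3")]))
        assert classified[0].category is Category.FUNCT_ACTIVE
        assert rec.conservation_score == 1.0

    def test_no_links_at_homologous_site_scores_zero(self, simple_setting):
        m, classified = simple_setting
        (rec,) = link_targets(
            classified,
            links_a=[link("chrT", 25, 80, "ACAP3")],
            links_b=[],
            orthologs=OrthologTable([("ACAP3", "Acap3")]))
        assert rec.conservation_score == 0.0

    def test_no_own_targets_score_absent(self, simple_setting):
        m, classified = simple_setting
        (rec,) = link_targets(classified, [], [],
                              OrthologTable([("ACAP3", "Acap3")]))
        assert rec.conservation_score is None

    def test_invariant_to_non_orthologous_genes(self, simple_setting):
        m, classified = simple_setting
        la = [link("chrT", 25, 80, "ACAP3")]
        lb = [link("chrQ", 115, 135, "Acap3")]
        orth = OrthologTable([("ACAP3", "Acap3")])
        (before,) = link_targets(classified, la, lb, orth)
        la2 = la + [link("chrT", 20, 40, "NOVELA")]
        lb2 = lb + [link("chrQ", 110, 150, "NOVELB")]
        (after,) = link_targets(classified, la2, lb2, orth)
        assert before.conservation_score == after.conservation_score
        assert before.shared_orthologous == after.shared_orthologous


class TestPlantedRecovery:
    def test_retained_fractions_recovered_exactly(self, planted):
        peaks, links = planted["peaks"], planted["links"]
        classified = classify_tfos(peaks.peaks_a, planted["map"],
                                   peaks.compendium_b, peaks.analogs)
        records = link_targets(classified, links.links_a, links.links_b,
                               links.orthologs)
        assert retained_target_fraction(records, Category.FUNCT_ACTIVE) == 0.43
        assert retained_target_fraction(records, Category.FUNCT_CONS) == 0.9

    def test_empty_category_absent(self, planted):
        peaks, links = planted["peaks"], planted["links"]
        classified = classify_tfos(peaks.peaks_a, planted["map"],
                                   peaks.compendium_b, peaks.analogs)
        records = link_targets(classified, links.links_a, links.links_b,
                               links.orthologs)
        # species-specific TFos got no links in the plant
        assert retained_target_fraction(records,
                                        Category.SPECIES_SPECIFIC) is None


class TestCompareConservation:
    def _records(self, planted, fc_scores, fa_scores):
        # wrap bare score values in minimal records via planted TFos
        peaks = planted["peaks"]
        classified = classify_tfos(peaks.peaks_a, planted["map"],
                                   peaks.compendium_b, peaks.analogs)
        fc = [c for c in classified if c.category is Category.FUNCT_CONS]
        fa = [c for c in classified if c.category is Category.FUNCT_ACTIVE]
        from tfosmap.targets import TargetConservationRecord

        recs = []
        for c, s in zip(fc, fc_scores):
            recs.append(TargetConservationRecord(
                c, frozenset({"g1", "g2"}), frozenset(),
                int(round(2 * s))))
        for c, s in zip(fa, fa_scores):
            recs.append(TargetConservationRecord(
                c, frozenset({"g1", "g2"}), frozenset(),
                int(round(2 * s))))
        return recs

    def test_identical_distributions(self, planted):
        scores = [0.0, 0.5, 1.0] * 10
        res = compare_target_conservation(
            self._records(planted, scores, scores))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self, planted):
        res = compare_target_conservation(
            self._records(planted, [1.0] * 50, [0.0] * 50))
        assert res.statistic == 1.0
        assert res.p_value < 1e-20

    def test_planted_shift_recovers_cdf_gap(self, planted):
        rng = np.random.default_rng(0)
        fa = np.clip(rng.uniform(0, 1, 200), 0, 1)
        # shift by 0.3: the maximal CDF gap of U(0,1) vs U(0.3,1.3)
        # clipped to [0,1] is ~0.3 at x just below 0.3
        fc = np.clip(fa + 0.3, 0, 1)
        res = compare_target_conservation(self._records(
            planted, [round(x * 2) / 2 for x in fc],
            [round(x * 2) / 2 for x in fa]))
        assert res.statistic == pytest.approx(0.3, abs=0.12)

    def test_empty_category_untestable(self, planted):
        res = compare_target_conservation(
            self._records(planted, [], [0.5] * 5))
        assert res.untestable


def test_readers_and_duplicate_rejection():
    links = read_links("chr1\t10\t20\tACAP3\n", species="A")
    assert links[0].gene_id == "ACAP3"
    orth = read_orthologs("ACAP3\tAcap3\nPUSL1\tPusl1\n")
    assert orth.ortholog_of("PUSL1") == "Pusl1"
    assert orth.ortholog_of("Acap3", side="B") == "ACAP3"
    with pytest.raises(ValueError, match="repeated"):
        OrthologTable([("a", "b"), ("a", "c")])
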